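"""End-to-end pipeline: simulate/load -> normalize -> distances -> cluster
-> embed -> report.

A run consumes either the built-in synthetic 24-trial library (preset
``elderly24``) or a directory of real inputs (``skeletons/<trial>.csv``,
``seats/<trial>.yaml`` sidecars and ``metadata.tsv``), and writes every
intermediate artifact into one output directory together with a manifest
(config echo, seed, package version), so a run is fully auditable and a
fixed seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import (
    AverageBehavior,
    ClusterModel,
    Embedding,
    annotate_map,
    average_behavior,
    linkage,
    mds_embed,
    select_k,
)
from .io import (
    read_metadata_tsv,
    read_seat_scan,
    read_skeleton_csv,
    write_distance_matrix_csv,
    write_metadata_tsv,
    write_object_frame_json,
    write_seat_scan,
    write_skeleton_csv,
)
from .metrics import (
    N_RESAMPLED_FRAMES,
    BehaviorDistanceMatrix,
    distance_matrix,
    resample_sequence,
)
from .object_frame import SeatScan, SkeletonSequence, frame_from_scan, normalize_sequence
from .synthetic import elderly_library

logger = logging.getLogger("standmap")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All knobs of one analysis run.

    The defaults reproduce the reference analysis: 500-frame resampling,
    Manhattan trajectory distance, UPGMA linkage, silhouette scan over
    k = 2..12, 2-D SMACOF embedding with 8 restarts.
    """

    preset: str | None = "elderly24"
    in_dir: str | None = None
    out_dir: str = "standmap_run"
    seed: int = 0
    n_frames: int = N_RESAMPLED_FRAMES
    distance_norm: str = "manhattan"
    linkage_method: str = "upgma"
    k_min: int = 2
    k_max: int = 12
    mds_dim: int = 2
    mds_restarts: int = 8
    behavior_noise_sd: float = 0.01
    scan_noise_sd: float = 0.005
    write_plots: bool = False
    log_level: str = "INFO"

    def validate(self, n_trials: int | None = None) -> None:
        if self.preset is None and self.in_dir is None:
            raise ValueError("either preset or in_dir must be given")
        if self.preset is not None and self.preset != "elderly24":
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.distance_norm not in ("manhattan", "euclidean_per_frame"):
            raise ValueError(f"unknown distance_norm {self.distance_norm!r}")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")
        if n_trials is not None and self.k_max >= n_trials:
            raise ValueError(
                f"k_max={self.k_max} must be < number of trials ({n_trials})"
            )


@dataclass
class PipelineResult:
    """In-memory handle on everything a run computed and wrote."""

    config: PipelineConfig
    metadata: pd.DataFrame
    distances: BehaviorDistanceMatrix
    model: ClusterModel
    averages: list[AverageBehavior]
    embedding: Embedding
    map_table: pd.DataFrame
    out_dir: Path
    normalized: list[SkeletonSequence] = field(repr=False, default_factory=list)


def _load_inputs(
    config: PipelineConfig,
) -> tuple[list[tuple[SkeletonSequence, SeatScan]], pd.DataFrame]:
    if config.preset == "elderly24":
        trials, metadata = elderly_library(
            config.seed,
            behavior_noise_sd=config.behavior_noise_sd,
            scan_noise_sd=config.scan_noise_sd,
        )
        return [(t.sequence, t.scan) for t in trials], metadata
    in_dir = Path(config.in_dir)
    metadata = read_metadata_tsv(in_dir / "metadata.tsv")
    pairs = []
    for trial_id in metadata["trial_id"]:
        seq = read_skeleton_csv(in_dir / "skeletons" / f"{trial_id}.csv")
        scan = read_seat_scan(in_dir / "seats" / f"{trial_id}.yaml")
        pairs.append((seq, scan))
    return pairs, metadata


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order and write all artifacts to ``out_dir``."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage simulate/load: gathering trials")
    pairs, metadata = _load_inputs(config)
    config.validate(n_trials=len(pairs))
    write_metadata_tsv(metadata, out / "metadata.tsv")

    logger.info("stage normalize: fitting object frames for %d trials", len(pairs))
    (out / "frames").mkdir(exist_ok=True)
    (out / "normalized").mkdir(exist_ok=True)
    normalized: list[SkeletonSequence] = []
    for seq, scan in pairs:
        try:
            frame = frame_from_scan(scan, skeleton_hint=seq)
            norm = normalize_sequence(seq, frame)
        except ValueError as exc:
            raise RuntimeError(f"stage normalize failed on trial {seq.trial_id}: {exc}") from exc
        write_object_frame_json(frame, out / "frames" / f"{seq.trial_id}.json")
        write_skeleton_csv(norm, out / "normalized" / f"{seq.trial_id}.csv")
        normalized.append(norm)

    logger.info("stage distances: resampling to %d frames", config.n_frames)
    resampled = [resample_sequence(s, config.n_frames) for s in normalized]
    D = distance_matrix(resampled, norm=config.distance_norm)
    write_distance_matrix_csv(D, out / "distance_matrix.csv")

    logger.info("stage cluster: %s linkage, k in [%d, %d]", config.linkage_method,
                config.k_min, config.k_max)
    tree = linkage(D, method=config.linkage_method)
    model = select_k(tree, D, range(config.k_min, config.k_max + 1))
    pd.DataFrame(
        tree.merges, columns=["child_a", "child_b", "height", "size"]
    ).to_csv(out / "linkage.csv", index=False)
    (out / "dendrogram.nwk").write_text(tree.to_newick() + "\n", encoding="utf-8")
    pd.DataFrame(
        {"trial_id": D.trial_ids, "cluster": model.labels}
    ).to_csv(out / "labels.csv", index=False)
    pd.DataFrame(
        sorted(model.silhouette_by_k.items()), columns=["k", "mean_silhouette"]
    ).to_csv(out / "silhouette_by_k.csv", index=False)

    logger.info("stage averages: %d clusters", model.selected_k)
    averages = []
    (out / "averages").mkdir(exist_ok=True)
    for c in range(model.selected_k):
        members = [r for r, lab in zip(resampled, model.labels) if lab == c]
        ave = average_behavior(members, cluster_id=c)
        averages.append(ave)
        write_skeleton_csv(
            type(resampled[0])(trial_id=f"cluster_{c}_average", frames=ave.frames),
            out / "averages" / f"cluster_{c}.csv",
        )

    logger.info("stage embed: %d-D SMACOF, %d restarts", config.mds_dim, config.mds_restarts)
    emb = mds_embed(D, dim=config.mds_dim, seed=config.seed, n_restarts=config.mds_restarts)
    map_table = annotate_map(emb, metadata)
    map_table.to_csv(out / "map.csv", index=False)

    if config.write_plots:
        from . import plots

        plots.save_all(out, tree, model, emb, map_table)

    manifest = {
        "package": "standmap",
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "n_trials": len(pairs),
        "selected_k": model.selected_k,
        "cluster_sizes": model.cluster_sizes,
        "stress": emb.stress,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)

    logger.info(
        "done: k=%d, cluster sizes %s, stress %.4g",
        model.selected_k, model.cluster_sizes, emb.stress,
    )
    return PipelineResult(
        config=config,
        metadata=metadata,
        distances=D,
        model=model,
        averages=averages,
        embedding=emb,
        map_table=map_table,
        out_dir=out,
        normalized=normalized,
    )


def export_library(out_dir: str | Path, seed: int, **kwargs) -> Path:
    """Write the synthetic library to disk in the pipeline's input layout."""
    out = Path(out_dir)
    (out / "skeletons").mkdir(parents=True, exist_ok=True)
    (out / "seats").mkdir(exist_ok=True)
    trials, metadata = elderly_library(seed, **kwargs)
    write_metadata_tsv(metadata, out / "metadata.tsv")
    for t in trials:
        write_skeleton_csv(t.sequence, out / "skeletons" / f"{t.sequence.trial_id}.csv")
        write_seat_scan(t.scan, out / "seats", stem=t.sequence.trial_id)
    return out
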