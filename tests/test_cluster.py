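"""Linkage, silhouette model selection, cluster averages and the 2-D map."""

import numpy as np
import pandas as pd
import pytest
from sklearn.manifold import smacof

from conftest import random_resampled
from oracles import (
    elementwise_mean,
    naive_upgma,
    procrustes_error,
    scipy_merge_sets,
    silhouette_by_hand,
)
from standmap.cluster import (
    annotate_map,
    average_behavior,
    linkage,
    mds_embed,
    select_k,
    silhouette_score,
)
from standmap.metrics import distance_matrix
from standmap.synthetic import elderly_library


def _random_metric_matrix(rng, n):
    """A Euclidean (hence metric) random dissimilarity matrix."""
    pts = rng.normal(size=(n, 3))
    D = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    return D


class TestLinkage:
    def test_two_pairs_merge_then_join(self):
        D = np.array(
            [
                [0, 1, 10, 10],
                [1, 0, 10, 10],
                [10, 10, 0, 1],
                [10, 10, 1, 0],
            ],
            dtype=float,
        )
        tree = linkage(D)
        heights = tree.merges[:, 2]
        assert np.allclose(heights, [1, 1, 10])
        assert sorted(tree.cut(2).tolist()) == [0, 0, 1, 1]

    def test_two_leaves_single_merge(self):
        D = np.array([[0, 2.5], [2.5, 0]])
        tree = linkage(D)
        assert tree.merges.shape == (1, 4)
        assert tree.merges[0, 2] == pytest.approx(2.5)

    def test_matches_naive_agglomeration(self, rng):
        D = _random_metric_matrix(rng, 6)
        tree = linkage(D)
        got = scipy_merge_sets(tree.merges, 6)
        want = naive_upgma(D)
        for (ga, gb, gh), (wa, wb, wh) in zip(got, want):
            assert {ga, gb} == {wa, wb}
            assert gh == pytest.approx(wh, abs=1e-9)

    def test_upgma_heights_monotone_on_metric_input(self, rng):
        D = _random_metric_matrix(rng, 12)
        tree = linkage(D)
        assert np.all(np.diff(tree.merges[:, 2]) >= -1e-12)

    def test_invalid_input_rejected(self, rng):
        with pytest.raises(ValueError, match="symmetric"):
            linkage(np.array([[0, 1.0], [2.0, 0]]))
        with pytest.raises(ValueError, match="non-negative"):
            linkage(np.array([[0, -1.0], [-1.0, 0]]))
        with pytest.raises(ValueError, match="unknown linkage"):
            linkage(_random_metric_matrix(rng, 4), method="single")

    def test_ward_alternative_runs(self, rng):
        D = _random_metric_matrix(rng, 8)
        tree = linkage(D, method="ward")
        assert tree.method == "ward"
        assert tree.merges.shape == (7, 4)

    def test_newick_export_parses(self, rng):
        pytest.importorskip("dendropy")
        import dendropy

        D = _random_metric_matrix(rng, 5)
        tree = linkage(D)
        t = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert len(t.leaf_nodes()) == 5


class TestSilhouette:
    def test_perfectly_separated_scores_one(self):
        D = np.full((4, 4), 10.0)
        np.fill_diagonal(D, 0)
        D[0, 1] = D[1, 0] = 0.0
        D[2, 3] = D[3, 2] = 0.0
        assert silhouette_score(D, np.array([0, 0, 1, 1])) == pytest.approx(1.0)

    def test_all_equal_distances_score_zero(self):
        D = np.full((6, 6), 3.0)
        np.fill_diagonal(D, 0)
        assert silhouette_score(D, np.array([0, 0, 0, 1, 1, 1])) == pytest.approx(0.0)

    def test_matches_hand_rolled_oracle(self, rng):
        D = _random_metric_matrix(rng, 8)
        labels = rng.integers(0, 3, 8)
        while len(np.unique(labels)) < 2:
            labels = rng.integers(0, 3, 8)
        assert silhouette_score(D, labels) == pytest.approx(
            silhouette_by_hand(D, labels), abs=1e-12
        )

    def test_degenerate_k_rejected(self, rng):
        D = _random_metric_matrix(rng, 5)
        with pytest.raises(ValueError):
            silhouette_score(D, np.zeros(5, dtype=int))
        with pytest.raises(ValueError):
            silhouette_score(D, np.arange(5))

    def test_always_in_unit_interval(self, rng):
        for _ in range(5):
            D = _random_metric_matrix(rng, 7)
            labels = rng.integers(0, 3, 7)
            if len(np.unique(labels)) < 2:
                continue
            s = silhouette_score(D, labels)
            assert -1.0 <= s <= 1.0


class TestSelectK:
    def test_three_planted_groups_recovered(self, rng):
        centers = np.array([[0, 0], [50, 0], [0, 50.0]])
        pts = np.vstack([c + rng.normal(0, 0.5, size=(5, 2)) for c in centers])
        D = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        model = select_k(linkage(D), D)
        assert model.selected_k == 3
        assert sorted(model.cluster_sizes) == [5, 5, 5]

    def test_duplicated_behavior_co_clusters(self, rng):
        dup = random_resampled(rng, "base", n_frames=30)
        lib = [
            type(dup)(trial_id=f"dup{i}", frames=dup.frames + rng.normal(0, 1e-4, dup.frames.shape))
            for i in range(5)
        ]
        far = random_resampled(rng, "far", n_frames=30)
        lib.append(type(far)(trial_id="far1", frames=far.frames))
        lib.append(type(far)(trial_id="far2", frames=far.frames + 1e-4))
        D = distance_matrix(lib)
        model = select_k(linkage(D), D)
        labels = dict(zip(D.trial_ids, model.labels))
        assert len({labels[f"dup{i}"] for i in range(5)}) == 1

    def test_profile_recorded_over_full_range(self, rng):
        D = _random_metric_matrix(rng, 10)
        model = select_k(linkage(D), D)
        assert sorted(model.silhouette_by_k) == list(range(2, 10))
        assert model.selected_k == max(
            model.silhouette_by_k, key=lambda k: (model.silhouette_by_k[k], -k)
        )

    def test_empty_k_range_rejected(self, rng):
        D = _random_metric_matrix(rng, 5)
        with pytest.raises(ValueError, match="empty"):
            select_k(linkage(D), D, range(8, 4))


class TestAverageBehavior:
    def test_single_member_is_identity(self, rng):
        m = random_resampled(rng, "m", n_frames=40)
        ave = average_behavior([m])
        assert np.array_equal(ave.frames, m.frames)
        assert ave.n == 1

    def test_symmetric_pair_averages_to_midpoint(self, rng):
        mid = random_resampled(rng, "mid", n_frames=30)
        delta = np.random.default_rng(1).normal(size=mid.frames.shape)
        a = type(mid)(trial_id="a", frames=mid.frames + delta)
        b = type(mid)(trial_id="b", frames=mid.frames - delta)
        ave = average_behavior([a, b])
        assert np.abs(ave.frames - mid.frames).max() < 1e-12

    def test_matches_elementwise_loop_oracle(self, rng):
        members = [random_resampled(rng, f"m{i}", n_frames=8) for i in range(5)]
        ave = average_behavior(members)
        want = elementwise_mean([m.frames for m in members])
        assert np.abs(ave.frames - want).max() < 1e-12

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            average_behavior([])


class TestMDS:
    def test_triangle_embeds_exactly(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]])
        emb = mds_embed(D, seed=0)
        assert emb.stress < 1e-6

    def test_planar_configuration_recovered(self, rng):
        pts = rng.normal(size=(12, 2))
        D = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        emb = mds_embed(D, seed=0)
        assert procrustes_error(pts, emb.coordinates) < 1e-6

    def test_stress_non_increasing_within_a_restart(self):
        pts = np.random.default_rng(3).normal(size=(10, 3))
        D = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        stresses = []
        for it in (1, 2, 5, 10, 30, 100):
            _, s = smacof(
                D, n_components=2, n_init=1, random_state=5, max_iter=it,
                eps=0.0, normalized_stress=False,
            )
            stresses.append(s)
        assert all(b <= a + 1e-12 for a, b in zip(stresses, stresses[1:]))

    def test_gauge_is_deterministic(self, rng):
        D = _random_metric_matrix(rng, 9)
        a = mds_embed(D, seed=4)
        b = mds_embed(D, seed=4)
        assert np.array_equal(a.coordinates, b.coordinates)
        assert np.allclose(a.coordinates.mean(axis=0), 0, atol=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            mds_embed(np.zeros((2, 2)), seed=0)


class TestAnnotateMap:
    def test_reference_library_map_table(self):
        from standmap.object_frame import frame_from_scan, normalize_sequence
        from standmap.metrics import resample_sequence

        trials, meta = elderly_library(seed=1)
        rs = [
            resample_sequence(
                normalize_sequence(t.sequence, frame_from_scan(t.scan, t.sequence))
            )
            for t in trials
        ]
        D = distance_matrix(rs)
        emb = mds_embed(D, seed=1, n_restarts=2)
        table = annotate_map(emb, meta)
        assert len(table) == 24
        assert list(table.columns) == ["trial_id", "x", "y", "product", "BI", "MMSE"]
        assert set(table["BI"]) == {55, 80, 85}
        # the two planted forward-lean trials are mutual nearest in the map
        coords = table.set_index("trial_id")[["x", "y"]]
        lean = coords.loc[["no31_4", "no32_2"]].to_numpy()
        rest = coords.drop(["no31_4", "no32_2"]).to_numpy()
        d_pair = np.linalg.norm(lean[0] - lean[1])
        d_out = min(
            np.linalg.norm(lean[i] - r) for i in range(2) for r in rest
        )
        assert d_pair < d_out

    def test_missing_metadata_rejected(self, rng):
        D = _random_metric_matrix(rng, 4)
        emb = mds_embed(D, seed=0, n_restarts=1)
        meta = pd.DataFrame(
            {"trial_id": ["x"], "product": ["chair"], "BI": [50], "MMSE": [20]}
        )
        with pytest.raises(ValueError, match="missing trials"):
            annotate_map(emb, meta)
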