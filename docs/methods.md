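# Methods

## The analysis in one paragraph

Each sit-to-stand trial consists of a seat point cloud (surface patch,
backrest/side-frame patch, annotated armrest/handrail base point) and a
skeleton sequence of 13 joints, both in the camera frame of whatever depth
camera recorded it. The pipeline (1) builds a seat-anchored rigid frame
from the two plane fits and the anchor, (2) transforms the skeleton into
it, (3) resamples every trial to 500 frames with natural cubic splines,
(4) computes the summed per-joint Manhattan trajectory distance matrix,
(5) clusters it hierarchically (UPGMA) with the cluster count chosen by
mean silhouette, (6) averages each cluster's trajectories into a
representative motion, and (7) lays the trials out in 2-D by metric MDS
for inspection against seat type, Barthel Index and MMSE.

## Object-centered frame

* **Plane model.** `a·X + b·Y + c·Z + d = 0` with `c = 1` fixed, solved by
  ordinary least squares. This parameterization is singular for planes
  parallel to the camera z-axis; patches whose total-least-squares unit
  normal has `|n_z| < 0.1` are rejected with an explicit error rather than
  silently mis-fit. Collinear patches (rank-deficient design) are likewise
  rejected.
* **Basis.** `e_z = normalize([a, b, 1])` from the seat fit, `e_x′` the
  analogous backrest/side-frame normal, `e_y = normalize(e_z × e_x′)`,
  `e_x = e_y × e_z`. The plane normals `[a, b, 1]` are normalized to unit
  length before forming `R` — `R` must be orthonormal for the transform to
  be rigid — and the pre-normalization direction is retained on the frame
  object for audit.
* **Sign convention.** A plane fit leaves each normal's sign arbitrary.
  Using the trial's own skeleton: `e_z` is flipped so the temporal mean of
  the two shoulder joints lies on its positive side of the seat plane (up
  points from seat toward shoulders), and `e_x` (with `e_y`, preserving
  right-handedness) is flipped so the pelvis center's net first-to-last
  displacement has non-negative forward component. Both rules are
  deterministic and data-driven.
* **Transform.** `H = [[R, −R·P0], [0, 1]]` maps camera to object
  coordinates, with rows of `R` being `e_x, e_y, e_z` and `P0` the
  annotated anchor. (The alternative convention `[[R, P0], [0, 1]]` maps
  the other way; this package deliberately standardizes on camera→object,
  which is the direction the analysis needs.)
* **Anchor.** `P0` is an annotation carried in the seat sidecar file; the
  synthetic generator writes it, real-data users must supply it. No
  automatic anchor detection is attempted.

## Time normalization and distance

* Resampling uses natural cubic splines per coordinate channel over
  normalized time `u ∈ [0, 1]`, uniform in frame index (timestamps, when
  present, are used instead, rescaled to [0, 1]); output endpoints are
  pinned to the input endpoints. Sequences shorter than 4 frames are
  rejected, not padded.
* The per-frame difference `|J_Kt − J_Lt|` is the L1 norm over x, y, z
  (the Manhattan distance); a per-frame Euclidean alternative exists
  behind `distance_norm="euclidean_per_frame"` but is not the default.
  `D_sum = Σ_j D_j` holds exactly by construction and is verified to 1e-9
  in tests, along with symmetry, zero diagonal, the triangle inequality
  and scale equivariance.

## Clustering, selection, embedding

* UPGMA (average linkage) on the precomputed `D_sum` is the default;
  Ward's update is available (`linkage_method="ward"`) as a cross-check,
  with the caveat that Ward formally assumes squared Euclidean input.
  Agglomeration is delegated to scipy; under exact distance ties the merge
  order is scipy's deterministic internal order (ties never arise on the
  continuous data this pipeline consumes).
* Mean silhouette is scanned over `k = 2 .. min(12, n−1)`; ties select the
  smallest k. Singleton clusters contribute 0 to the mean. k = 1 and
  k = n are rejected as undefined/degenerate.
* Cluster averages are plain elementwise means of the members' resampled
  trajectories; a singleton cluster's average equals the member exactly.
* The 2-D embedding minimizes raw stress by SMACOF (scikit-learn), best of
  8 seeded restarts, `eps = 1e-12`, `max_iter = 1000`. The solution's
  translation/rotation/reflection gauge is fixed by centering, rotating to
  principal axes, and orienting each axis so its largest-magnitude
  coordinate is positive, so repeated runs are comparable. Raw stress is
  reported unnormalized; with trajectory distances summed over 500 frames
  and 13 joints its absolute magnitude is large and only relative
  comparisons are meaningful.

## Synthetic study conditions

The generator emulates the recording conditions the analysis was designed
for; values not fixed by the study design were chosen once as realistic
and are listed here.

* **Seats.** Canonical frame: floor `z = 0`, seat-surface center
  `(0, 0, h)`, x forward, y to the sitter's left. Dimensions
  (height/depth/width, m): chair 0.42/0.45/0.55, sofa 0.40/0.55/1.60,
  nursing bed 0.45/0.90/1.20. The armrest/handrail base (anchor) sits at
  the seat-surface edge, `y = width/2 + 0.03`. The backrest/side-frame
  patch is reclined 25° from vertical, as real backrests are; this keeps
  its plane representable under the `c = 1` parameterization for any
  camera tilt up to the generator's 10° bound.
* **Camera poses.** Free yaw, tilt uniform in [0°, 10°], offset a few
  meters — a ceiling-mounted camera viewing the seat obliquely from above.
* **Behaviors.** Three key poses (seated, transition at normalized time
  0.5, standing) per joint, interpolated by natural cubic splines.
  Archetype defaults: armrest-assisted — trunk pitch 0.30 rad, shoulder
  excursion 0.12 m, left hand to the armrest base, sitting 0.25 m inboard
  of the anchor; forward-lean — trunk pitch 0.80 rad, shoulder excursion
  0.30 m, hands to the knees, sitting at the seat center. These defaults
  make the archetypes separable at jitter sd 0.01 m.
* **Noise.** Isotropic Gaussian jitter (sd 0.01 m) on joints, drawn in the
  canonical seat frame *before* the camera pose is applied: isotropic
  noise is rotation-invariant, and this makes a fixed behavior seed
  reproduce the identical behavior under every camera pose, which is what
  the camera-pose-invariance tests quantify. Scan noise sd 0.005 m, 400
  points per patch, applied after the pose. The anchor annotation is
  transformed exactly.
* **Library.** The 24-trial roster (IDs, sex, BI, MMSE, seat type) is
  embedded verbatim: 6 participants; 5 nursing-bed, 8 chair, 11 sofa
  trials; BI ∈ {55, 80, 85}; MMSE ∈ {6, 15, 17, 19, 22, 24}. Trials
  `no31_4` and `no32_2` carry the forward-lean archetype. Durations are
  uniform in 60–150 frames (2–5 s at ~30 fps). All randomness derives
  from one integer seed; identical seeds give bit-identical libraries.

**What the generator does not emulate:** pose-estimation error structure
(correlated, occlusion-driven, occasionally catastrophic), missing joints,
within-archetype stylistic variation between people, non-planar or
cluttered seat geometry, and behavior segmentation. Passing tests
demonstrate that the pipeline recovers planted structure under idealized
noise, not that the two-cluster finding generalizes to new real data.

## Problem sizes used in tests and the acceptance script

The acceptance script runs the full 24-trial analysis at the study's
actual scale (n = 24, 500 frames, 13 joints) — it is small enough to run
in seconds. The test suite exercises recovery across 20 generator seeds,
pose invariance on 50 render pairs, and oracle equivalence on libraries of
n ≤ 8 with 20–60-frame trials, sizes at which the brute-force reference
implementations are instant.

## Known limitations

* The `c = 1` plane parameterization forbids near-vertical patches; scans
  from cameras mounted at seat height would be rejected.
* Silhouette-based selection inherits silhouette's bias toward compact,
  well-separated partitions; secondary maxima at large k on real data are
  expected and are not treated as reproducible structure.
* Raw-stress MDS has no unique optimum; restarts mitigate but do not
  eliminate local minima.
* Dynamic-time-warping distances and non-hierarchical clustering are out
  of scope for this version.
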