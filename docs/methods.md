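# Methods

This note records the models, conventions and numerical choices behind
`mothflight`, and what the synthetic scenes do and do not establish
about real recordings.

## Coordinate conventions and I/O

Point clouds live in the camera frame: origin at the stereo camera,
+Z depth away from the camera, +X right, +Y up, coordinates in metres.
"Distance from the camera" is the Euclidean norm of a centroid. The
PLY codec reads ascii and binary little-endian files whose vertex
element has scalar x/y/z properties and writes binary float32; frame
files embed consecutive integer indices in their names, and a gap is an
input error rather than a recoverable condition, because the tracker
treats discontinuity as a noise signature. Trajectory CSVs hold one row
per frame with centroid, point count, outline-box volume (OBV), speed,
turning angle, camera distance and point density, written at 12
significant digits so they round-trip losslessly well past the 9-digit
contract.

## Pipeline stages and their parameters

| parameter | default | meaning |
|---|---|---|
| `voxel_size_m` | 0.05 | background voxel edge |
| `n_training_frames` / `min_occupancy_frames` | 4 / 2 | frames examined / occupancy to call a voxel background |
| `link_dist_m` | 0.01 | single-linkage clustering gap (inclusive) |
| `min_pts` / `max_pts` | 20 / 900 | plausible moth point-count window (inclusive) |
| `gate_m` | 0.09 | frame-to-frame linking gate on centroid distance |
| `min_length_frames` | 10 | shortest trajectory kept |
| `window_frames` | 10 | classifier feature window |
| `max_angle_deg` | 110 | turning-angle cutoff (strict: noise occupies 110° < θ ≤ 180°) |
| `fence_k` | 1.5 | Tukey fence multiplier of the IQR screen |
| `frame_rate_fps` | 55 | stereo update rate (18 ms per update; 2 steps = 36 ms lead) |

Notes on ambiguous points, resolved here as package conventions:

* **Voxel grid.** Keys are `floor(coord / size)` per axis, anchored at
  the camera origin; cells are half-open so boundary points belong to
  the higher-index voxel, and negative coordinates use the true floor.
  Documentation of the recording system gives the voxel size as 5 cm in
  one place and 2.5 cm in another; 5 cm is the default and the value is
  configurable.
* **Clustering.** "Closest point within 1 cm" is read as single
  linkage (chained proximity), with the boundary inclusive. The KD-tree
  implementation is contractually identical to brute-force connected
  components on the pairwise distance graph, and is tested against an
  independent dense-matrix oracle.
* **Linking conflicts.** Each object proposes only its nearest
  successor; proposals are granted in ascending distance (ties by lower
  object index), and losers simply terminate. No gap bridging: a single
  missed frame ends a trajectory. The gate applies to centroid
  distance, consistent with the centroid being "the position" of an
  object.
* **Prediction.** The two-step-ahead prediction is a constant-velocity
  extrapolation from the last two centroids. The lead time is an
  arithmetic consequence of the update rate (2 × 1000/55 ≈ 36 ms); the
  predictor form is isolated behind `predict_position` so alternatives
  can be swapped.
* **Turning-angle indexing.** The angle "at frame t" is computed
  backward from c_{t−2}, c_{t−1}, c_t, so a trajectory's first two
  frames have no angle. This matches the real-time view (at frame t
  only past centroids exist) and the CSV contract; the multiset of
  angles is identical to the symmetric convention. Zero-length
  displacements contribute a 0° angle by convention.
* **Classifier features.** "SD of positions" over the window is the
  scalar spatial SD (RMS distance from the window mean); a
  per-axis-SD-norm variant is available via `position_sd_mode` for
  sensitivity checks. Angles are in degrees. Classification is applied
  once per trajectory on its final window by default; a sliding mode
  labels a trajectory noise if any window does.
* **Decision rule.** Features are standardised by training means/SDs;
  the model is a primal linear SVM (deterministic refits) serialised as
  a five-number JSON record; a decision value of exactly 0 is noise.
* **OBV.** Axis-aligned bounding box in camera coordinates (the
  orientation of the original "outline box" is unstated). Volumes
  ≤ 1e−12 m³ count as zero.
* **IQR screen.** "Outliers in the interquartile range" is implemented
  as Tukey fences at `fence_k` × IQR on metrics pooled over all frames
  of currently kept trajectories — one-sided (high) for turning angle,
  two-sided for OBV. Flagged trajectories are confirmed by an automated
  proxy replacing visual animation review: net displacement < 5 cm over
  the lifetime, or any frame discontinuity. Confirmed trajectories are
  removed and fences recomputed until a fixed point (bounded by
  `max_iterations`). Quartiles use linear interpolation
  (`numpy.percentile`). With fewer than 4 trajectories the screen is a
  no-op. A `trim` mode instead crops flagged frames off trajectory
  ends, for recordings where noise brackets a genuine flight segment.
* **Statistics.** Pooled per-frame speed statistics are the primary
  summary; per-trajectory mean speeds are also reported because "mean
  flight speed" can be read either way. Speed SD uses ddof = 1.
* **Training frames downstream.** The four training frames are also
  background-filtered, but detection and tracking start at frame 4 by
  default (`tracking_start_frame`), since the background model assumes
  those frames show the static scene.

## The scene simulator

The simulator replaces unavailable recordings and defines the test
conditions; its defaults are the recording conditions where these are
known, and stated assumptions elsewhere.

* **Geometry.** Arena 1.8 m (W) × 1.8 m (H) × 3.5 m (D), camera at the
  centre of one short side; field of view 47.2° × 36.3°, 55 fps; points
  outside the viewing frustum are dropped (near plane 0.3 m).
* **Background.** Wall points (side walls, floor, ceiling, back wall)
  at 1200 points/m², fixed positions 1–4 mm proud of the wall plane
  (net roughness) with ±0.5 mm per-frame jitter — an order of magnitude
  below the voxel size, so the background is static up to jitter. Base
  points are frustum-clipped once with a jitter-sized margin so the
  per-frame point count is constant.
* **Moth flight.** Heading follows a damped random walk (isotropic
  Gaussian perturbation, σ = 0.12 per frame ≈ 8–10° typical turn) with
  the per-frame turn capped at 40°, steered smoothly back toward the
  flight volume within 0.3 m of its boundary; per-step speeds are
  N(1.8, 0.3²) m/s, floored at 10% of the mean. The body is an
  isotropic Gaussian blob (σ = 2 cm) of 60–400 points, contracted if
  necessary so it is always one cluster at the 1 cm link distance.
  Moths enter the field of view at frame 4 by default
  (`moth_entry_frame`), emulating release around recording start; a
  moth visible during the background-training frames would imprint
  mid-air background voxels, which the background model (by its own
  assumption) does not anticipate. With `separate_moths`, each moth is
  confined to a disjoint sub-volume with ≥ 0.25 m buffer, guaranteeing
  pairwise separation above the tracking gate.
* **Noise.** Two morphologies. *Transient blobs* live 1–60 frames,
  oscillating around a fixed base along a random axis (amplitude 1–3 cm
  plus 3 mm jitter): net displacement stays below 5 cm and consecutive
  displacements nearly reverse, concentrating turning angles in
  110°–180°. *Coplanar artifacts* have every point at exactly one depth
  (zero z-extent, hence OBV exactly 0) near the 0.9 m minimum effective
  range, with in-plane reciprocating motion; their lifetime is drawn
  from 10–60 frames so they survive the 10-frame length filter and
  actually exercise the OBV stage (no lifetime is documented for the
  real artifacts).
* **Classifier training data.** The moth/noise model is fitted on
  centroid paths drawn from these same flight and transient-noise
  models (200 per class by default), with 1.5 mm Gaussian centroid
  noise on moth paths to mimic blob-averaging error. No trained weights
  exist for the original system, so this synthetic fit is the package's
  operating classifier.

**What the simulator does not model:** stereo disparity quantisation,
photometric effects, wing-beat articulation of the blob, occlusion
between moths, UV-attraction behaviour, and mixed moth+noise point
clouds within a single frame. Passing tests therefore establish the
pipeline's correctness and internal consistency under the documented
scene statistics — not that the classifier or the filters would achieve
the same rates on real recordings, whose noise morphology is only
qualitatively emulated. In particular the headline field measurements
(68 trajectories; 1.81 ± 0.68 m/s mean, 1.75 m/s median free-flight
speed) come from unreleased recordings and are inputs for comparison
(see `mothflight.literature`), not quantities this package re-derives.

## Problem sizes used in tests and the acceptance script

Simulated scenes of 40–120 frames with 0–2 moths and 0–6 noise events;
clustering oracle checks on random frames up to 2000 points; classifier
evaluation on 200 + 200 held-out trajectories; speed-recovery bias over
12–20 replicate scenes (~1100+ pooled speed steps); tracking identity
switches over 10–20 two-moth scenes. These sizes give stable statistics
(e.g. the recovery bias estimate is an order of magnitude below its 2%
tolerance) while keeping a full run to tens of seconds.

## Known limitations

* The background model is fixed after the first four frames; slow
  scene drift is not handled (matching the recording system).
* Two moths within 1 cm merge into one cluster and within 9 cm can
  swap identities; the method has no appearance model.
* The IQR screen's fixed point depends on the cohort; with heavy
  contamination (> ~25% outlier trajectories) Tukey fences lose power.
* `LinearSVC` with the primal solver makes refits exactly
  deterministic, but retraining with different class balance shifts the
  boundary; the shipped default is 1:1.
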