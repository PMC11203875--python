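# mothflight

Noise-reduced 3D point-cloud tracking and flight kinematics of the
free-flying cotton leafworm moth, *Spodoptera litura*.

`mothflight` is for researchers measuring insect flight under low-light
conditions with a stereo camera: each video frame is reduced to a 3D
point cloud (metres, camera frame), and the task is to recover the
moth's flight trajectory and speed from clouds dominated by static
background and stereo-matching artifacts. The motivating application is
laser-based pest control, where the system must also predict the moth's
position a couple of frames ahead to compensate for processing latency.

## The pipeline

Given a sequence of per-frame point clouds at 55 fps:

1. **Background model** — space is discretised into 5 cm cubic voxels;
   a voxel occupied in ≥ 2 of the first 4 frames is background, and all
   points in background voxels are removed from subsequent frames.
2. **Object detection** — residual points are grouped by single-linkage
   Euclidean clustering (chained gaps ≤ 1 cm); clusters with fewer than
   20 or more than 900 points are discarded as non-moth.
3. **Tracking** — each object's centroid (mean of member points) is
   linked to its nearest successor in the next frame if within 9 cm;
   trajectories shorter than 10 frames are dropped. A constant-velocity
   extrapolation two frames ahead (36 ms at the 18 ms update interval)
   provides the aiming prediction.
4. **Classification** — a linear SVM labels each candidate moth or
   noise from two features of the last 10 frames: the spatial SD of the
   centroid positions and the SD of the turning angles θ between
   consecutive displacement vectors.
5. **OBV filter** — trajectories containing a frame whose axis-aligned
   outline-box volume is zero (all points coplanar, a stereo artifact
   near the camera's ~0.9 m minimum effective range) are removed.
6. **Turning-angle filter and IQR screen** — trajectories with any turn
   θ > 110° are removed (noise reciprocates in 110° < θ ≤ 180°), and an
   iterative Tukey-fence screen on pooled outline-box volume and
   turning angle removes remaining outlier trajectories confirmed by an
   automated low-movement/discontinuity proxy.

Per-frame speed is ‖c_t − c_{t−1}‖ · fps from the surviving centroids;
the package reports pooled and per-trajectory descriptive statistics.

The original recordings are not public, so the package ships a
simulator (`mothflight.simulate`) that renders labelled scenes with the
recording geometry — a 1.8 × 1.8 × 3.5 m arena viewed through a
47.2° × 36.3° field of view — including wall background, smooth moth
flights and both noise morphologies. Every stage is tested against this
ground truth.

## Worked example

```python
from mothflight import PipelineConfig, SceneConfig, process_sequence, simulate_scene

scene = SceneConfig(n_frames=100, n_moths=1, n_noise_events=4, rng_seed=3)
sequence, truth = simulate_scene(scene)
kept, report = process_sequence(sequence, PipelineConfig(seed=0))
print(report["final"]["n_trajectories"])
print(report["final"]["stats"]["speed_mean_mps"])
print(truth.all_moth_speeds(55.0).mean())
```

prints

```
1
1.824977109903823
1.8153310471503683
```

— the scene contained one moth plus four noise events, exactly one
denoised trajectory survives, and its pooled per-step speed (1.825 m/s)
recovers the ground-truth flight speed (1.815 m/s) to within 0.6%.
The full stage-by-stage bookkeeping (points removed by the background
model, clusters passing the size gate, trajectories removed per filter)
is in `report["steps"]`; `examples/` contains narrative scripts for the
simulator, the pipeline, the classifier and the speed statistics.

A thin CLI wraps the same stages:

```bash
mothflight simulate --seed 42 --out scene/
mothflight run scene/frames --out results/
mothflight stats results/ --out stats/
```

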