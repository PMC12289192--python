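# fintrack

Single-animal video analysis for behavioural assays in obstacle arenas.

`fintrack` turns the sparse output of any bounding-box object detector into
a complete, frame-by-frame account of what one animal did in an overhead
video: where it was, how fast it moved, which way it was heading, and —
for arenas containing discrete obstacles — which gaps ("virtual gates")
between obstacles or between an obstacle and the tank wall it chose to swim
through. It was built for experiments in which a fish navigates a
pseudo-random field of cylindrical obstacles toward a food target, but every
stage is generic: the detector is consumed through a plain CSV interface and
the geometry needs only one 8-point manual calibration per camera setup.

## What it computes

**Detect+Track gap filling.** A detector localizes the animal with high
confidence (> 0.7) in only a fraction of frames. Each maximal run of frames
without a high-confidence detection (a *missing segment*) is flanked by
anchor detections; a zero-normalized cross-correlation template tracker runs
forward from the anchor before the segment and backward from the anchor
after it, each to the segment midpoint. The output track has a bounding box
in **every** frame for any dropout pattern with at least one anchor.

**Virtual gates.** Obstacle centers seed a Voronoi tessellation; obstacles
whose cells share an edge of positive length form an *obstacle gate* with
gap length `|c_i − c_j| − r_i − r_j`. Obstacles with unbounded cells sit
near the wall: the tank-floor corners P1–P4 are mapped into the plane of
the obstacle tops by the parallel-plane homology

```
x' = vp + (x − vp) / (1 + μ)
```

where `vp` is the vertical vanishing point (intersection of the images of
two vertical obstacle edges, P5P6 and P7P8) and μ follows from one
ground/top point pair. Dropping a wall obstacle's center perpendicularly
onto each projected tank edge its cell touches yields *imaginary obstacles*
and hence *boundary gates*.

**Optical-flow motion.** Between consecutive frames, dense optical flow
inside the tracked box segments the moving body: pixels with flow magnitude
`s(x,y) = √(fx² + fy²) ≥ t` (default `t = 0.1` px/frame) form a mask whose
mean position is the body centroid `(cx, cy)` and whose mean flow vector
`v` gives motion direction and speed `‖v‖ · fps` (px/s). The masked-flow
centroid stays on the body even when it bends into a C-shape, unlike the
box center.

**Events and evaluation.** Centroid-trajectory segments crossing a gate
segment produce time-stamped crossing events; visited Voronoi cells are
logged in first-visit order. Tracks are scored with normalized PCK
(distance / √(bbox area)), detection failure rate, and per-frame bbox IoU.

A fully ground-truthed synthetic arena generator (`fintrack.synthfish`)
renders overhead trials — perspective-consistent obstacle layout, a
deformable textured fish, surface-ripple intensity noise, detector dropout
and bbox jitter — so the whole pipeline is testable without any recordings.

## Worked example

```bash
fintrack simulate --out trial0 --seed 5 --n-frames 200 --dropout 0.6
fintrack analyze  --trial trial0 --out trial0/results.json
fintrack evaluate --pred trial0/results.json --gt trial0/ground_truth.json \
                  --out trial0/metrics.json
```

The `evaluate` step prints:

```
PCK@0.3=1.000 IoU>0.5 fraction=1.000 missed=0
```

meaning: every flow-estimated centroid lies within 0.3 characteristic
lengths (≈ 10 px for this fish size) of the true body centroid, every
tracked box overlaps the true box with IoU > 0.5, and no frame is left
without a detection even though 60% of frames had no high-confidence
detector output. `trial0/results.json` holds the full per-frame record
(bbox, source, centroid, motion vector, speed in px/s), the gate layout
with pixel lengths, and the ordered crossing events with times.

The same pipeline is scriptable from Python:

```python
import fintrack

cfg = fintrack.SceneConfig(n_frames=200, dropout_p=0.6)
trial = fintrack.generate_trial(cfg, seed=5)
doc = fintrack.run_pipeline(trial.frames, trial.detections,
                            trial.scene.obstacles, trial.scene.calibration)
print([c["gate_id"] for c in doc.crossings])   # gates crossed, in order
```

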