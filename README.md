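# otassess

Multisensor upper-limb assessment toolkit for occupational-therapy (OT)
exercises. It implements the full analysis chain for a two-sensor,
three-signal rehabilitation protocol:

- **Kinematic fusion** (`otassess.fusion`) — timestamp synchronization of a
  low-rate depth-camera joint stream and a high-rate IMU-derived position
  stream, followed by a per-axis scalar Kalman fusion. Two modes: the
  `standard` inverse-variance recursion (guaranteed error reduction) and a
  `literal` transcription of the published pseudocode, kept for audit.
- **Completion scoring** (`otassess.completion`) — dynamic-time-warping
  alignment of a patient trajectory against healthy references, per-axis
  Pearson correlation, and the ordinal 0–3 completion rubric
  (r ≥ 0.8 → 3, 0.5–0.8 → 2, 0.3–0.5 → 1, < 0.3 → 0), plus the
  correlation of completion scores with Lovett muscle-strength grades.
- **sEMG processing** (`otassess.emg`) — zero-phase band-pass/notch
  filtering, the integrated-EMG envelope (windowed mean absolute value),
  automatic burst segmentation via a recursive min-value × length interval
  search, and fixed-length (200×3) segment extraction.
- **Action classification** (`otassess.classifier`) — a four-branch 1-D CNN
  (conv kernels 20/16/12/8, two conv-pool stages per branch, 1728 fused
  features, two fully connected layers with dropout, 4 outputs) implemented
  in pure numpy with hand-written backprop, plus stratified splitting,
  training, and confusion-matrix evaluation.
- **Synthetic cohorts** (`otassess.synthetic`) — parametric templates of the
  four OT actions, severity profiles keyed to Lovett grades, per-sensor
  noise models, burst-modulated three-channel sEMG with ground-truth
  intervals, and whole-cohort generation/serialization.
- **Orchestration** (`otassess.pipeline`, `otassess.cli`) — session config,
  per-recording reports, cohort batch reports, and a `click` CLI.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes brute-force oracles (exhaustive DTW path enumeration,
O(n²) min×length interval search, finite-difference gradient checks) and an
acceptance suite (`tests/test_acceptance.py`); the end-to-end classification
test trains the CNN on a 9-participant synthetic cohort and takes a couple
of minutes on one CPU.

## CLI

```sh
otassess simulate --participants 9 --grades 3,3,3,5,4,4,4,3,4 --reps 15 --seed 0 --out cohort/
otassess fuse --kinect k.csv --imu i.csv --rate 30 --mode standard --out fused.csv
otassess assess --patient fused.csv --refs refs/ --action 2 --out report.csv
otassess segment --emg rec.csv --window-ms 100 --out segs/
otassess train --cohort cohort/ --epochs 40 --seed 42 --out model.npz
otassess classify --model model.npz --segment segs/segment_000.csv
otassess report --cohort cohort/ --out table.csv
```

File formats are plain CSV: trajectories as `timestamp_s,x_m,y_m,z_m`,
sEMG as `timestamp_s,ch1,ch2,ch3`; cohorts carry a `manifest.csv` and a
`ground_truth.json` of burst intervals.

## Notes on the published architecture

The printed per-layer map sizes are reproduced exactly except for the
second pooling stage: no assignment of the nominal windows (5, 4, 3, 2)
yields the printed output lengths (2, 2, 2, 3) from the printed
second-convolution maps (14, 13, 12, 12) under non-overlapping pooling.
The shipped default derives the windows (7, 6, 6, 4) from the printed
output lengths — on which the 1728-feature total depends — and
`compute_feature_shapes` reports the inconsistency in its
`discrepancies` field instead of hiding it.
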