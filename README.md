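# flarekit

Quantitative analysis of turn-taking aggressive displays in paired fish
(and fish-vs-animation encounters) from pose-tracking keypoints:

- **kinematics** — keypoint cleaning (confidence threshold 0.8, 15-px jump
  rule, linear interpolation), contour tail geometry, per-frame behavioral
  features (orientation, speed, turning angle, operculum angles, elevation,
  ...), 11-frame median smoothing (0.275 s at 40 fps).
- **dtcn** — a dilated temporal convolutional network (two dilation blocks,
  kernel 9, 32 channels, dropout 0.1, residual skips, dense + softmax head)
  classifying each frame as none / partial / full flaring, trained with
  class-weighted (N/N_i) cross-entropy, Adam at 1e-4, 1,000-frame sequence
  chunking with a 90/10 split and patience-20 early stopping. Implemented
  directly on NumPy (explicit forward/backward), no deep-learning runtime
  required.
- **synchrony** — loop folding of a flaring series against a repeating
  stimulus (default 37-s loop), the frequency-profile variance statistic,
  and the circular-shift resampling test (1,000 iterations, 95th-percentile
  threshold).
- **dynamics** — point-biserial flare-feature correlations with coflaring
  filtering and shuffle controls, isolated-bout peri-event time histograms
  (±3 s), min-max elevation normalization, and engagement-decay persistence
  curves (8-s bins, exponential fit, ¾/½-of-max crossing times).
- **transitions** — 8 per-fish behavioral states (2 flaring × 4 orientation
  bands), 64 dyadic states, embedded-jump-chain transition matrices with
  occupancy (≥2%) and edge-probability (≥0.0025) filters, two-eigenvector
  spectral layouts, and per-state dwell-time exponentiality checks.
- **simulate** — a synthetic dyad generator (coupled semi-Markov agents with
  hazard-modulated turn taking, exponential dwells, engagement decay,
  elevation coupling) and an animation-response generator with tunable
  phase-lock strength, plus a geometric keypoint renderer, so the entire
  pipeline is testable end to end without recordings.
- **pipeline / cli** — orchestration with one master seed, documented
  splitmix sub-seeding, config hashing, and CSV/JSON I/O.

## CLI

```bash
flarekit simulate --mode dyad --seed 7 --out sim/        # keypoints + labels
flarekit features --keypoints sim/agent0_keypoints.csv --out feats.csv
flarekit train --features f0.csv --labels l0.csv --features f1.csv \
               --labels l1.csv --out model
flarekit predict --model model --features feats.csv --out ethogram.csv
flarekit sync --ethogram ethogram.csv --loop-length 37 --fps 40 \
              --iters 1000 --seed 7 --out sync.json
flarekit correlate --ethogram e.csv --features feats.csv --out corr.csv
flarekit peth --ethogram e.csv --features feats.csv --channel elevation \
              --out peth.csv
flarekit persist --ethogram e.csv --out persist.json
flarekit transitions --states states.csv --out graph/
flarekit report --n-fish 21 --lock-strength 0.5 --seed 7 --out report/
```

`--config file.yaml` supplies any simulator or pipeline parameters; CLI
flags take precedence.

## Conventions

Image coordinates (origin top-left, y down); frame rate is an explicit
parameter everywhere (default 40 fps); flaring labels are 0 = none,
1 = partial, 2 = full, and "binary flaring" means label ≠ 0. Orientation is
the unsigned angle in [0°, 180°] between the body axis (centroid → nose)
and the stimulus normal. All randomness flows from explicit seeds; identical
config + seed reproduces outputs bit for bit.
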