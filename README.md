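# vasclite

Lightweight EfficientNet variants for binary classification of vascular
network images (normal = connected branching vasculature, abnormal =
fragmented/sparse vessels), together with the full experimental
apparatus around them:

- **`vasclite.models`** — EfficientNet-B0/B1/B2 built from scratch on a
  NumPy backend, plus three lightweight variants: `modified1`
  (SiLU→ReLU), `modified2` (SE blocks replaced by identity `DummySE`),
  `modified3` (both). Exact trainable-parameter, activation-site and
  serialized-size accounting (B0: 4.0 M → 3.4 M, 49 → 33 activation
  sites when SE is removed).
- **`vasclite.nn`** — the minimal layer/optimizer core (conv, depthwise
  conv, batch norm, SE gating, AdamW, cross-entropy) with manual
  forward/backward passes. No deep-learning framework is required.
- **`vasclite.mi_analysis`** — per-stage mutual information between
  pooled feature maps (tapped before vs after SE gating) and class
  labels, using the k-nearest-neighbour MI estimator.
- **`vasclite.pipeline`** — multichannel-TIFF vessel-channel extraction,
  preprocessing to 3×224×224 tensors in [−1, 1], the 10-transform
  augmentation plan (flips, rotations 15/30/60/90/180/270°, +5 %/+10 %
  zooms) applied only to normal training images, Gaussian-noise
  expansion (σ ~ U[0.02, 0.06]), and split/manifest bookkeeping.
- **`vasclite.phantom`** — synthetic fluorescence vasculature generator
  (connected branching networks vs fragmented ones) so every stage is
  testable without proprietary data.
- **`vasclite.training`** — AdamW + cosine-annealing training loop
  (50 epochs, lr 1e-4, batch 32, dropout 0.2 by default), fully seeded.
- **`vasclite.evaluation`** — confusion-matrix metrics (accuracy,
  per-class precision/recall/F1), penultimate-layer embedding export,
  t-SNE projection, and a single-image CPU latency/FPS benchmark.

## CLI

```bash
vasclite inspect-model --base B0 --variant modified3 --out runs/inspect
vasclite simulate-data --n-normal 169 --n-abnormal 973 --seed 1 --out runs/raw
vasclite prepare-data  --data runs/raw --seed 1 --out runs/prep
vasclite train    --data runs/prep/dataset.npz --variant modified3 \
                  --epochs 50 --out runs/train
vasclite evaluate --checkpoint runs/train/checkpoint.npz \
                  --data runs/prep/dataset.npz --tsne --out runs/eval
vasclite mi-analysis --data runs/prep/dataset.npz --base B0 --out runs/mi
vasclite benchmark --base B0 --variant modified3 --out runs/bench
```

Each command writes fixed-name artifacts (`params.json`,
`manifest.csv`, `training_log.csv`, `metrics.json`, `mi_report.csv`,
`latency.json`) plus a resolved-config snapshot and a log file into the
run directory. Exit codes: 0 success, 2 config error, 3 data error,
4 runtime failure.

## Notes

- Everything is NumPy: training the B0 variant end-to-end is feasible
  at reduced input resolution (the test suite uses 64×64); 224×224
  single-image inference runs at seconds-per-image rather than the
  millisecond latencies of a compiled framework, so the benchmark
  protocol (warm-up + timed batch-1 passes, FPS = 1000/latency) is the
  reproducible part, not the absolute timings.
- Checkpoints are `.npz` weight maps with a JSON sidecar recording
  base, variant, class count, seed and parameter count.
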