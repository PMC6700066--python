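# semsr

Resolution enhancement for scanning electron microscopy (SEM) images, built
as a reusable toolkit:

- **synthesis** (`semsr.synth`) — gold-on-carbon-like test specimens
  (particles 5–150 nm in diameter, planted near-pairs with known gaps) and a
  forward model of the low-magnification acquisition: beam-PSF blur, plain
  aliasing decimation (7.1 nm/px → 14.2 nm/px), per-pixel noise, automatic
  contrast, and smooth beam-damage warps;
- **co-registration** (`semsr.registration`) — Lanczos upsampling,
  correlation-driven affine alignment, and coarse-to-fine block-matching
  elastic registration producing dense sub-pixel displacement fields;
- **patch preparation** (`semsr.patches`) — per-image mean/std
  normalisation, tiling, correlation-based filtering of damage-corrupted
  pairs, dihedral augmentation;
- **adversarial super-resolution** (`semsr.gan`) — a residual U-Net
  generator and VGG-style discriminator trained with
  `L1 + α·TV + β·(1 − D(G(x)))²` against `D(G(x))² + (1 − D(z))²`, the
  discriminator stepping every fourth iteration, plus tiled full-image
  inference. The networks run on a small, gradient-checked numpy layer
  library (`semsr.nn`) — no deep-learning framework required;
- **evaluation** (`semsr.evaluation`) — particle-gap resolvability (a gap
  exists when the valley falls below 60% of the flanking peak; width between
  the 80% crossings) and radially-averaged power spectra;
- **CLI** (`semsr.cli`) — a resumable, seeded, YAML-configured pipeline.

## CLI

```bash
semsr run-all --config examples/pipeline.yaml          # simulate → … → evaluate
semsr simulate --config examples/pipeline.yaml         # individual stages
semsr train    --config examples/pipeline.yaml --force
semsr enhance-image low.tif --model out/train/generator.npz --out enhanced.tif
semsr register-affine moving.tif fixed.tif --out affine.json
semsr register-elastic moving.tif fixed.tif --levels 3 --min-block 24
```

Each stage writes outputs plus a JSON report (resolved config, digest,
metrics, wall time) under `out_dir/reports/`; re-runs skip stages whose
digests match unless `--force` is given. One global `seed` fans out to
per-stage seeds.

A minimal configuration (`examples/pipeline.yaml`):

```yaml
seed: 1
out_dir: semsr_out
simulate: {n_train_fields: 8, n_test_fields: 4}
train: {iterations: 600}
```

Unknown keys are rejected by the schema.

## Library example

```python
from semsr.pipeline import SimulationParams, simulate_pair, run_experiment

pair = simulate_pair(SimulationParams(), seed=7)     # co-acquired GT/LR images
result = run_experiment(seed=1)                      # full desk-scale study
print(result.gap_metrics["output"]["undetected_fraction"])
```
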