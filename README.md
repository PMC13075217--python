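# kandescod

A conditional denoising-diffusion (DDPM) model for single-lead ECG segments
in which the noise-level conditioning layers are Kolmogorov–Arnold (B-spline)
transforms, with a dedicated sparsity + entropy regularizer on the spline
weights.  Everything runs on CPU in NumPy: the package ships its own small
reverse-mode autodiff engine (`kandescod._autograd`), so no deep-learning
framework is required.

## Layout

| module                    | purpose |
|---------------------------|---------|
| `kandescod.splines`       | uniform B-spline grids, Cox–de Boor basis evaluation |
| `kandescod.conditioning`  | sin/cos noise-level encoding; linear and spline ("KAN") affine layers; feature-wise modulation |
| `kandescod.backbone`      | multi-scale residual 1-D conv denoiser with conditioning Bridges (linear/kan switchable); checkpoints |
| `kandescod.diffusion`     | quadratic beta schedule, forward diffusion, reverse sampler, multi-shot averaging |
| `kandescod.objective`     | L1 noise loss + spline-weight sparsity/entropy regularizer |
| `kandescod.metrics`       | SSD / MAD / PRD / CosSim / timing; noise-level stratified reports |
| `kandescod.synthgen`      | synthetic PQRST beats, three clinical noise classes, amplitude-controlled mixing, record-disjoint splits, CSV/NPZ IO |
| `kandescod.train`         | Adam training loop with step LR decay, validation monitoring, resumable state |
| `kandescod.cli`           | `simulate | train | denoise | evaluate` commands |

## CLI

All hyperparameters live in a YAML config (defaults: grid size 5, spline
order 3, SiLU base activation, grid range [-1, 1], T = 50 quadratic schedule
on [1e-4, 0.5], hidden width 80, 200 epochs, batch 96, Adam 1e-3 with x0.1
decay at epoch 150, lambda_kan = 0.001).  Any key can be overridden with
`--set key=value`.

```bash
kandescod simulate --config config.yaml                 # write synthetic dataset (CSV + manifest)
kandescod train    --config config.yaml                 # train; saves runs/checkpoint.npz
kandescod denoise  --config config.yaml --checkpoint runs/checkpoint.npz
kandescod evaluate --config config.yaml                 # stratified metric reports (CSV)
```

A CPU-scale smoke profile is available through overrides, e.g.
`--set hidden_features=16 --set diffusion_steps=10 --set max_steps=300`.

Every command writes a JSON manifest (config hash, seed, file checksums,
library versions) into its output directory; runs are bit-reproducible at
fixed seed and software versions.

## Checkpoint format

A single `.npz` archive with one array per parameter (`param/<name>`) and a
JSON header (`__header__`) holding the network configuration.
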