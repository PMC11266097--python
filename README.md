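# morphgen

Two-stage generative modelling of 3D brain-like volumes, desk-scale and
dependency-light:

1. **VQ-VAE** — 3D conv encoder, vector quantizer with an
   exponential-moving-average (EMA) codebook, 3D conv decoder, and a
   composite loss (pixel MSE + Fourier-amplitude MSE + slice-wise perceptual
   distance + least-squares PatchGAN adversarial terms, plus the
   commitment loss).
2. **Autoregressive transformer** — causal transformer over the raster-ordered
   token grid with a 3D relative positional bias, RMS normalization, gated
   attention blocks, cross-attention conditioning on covariates
   (sex, age, ventricular volume, brain size, pathology) and augmentation
   parameters, optional "enhanced recurrence" at sampling time, and plain
   ancestral sampling.

Because the MRI corpora such models are usually trained on are
access-controlled, the package ships a **phantom generator**: nested-ellipsoid
volumes whose region volumes (brain, cortical shell, ventricles, focal
lesion) are analytic functions of the covariates. That makes conditioning
recovery and morphology statistics testable end-to-end offline.

An **evaluation** module implements the fidelity metrics (FID, MMD, MS-SSIM,
4-G-SSIM with pluggable feature extractors) and morphology-preservation
statistics (Wasserstein-1, Gaussian-moment KL, tie-corrected Mann–Whitney U,
Glass's Δ, |Z|-threshold failure rate, conditioning-recovery Pearson r, and a
voxelwise Welch t-map).

All neural components run on a small in-repo reverse-mode autodiff engine
over numpy (`morphgen.autodiff`, `morphgen.nn`) — no deep-learning framework
required. Full-scale reference hyperparameters are the config defaults
(`VQVAEConfig()`, `SeqModelConfig()`); `*.desk()` profiles shrink shapes for
single-CPU experiments.

## CLI

```bash
# 1. generate a phantom dataset (NIfTI + covariate TSV)
morphgen make-data --config config.yaml --out runs/data --n 200

# 2. train the VQ-VAE
morphgen train-vqvae --config config.yaml --data runs/data --out runs/vq

# 3. train the transformer on tokens computed on the fly
morphgen train-transformer --config config.yaml --data runs/data \
    --vqvae runs/vq/vqvae.npz --out runs/tr

# 4. sample conditionally
morphgen sample --config config.yaml --vqvae runs/vq/vqvae.npz \
    --transformer runs/tr/transformer.npz --n 50 --seed 1 --out runs/synth

# 5. evaluate synthetic vs real
morphgen evaluate --config config.yaml --real runs/data --synth runs/synth \
    --out runs/eval
```

The config is a single YAML file (see `morphgen/config.py` for the defaults
and keys); every artifact directory receives the exact config, its hash, and
a checksum manifest, so reruns with the same config and seed reproduce
outputs bit-for-bit.

## Layout

```
src/morphgen/
  autodiff.py      reverse-mode autodiff engine (numpy, float64)
  nn.py            conv3d / transposed conv / linear / embedding / norms
  phantoms/        covariate sampling, rendering, measurement, augment, I/O
  vqvae/           quantizer (EMA codebook), encoder/decoder/discriminator,
                   composite losses, training loop, checkpoints
  seq_model/       rasterization, attention + 3D relative bias + gates,
                   conditioning embedder, transformer, sampling, training
  evaluation/      MMD / FID / MS-SSIM / 4-G-SSIM, region statistics,
                   failure rate, conditioning recovery, voxelwise t-map
  cli.py           typer CLI (make-data / train-* / sample / evaluate)
  config.py        YAML run configuration
```
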