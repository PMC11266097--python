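"""Composite VQ-VAE loss: pixel MSE, Fourier-amplitude MSE, slice-wise
perceptual distance, and least-squares adversarial terms.

Total objective:

    L = L_quant + a_pix * L_pix + a_freq * L_freq + a_pcp * L_pcp + a_dis * L_adv

with default weights (1, 1, 0.001, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..autodiff import Tensor

__all__ = [
    "LossWeights",
    "loss_pix",
    "loss_freq",
    "loss_pcp",
    "discriminator_loss",
    "generator_adv_loss",
    "total_vqvae_loss",
    "mse_slice_extractor",
    "fft_amplitude",
]


@dataclass(frozen=True)
class LossWeights:
    alpha_pix: float = 1.0
    alpha_freq: float = 1.0
    alpha_pcp: float = 0.001
    alpha_dis: float = 1.0

    def __post_init__(self):
        for name, v in vars(self).items():
            if v < 0:
                raise ValueError(f"loss weight {name} must be >= 0, got {v}")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _check_shapes(x: Tensor, y: Tensor):
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")


def loss_pix(x, x_hat) -> Tensor:
    """Plain mean squared error in the intensity domain."""
    x, x_hat = _as_tensor(x), _as_tensor(x_hat)
    _check_shapes(x, x_hat)
    d = x - x_hat
    return (d * d).mean()


def fft_amplitude(x: Tensor, axes: tuple) -> Tensor:
    """|FFT(x)| over ``axes`` (orthonormal transform), differentiable.

    The transform convention is fixed to ``norm="ortho"`` so the frequency
    loss lives on the same scale as the pixel MSE (Parseval); any other fixed
    convention would only rescale the loss and be absorbed by its weight.
    """
    x = _as_tensor(x)
    F = np.fft.fftn(x.data, axes=axes, norm="ortho")
    amp = np.abs(F)

    def bwd(g):
        if x.requires_grad:
            safe = np.maximum(amp, 1e-30)
            c = g * np.conj(F) / safe
            x._accum(np.real(np.fft.fftn(c, axes=axes, norm="ortho")))

    return Tensor._make(amp, (x,), bwd)


def loss_freq(x, x_hat) -> Tensor:
    """MSE between Fourier amplitudes of the two volumes (symmetric)."""
    x, x_hat = _as_tensor(x), _as_tensor(x_hat)
    _check_shapes(x, x_hat)
    axes = tuple(range(x.ndim - 3, x.ndim))
    d = fft_amplitude(x, axes) - fft_amplitude(x_hat, axes)
    return (d * d).mean()


def mse_slice_extractor(a: Tensor, b: Tensor) -> Tensor:
    """Identity-feature slice distance: mean squared error over the slices.

    Stands in for a pretrained 2D perceptual metric so the slice-wise loss is
    oracle-checkable without downloads; any callable with the same signature
    (two stacked slice tensors -> scalar Tensor) can replace it.
    """
    d = a - b
    return (d * d).mean()


def loss_pcp(x, x_hat, extractor=mse_slice_extractor,
             slice_fraction: float = 0.5, seed: int = 0) -> Tensor:
    """Slice-wise perceptual distance, summed over the three planes.

    For each spatial axis a random ``slice_fraction`` of slices is selected
    (all slices when an axis has fewer than 2) and the mean extractor
    distance over that subset is computed; the three plane terms are summed.
    Deterministic for a fixed seed.
    """
    x, x_hat = _as_tensor(x), _as_tensor(x_hat)
    _check_shapes(x, x_hat)
    rng = np.random.default_rng(seed)
    spatial_axes = range(x.ndim - 3, x.ndim)
    total = Tensor(0.0)
    for ax in spatial_axes:
        n = x.shape[ax]
        if n < 2:
            idx = np.arange(n)
        else:
            k = max(1, int(round(slice_fraction * n)))
            idx = np.sort(rng.choice(n, size=k, replace=False))
        sl = [slice(None)] * x.ndim
        sl[ax] = idx
        total = total + extractor(x[tuple(sl)], x_hat[tuple(sl)])
    return total


def discriminator_loss(real_scores, fake_scores) -> Tensor:
    """Least-squares discriminator objective over patch logits."""
    r, f = _as_tensor(real_scores), _as_tensor(fake_scores)
    dr = r - 1.0
    return (dr * dr).mean() * 0.5 + (f * f).mean() * 0.5


def generator_adv_loss(fake_scores) -> Tensor:
    """Least-squares generator objective: push fake patch logits toward 1."""
    f = _as_tensor(fake_scores)
    d = f - 1.0
    return (d * d).mean() * 0.5


def total_vqvae_loss(l_quant, l_pix, l_freq, l_pcp, l_adv,
                     weights: LossWeights = LossWeights()) -> Tensor:
    """Weighted sum of the five loss components."""
    parts = [_as_tensor(t) for t in (l_quant, l_pix, l_freq, l_pcp, l_adv)]
    for p in parts:
        if not np.all(np.isfinite(p.data)):
            raise ValueError("loss components must be finite")
    lq, lp, lf, lc, la = parts
    return (lq + weights.alpha_pix * lp + weights.alpha_freq * lf
            + weights.alpha_pcp * lc + weights.alpha_dis * la)
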