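"""Transformer building blocks: scaled dot-product attention, 3D relative
positional bias, RMS normalization and sigmoid-gated residuals."""

from __future__ import annotations

import numpy as np

from ..autodiff import Parameter, Tensor
from ..nn import Linear, Module

_NEG = -1e30


def attention(q: Tensor, k: Tensor, v: Tensor, mask: np.ndarray | None = None,
              bias: Tensor | np.ndarray | None = None) -> Tensor:
    """softmax(QK^T / sqrt(d_K) + bias) V over unmasked keys.

    ``mask`` is boolean, True where attention is *allowed*, broadcastable to
    the logit shape (..., Lq, Lk).  A query with every key masked raises
    rather than silently producing NaNs.
    """
    d_k = q.shape[-1]
    logits = (q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)) * (
        1.0 / np.sqrt(d_k)
    )
    if bias is not None:
        logits = logits + (bias if isinstance(bias, Tensor) else Tensor(bias))
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        full = np.broadcast_to(mask, logits.shape)
        if (~full).all(axis=-1).any():
            raise ValueError("a query position has all keys masked")
        logits = logits + np.where(mask, 0.0, _NEG)
    return logits.softmax(-1) @ v


def rms_norm(x: Tensor, gain: Tensor | np.ndarray | None = None,
             eps: float = 1e-8) -> Tensor:
    """x / sqrt(mean(x^2) + eps) * gain over the last axis."""
    if not isinstance(x, Tensor):
        x = Tensor(x)
    ms = (x * x).mean(axis=-1, keepdims=True)
    y = x * ((ms + eps) ** -0.5)
    if gain is not None:
        y = y * (gain if isinstance(gain, Tensor) else Tensor(gain))
    return y


class RMSNorm(Module):
    def __init__(self, dim: int):
        self.gain = Parameter(np.ones(dim))

    def forward(self, x: Tensor) -> Tensor:
        return rms_norm(x, self.gain)


class RelPosBias3D(Module):
    """Per-head learned 1D offset tables combined per 3D offset.

    For raster positions p, q with offsets (dx, dy, dz), the bias is the
    product b_x[dx] * b_y[dy] * b_z[dz] (one scalar per table entry per
    head); an additive-sum variant is available for ablation.  No distance
    bucketing: every offset has its own entry.
    """

    def __init__(self, dims: tuple, heads: int, rng: np.random.Generator,
                 combine: str = "product"):
        if combine not in ("product", "sum"):
            raise ValueError("combine must be 'product' or 'sum'")
        self.dims = tuple(dims)
        self.heads = heads
        self.combine = combine
        h, w, d = self.dims
        init = 1.0 if combine == "product" else 0.0
        scale = 0.1
        self.table_x = Parameter(init + rng.normal(0, scale, (heads, 2 * h - 1)))
        self.table_y = Parameter(init + rng.normal(0, scale, (heads, 2 * w - 1)))
        self.table_z = Parameter(init + rng.normal(0, scale, (heads, 2 * d - 1)))
        self._idx = self._offset_indices(self.dims)

    @staticmethod
    def _offset_indices(dims: tuple):
        h, w, d = dims
        coords = np.stack(np.unravel_index(np.arange(h * w * d), dims), axis=1)
        delta = coords[:, None, :] - coords[None, :, :]  # (L, L, 3)
        ix = delta[:, :, 0] + (h - 1)
        iy = delta[:, :, 1] + (w - 1)
        iz = delta[:, :, 2] + (d - 1)
        return ix, iy, iz

    def forward(self, length: int | None = None) -> Tensor:
        """Bias tensor (heads, L, L) for the full raster; optionally cropped
        to the first ``length`` positions (prefix of the raster order)."""
        ix, iy, iz = self._idx
        if length is not None:
            ix, iy, iz = ix[:length, :length], iy[:length, :length], iz[:length, :length]
        bx = self.table_x[:, ix]
        by = self.table_y[:, iy]
        bz = self.table_z[:, iz]
        if self.combine == "product":
            return bx * by * bz
        return bx + by + bz


class GateUnit(Module):
    """Learned sigmoid gate over a sublayer output: y = x + sigma(g) * sub,
    g an affine map of [x, sub].  Gate bias at -inf gives the identity;
    saturated at +inf, a plain residual."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.proj = Linear(2 * dim, dim, rng)
        # bias ~ +1 so training starts close to a plain residual block
        self.proj.bias.data[:] = 1.0

    def forward(self, x: Tensor, sub: Tensor) -> Tensor:
        if x.shape != sub.shape:
            raise ValueError("gate inputs must share a shape")
        g = self.proj(Tensor.concat([x, sub], axis=-1))
        return x + g.sigmoid() * sub


def gated_block(x: Tensor, sub: Tensor, gate: GateUnit) -> Tensor:
    """Functional form of :class:`GateUnit`."""
    return gate(x, sub)
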