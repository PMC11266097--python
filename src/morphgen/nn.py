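"""Neural-network layers on top of the autodiff engine.

Convolutions use an im2col/col2im pair; transposed convolution is wired as
the exact adjoint of the strided convolution, so up/down-sampling layers are
mutually consistent by construction.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor

__all__ = [
    "Module",
    "Linear",
    "Conv3d",
    "ConvTranspose3d",
    "Embedding",
    "Sequential",
    "LeakyReLU",
]


# ---------------------------------------------------------------------------
# im2col / col2im core (pure numpy, shared by Conv3d and ConvTranspose3d)
# ---------------------------------------------------------------------------


def _out_dims(spatial, k, s, p):
    return tuple((n + 2 * p - k) // s + 1 for n in spatial)


def _im2col(x: np.ndarray, k: int, s: int, p: int):
    """(N,C,H,W,D) -> (N, L, C*k^3) patch matrix, L = prod(out dims)."""
    if p:
        x = np.pad(x, ((0, 0), (0, 0)) + ((p, p),) * 3)
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
    win = win[:, :, ::s, ::s, ::s]  # (N,C,oh,ow,od,k,k,k)
    n, c, oh, ow, od = win.shape[:5]
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n, oh * ow * od, c * k**3)
    return np.ascontiguousarray(cols), (oh, ow, od)

def _col2im(gcols: np.ndarray, xshape, k: int, s: int, p: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch gradients back to the input."""
    n, c, h, w, d = xshape
    hp, wp, dp = h + 2 * p, w + 2 * p, d + 2 * p
    oh, ow, od = _out_dims((h, w, d), k, s, p)
    g = gcols.reshape(n, oh, ow, od, c, k, k, k).transpose(0, 4, 1, 2, 3, 5, 6, 7)
    gx = np.zeros((n, c, hp, wp, dp))
    for i in range(k):
        for j in range(k):
            for m in range(k):
                gx[
                    :,
                    :,
                    i : i + oh * s : s,
                    j : j + ow * s : s,
                    m : m + od * s : s,
                ] += g[..., i, j, m]
    if p:
        gx = gx[:, :, p : p + h, p : p + w, p : p + d]
    return gx


def _conv_fwd(x, wmat, k, s, p):
    """x:(N,Cin,H,W,D), wmat:(Cout, Cin*k^3) -> (N,Cout,oh,ow,od)."""
    cols, out = _im2col(x, k, s, p)
    y = cols @ wmat.T
    n = x.shape[0]
    return y.transpose(0, 2, 1).reshape(n, wmat.shape[0], *out), cols


def _conv_bwd_x(gy, wmat, xshape, k, s, p):
    n, cout = gy.shape[:2]
    gyl = gy.reshape(n, cout, -1).transpose(0, 2, 1)  # (N,L,Cout)
    gcols = gyl @ wmat  # (N,L,Cin*k^3)
    return _col2im(gcols, xshape, k, s, p)


def _conv_bwd_w(cols, gy):
    n, cout = gy.shape[:2]
    gyl = gy.reshape(n, cout, -1)  # (N,Cout,L)
    return np.einsum("ncl,nlk->ck", gyl, cols)


# ---------------------------------------------------------------------------
# Module base
# ---------------------------------------------------------------------------


class Module:
    """Lightweight container with recursive parameter discovery."""

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        out = []
        for name, attr in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(attr, Parameter):
                out.append((full, attr))
            elif isinstance(attr, Module):
                out.extend(attr.named_parameters(full + "."))
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{full}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{full}.{i}", item))
        return out

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={missing}, extra={extra}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        scale = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-scale, scale, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Embedding(Module):
    def __init__(self, num_embeddings: int, dim: int, rng: np.random.Generator):
        self.weight = Parameter(rng.normal(0.0, 0.02, (num_embeddings, dim)))

    def forward(self, indices) -> Tensor:
        idx = np.asarray(indices, dtype=np.int64)
        return self.weight[idx]


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Upsample3d(Module):
    """Nearest-neighbour 2x spatial upsampling."""

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w, d = x.data.shape
        y = np.repeat(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), 2, axis=4)

        def bwd(g):
            if x.requires_grad:
                x._accum(
                    g.reshape(n, c, h, 2, w, 2, d, 2).sum(axis=(3, 5, 7))
                )

        return Tensor._make(y, (x,), bwd)


class InstanceNorm3d(Module):
    """Per-sample, per-channel normalization over spatial dims with learned
    affine; stabilizes the deep conv stacks at toy learning rates."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gain = Parameter(np.ones((1, channels, 1, 1, 1)))
        self.shift = Parameter(np.zeros((1, channels, 1, 1, 1)))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3, 4), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3, 4), keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.gain + self.shift


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv3d(Module):
    """3D convolution, NCHWD layout."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, pad: int = 0, bias: bool = True):
        self.kernel, self.stride, self.pad = kernel, stride, pad
        # He init with leaky-relu gain; keeps activation scale through deep stacks
        fan_in = in_ch * kernel**3
        std = np.sqrt(2.0 / (1.0 + 0.2**2) / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        k, s, p = self.kernel, self.stride, self.pad
        w = self.weight
        wmat = w.data.reshape(w.data.shape[0], -1)
        y, cols = _conv_fwd(x.data, wmat, k, s, p)
        if self.bias is not None:
            y = y + self.bias.data.reshape(1, -1, 1, 1, 1)
        xshape = x.data.shape
        bias = self.bias

        def bwd(g):
            if w.requires_grad:
                gw = _conv_bwd_w(cols, g).reshape(w.data.shape)
                w._accum(gw)
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3, 4)))
            if x.requires_grad:
                x._accum(_conv_bwd_x(g, wmat, xshape, k, s, p))

        parents = (x, w) + ((bias,) if bias is not None else ())
        return Tensor._make(y, parents, bwd)


class ConvTranspose3d(Module):
    """Adjoint of Conv3d: output spatial size = (n-1)*stride - 2*pad + kernel."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, pad: int = 0, bias: bool = True):
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.out_ch = out_ch
        # each output position receives ~in_ch * k^3 / stride^3 contributions
        fan_in_eff = max(in_ch * kernel**3 // stride**3, 1)
        std = np.sqrt(2.0 / (1.0 + 0.2**2) / fan_in_eff)
        # weight laid out as (in_ch, out_ch, k, k, k), torch convention
        self.weight = Parameter(rng.normal(0.0, std, (in_ch, out_ch, kernel, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        k, s, p = self.kernel, self.stride, self.pad
        w = self.weight
        n, cin, h, wd, d = x.data.shape
        out_spatial = tuple((m - 1) * s - 2 * p + k for m in (h, wd, d))
        yshape = (n, self.out_ch, *out_spatial)
        wmat = w.data.reshape(cin, -1)  # (Cin, Cout*k^3)
        y = _conv_bwd_x(x.data, wmat, yshape, k, s, p)
        if self.bias is not None:
            y = y + self.bias.data.reshape(1, -1, 1, 1, 1)
        bias = self.bias

        def bwd(g):
            cols_g, _ = _im2col(g, k, s, p)
            if x.requires_grad:
                gx = (cols_g @ wmat.T).transpose(0, 2, 1).reshape(x.data.shape)
                x._accum(gx)
            if w.requires_grad:
                gw = _conv_bwd_w(cols_g, x.data).reshape(w.data.shape)
                w._accum(gw)
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3, 4)))

        parents = (x, w) + ((bias,) if bias is not None else ())
        return Tensor._make(y, parents, bwd)
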