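"""Sample-fidelity and diversity metrics: MMD, FID, MS-SSIM, 4-G-SSIM.

The feature extractor for MMD/FID is pluggable; the default is a fixed-seed
random projection of average-pooled volumes — deterministic, training-free,
and adequate for distribution comparisons at desk scale.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import linalg, ndimage

log = logging.getLogger(__name__)

# standard 5-scale MS-SSIM weights
MS_SSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)
_K1, _K2 = 0.01, 0.03


def _as_volumes(x) -> np.ndarray:
    """Accept list of Volume / arrays or an (N, ...) array."""
    if isinstance(x, np.ndarray) and x.ndim >= 2:
        return x
    arrs = [v.data if hasattr(v, "data") else np.asarray(v) for v in x]
    return np.stack(arrs)


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------


def random_projection_features(volumes, dim: int = 64, seed: int = 0,
                               pool: int = 4) -> np.ndarray:
    """(N, H, W, D) volumes -> (N, dim) features.

    Average-pool by ``pool`` per axis, flatten, project with a fixed-seed
    Gaussian matrix scaled by 1/sqrt(input dim).  Deterministic.
    """
    x = _as_volumes(volumes).astype(np.float64)
    n = x.shape[0]
    h, w, d = x.shape[1:]
    ph, pw, pd = h // pool, w // pool, d // pool
    pooled = x[:, : ph * pool, : pw * pool, : pd * pool].reshape(
        n, ph, pool, pw, pool, pd, pool
    ).mean(axis=(2, 4, 6))
    flat = pooled.reshape(n, -1)
    rng = np.random.default_rng(seed)
    proj = rng.normal(0.0, 1.0, (flat.shape[1], dim)) / np.sqrt(flat.shape[1])
    return flat @ proj


# ---------------------------------------------------------------------------
# MMD
# ---------------------------------------------------------------------------


def mmd(a: np.ndarray, b: np.ndarray, bandwidth: float | None = None) -> float:
    """Biased (V-statistic) squared MMD with a Gaussian RBF kernel.

    Kernel k(x, y) = exp(-||x-y||^2 / (2 h^2)); ``h`` defaults to the median
    pairwise Euclidean distance over the pooled set (median heuristic).
    """
    a, b = np.atleast_2d(np.asarray(a, float)), np.atleast_2d(np.asarray(b, float))
    if a.size == 0 or b.size == 0:
        raise ValueError("feature sets must be non-empty")
    if a.shape[1] != b.shape[1]:
        raise ValueError("feature dimensions differ")
    pooled = np.vstack([a, b])
    d2_pool = _sq_dists(pooled, pooled)
    if bandwidth is None:
        iu = np.triu_indices(len(pooled), k=1)
        med = np.median(np.sqrt(d2_pool[iu]))
        bandwidth = med if med > 0 else 1.0
    g = 1.0 / (2.0 * bandwidth**2)
    kaa = np.exp(-g * _sq_dists(a, a)).mean()
    kbb = np.exp(-g * _sq_dists(b, b)).mean()
    kab = np.exp(-g * _sq_dists(a, b)).mean()
    return float(kaa + kbb - 2.0 * kab)


def _sq_dists(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    d = x[:, None, :] - y[None, :, :]
    return np.einsum("ijk,ijk->ij", d, d)


# ---------------------------------------------------------------------------
# FID
# ---------------------------------------------------------------------------


def fid(a: np.ndarray, b: np.ndarray, eps: float = 1e-6) -> float:
    """Frechet distance between Gaussian fits of two feature sets.

    ||mu_a - mu_b||^2 + Tr(S_a + S_b - 2 (S_a S_b)^{1/2}); the matrix square
    root is stabilized by adding ``eps`` * I to both covariances whenever the
    plain product root comes back non-finite or notably complex.
    """
    a, b = np.atleast_2d(np.asarray(a, float)), np.atleast_2d(np.asarray(b, float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("feature dimensions differ")
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    s_a = np.atleast_2d(np.cov(a, rowvar=False))
    s_b = np.atleast_2d(np.cov(b, rowvar=False))
    if not (np.all(np.isfinite(s_a)) and np.all(np.isfinite(s_b))):
        raise ValueError("non-finite covariance")
    diff = mu_a - mu_b
    covmean = linalg.sqrtm(s_a @ s_b)
    if not np.all(np.isfinite(covmean)) or (
        np.iscomplexobj(covmean)
        and np.abs(covmean.imag).max() > 1e-6 * max(np.abs(covmean.real).max(), 1.0)
    ):
        off = eps * np.eye(s_a.shape[0])
        covmean = linalg.sqrtm((s_a + off) @ (s_b + off))
    covmean = np.real(covmean)
    return float(diff @ diff + np.trace(s_a) + np.trace(s_b) - 2.0 * np.trace(covmean))


# ---------------------------------------------------------------------------
# SSIM family (3D windows)
# ---------------------------------------------------------------------------


def _ssim_maps(x: np.ndarray, y: np.ndarray, data_range: float, sigma: float = 1.5):
    c1 = (_K1 * data_range) ** 2
    c2 = (_K2 * data_range) ** 2
    f = lambda a: ndimage.gaussian_filter(a, sigma, mode="reflect")
    mx, my = f(x), f(y)
    mxx, myy, mxy = f(x * x), f(y * y), f(x * y)
    vx = np.maximum(mxx - mx * mx, 0.0)
    vy = np.maximum(myy - my * my, 0.0)
    cxy = mxy - mx * my
    lum = (2 * mx * my + c1) / (mx * mx + my * my + c1)
    cs = (2 * cxy + c2) / (vx + vy + c2)
    return lum, cs


def ssim3d(x: np.ndarray, y: np.ndarray, data_range: float = 1.0) -> float:
    """Mean single-scale SSIM with 3D Gaussian windows; ssim3d(x, x) == 1."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    lum, cs = _ssim_maps(x, y, data_range)
    return float((lum * cs).mean())


def _downsample2(a: np.ndarray) -> np.ndarray:
    s = [n - n % 2 for n in a.shape]
    a = a[tuple(slice(0, n) for n in s)]
    for ax in range(a.ndim):
        a = (np.take(a, range(0, a.shape[ax], 2), axis=ax)
             + np.take(a, range(1, a.shape[ax], 2), axis=ax)) / 2.0
    return a


def ms_ssim(x: np.ndarray, y: np.ndarray, data_range: float = 1.0,
            weights=MS_SSIM_WEIGHTS, min_size: int = 8) -> float:
    """Multi-scale SSIM with the standard 5-scale weights, 3D windows.

    Volumes too small for the full pyramid use fewer scales with the weight
    vector renormalized (logged).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    weights = np.asarray(weights, float)
    max_scales = 1
    m = min(x.shape)
    while max_scales < len(weights) and m // 2 >= min_size:
        m //= 2
        max_scales += 1
    if max_scales < len(weights):
        log.info("volume too small for %d scales; using %d (renormalized)",
                 len(weights), max_scales)
        weights = weights[:max_scales] / weights[:max_scales].sum()
    vals = []
    for i in range(len(weights)):
        lum, cs = _ssim_maps(x, y, data_range)
        if i == len(weights) - 1:
            vals.append((lum * cs).mean())
        else:
            vals.append(cs.mean())
            x, y = _downsample2(x), _downsample2(y)
    vals = np.clip(np.asarray(vals), 1e-8, None)  # negative cs is rare; clamp
    return float(np.prod(vals ** weights))


def _pair_subset(n: int, max_pairs: int, seed: int) -> list[tuple]:
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if len(pairs) <= max_pairs:
        return pairs
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pairs), size=max_pairs, replace=False)
    return [pairs[i] for i in idx]


def ms_ssim_diversity(samples, max_pairs: int = 100, seed: int = 0,
                      data_range: float = 1.0) -> tuple:
    """Mean +/- sd of pairwise MS-SSIM over a fixed-seed subset of pairs.

    Lower values mean higher diversity.
    """
    x = _as_volumes(samples)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    vals = [ms_ssim(x[i], x[j], data_range) for i, j in
            _pair_subset(x.shape[0], max_pairs, seed)]
    return float(np.mean(vals)), float(np.std(vals))


# ---------------------------------------------------------------------------
# 4-G-SSIM
# ---------------------------------------------------------------------------

# two axis-aligned and two diagonal difference kernels (2D, applied slice-wise)
_G_KERNELS = (
    np.array([[1.0, -1.0], [0.0, 0.0]]),
    np.array([[1.0, 0.0], [-1.0, 0.0]]),
    np.array([[1.0, 0.0], [0.0, -1.0]]),
    np.array([[0.0, 1.0], [-1.0, 0.0]]),
)


def _gradient_magnitude(x: np.ndarray) -> np.ndarray:
    """Four-direction gradient magnitude, slice-wise over the last axis."""
    acc = np.zeros_like(x)
    for k in _G_KERNELS:
        k3 = k[:, :, None]  # same 2D kernel on every slice
        r = ndimage.convolve(x, k3, mode="nearest")
        acc += r * r
    return np.sqrt(acc)


def g4_ssim(x: np.ndarray, y: np.ndarray, data_range: float = 1.0) -> float:
    """SSIM on four-directional gradient-magnitude maps; g4_ssim(x, x) == 1."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    return ssim3d(_gradient_magnitude(x), _gradient_magnitude(y), data_range)


def g4_ssim_diversity(samples, max_pairs: int = 100, seed: int = 0,
                      data_range: float = 1.0) -> tuple:
    x = _as_volumes(samples)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    vals = [g4_ssim(x[i], x[j], data_range) for i, j in
            _pair_subset(x.shape[0], max_pairs, seed)]
    return float(np.mean(vals)), float(np.std(vals))
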