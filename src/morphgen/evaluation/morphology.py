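"""Morphology-preservation statistics: distribution distances, tests,
effect sizes, failure rate, conditioning recovery and a voxelwise t-map."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)


def gaussian_kl(p_values: np.ndarray, q_values: np.ndarray) -> float:
    """KL(N_p || N_q) between Gaussian moment fits of the two samples (nats).

    Used as KL(synthetic || real) in the region report; chosen over histogram
    KL for stability at small n (a histogram variant exists behind a flag in
    :func:`region_stats`).
    """
    p, q = np.asarray(p_values, float), np.asarray(q_values, float)
    mp, sp = p.mean(), p.std(ddof=1)
    mq, sq = q.mean(), q.std(ddof=1)
    if sp == 0 or sq == 0:
        return float("nan")
    return float(np.log(sq / sp) + (sp**2 + (mp - mq) ** 2) / (2 * sq**2) - 0.5)


def histogram_kl(p_values: np.ndarray, q_values: np.ndarray, bins: int = 10,
                 eps: float = 1e-9) -> float:
    """Discrete KL over a shared-bin histogram (flag alternative)."""
    p_values, q_values = np.asarray(p_values, float), np.asarray(q_values, float)
    lo = min(p_values.min(), q_values.min())
    hi = max(p_values.max(), q_values.max())
    hp, _ = np.histogram(p_values, bins=bins, range=(lo, hi))
    hq, _ = np.histogram(q_values, bins=bins, range=(lo, hi))
    p = hp / hp.sum() + eps
    q = hq / hq.sum() + eps
    p, q = p / p.sum(), q / q.sum()
    return float((p * np.log(p / q)).sum())


@dataclass
class RegionStats:
    wasserstein: float
    kl: float
    mannwhitney_u: float
    mannwhitney_p: float
    glass_delta: float
    z_scores: np.ndarray
    n_real: int
    n_synth: int


def region_stats(real_values, synth_values, kl_mode: str = "gaussian") -> RegionStats:
    """Distribution comparison for one region's volumes.

    Wasserstein-1 (sorted-sample quantile integral), KL of Gaussian moment
    fits (synthetic vs real), exact-tie-corrected two-sided Mann-Whitney U,
    and Glass's delta = (mean_synth - mean_real) / sd_real.  Zero real-side
    variance leaves delta undefined (NaN).
    """
    real = np.asarray(real_values, float)
    synth = np.asarray(synth_values, float)
    if real.size < 2 or synth.size < 2:
        raise ValueError("need at least 2 values per side")
    w = float(stats.wasserstein_distance(real, synth))
    if kl_mode == "gaussian":
        kl = gaussian_kl(synth, real)
    elif kl_mode == "histogram":
        kl = histogram_kl(synth, real)
    else:
        raise ValueError("kl_mode must be 'gaussian' or 'histogram'")
    u_res = stats.mannwhitneyu(synth, real, alternative="two-sided")
    sd_real = real.std(ddof=1)
    mean_diff = synth.mean() - real.mean()
    delta = float(mean_diff / sd_real) if sd_real > 0 else float("nan")
    if sd_real > 0:
        z = (synth - real.mean()) / sd_real
    else:
        z = np.full(synth.shape, np.nan)
    return RegionStats(
        wasserstein=w,
        kl=kl,
        mannwhitney_u=float(u_res.statistic),
        mannwhitney_p=float(u_res.pvalue),
        glass_delta=delta,
        z_scores=z,
        n_real=real.size,
        n_synth=synth.size,
    )


def failure_rate(synth_by_region: dict, reference: dict,
                 threshold: float = 5.0) -> float:
    """Fraction of synthetic samples with any region |Z| above ``threshold``.

    ``synth_by_region``: region -> array of per-sample values (aligned);
    ``reference``: region -> (mean, sd) from the real corpus.  Regions with
    zero reference sd are excluded with a warning.
    """
    zmax = None
    for region, values in synth_by_region.items():
        mean, sd = reference[region]
        if sd <= 0:
            log.warning("region %r has zero reference sd; excluded", region)
            continue
        z = np.abs((np.asarray(values, float) - mean) / sd)
        zmax = z if zmax is None else np.maximum(zmax, z)
    if zmax is None:
        raise ValueError("no region with positive reference sd")
    return float((zmax > threshold).mean())


def conditioning_recovery(conditioned_values, measured_values) -> tuple:
    """Pearson r (and two-sided p) between the conditioning used to sample
    and the value measured on the generated volumes."""
    c = np.asarray(conditioned_values, float)
    m = np.asarray(measured_values, float)
    if c.size != m.size or c.size < 3:
        raise ValueError("need >= 3 aligned pairs")
    if c.std() == 0 or m.std() == 0:
        log.warning("zero variance on one side; correlation undefined")
        return float("nan"), float("nan")
    r, p = stats.pearsonr(c, m)
    return float(r), float(p)


def voxelwise_tmap(group_a, group_b) -> tuple:
    """Two-sample unequal-variance t-statistic per voxel.

    Returns (tmap, valid_mask); voxels with zero pooled variance get t = 0
    and are marked invalid.  Groups must be voxelwise aligned (phantoms
    share a frame, so no registration).
    """
    a = np.stack([v.data if hasattr(v, "data") else np.asarray(v) for v in group_a])
    b = np.stack([v.data if hasattr(v, "data") else np.asarray(v) for v in group_b])
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 volumes per group")
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("group volume shapes differ")
    va = a.var(axis=0, ddof=1) / a.shape[0]
    vb = b.var(axis=0, ddof=1) / b.shape[0]
    denom2 = va + vb
    valid = denom2 > 0
    t = np.zeros(a.shape[1:])
    t[valid] = (a.mean(axis=0)[valid] - b.mean(axis=0)[valid]) / np.sqrt(denom2[valid])
    return t, valid
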