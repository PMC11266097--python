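"""Phantom rendering and region-volume measurement.

Geometry is nested ellipsoids: an outer "brain" ellipsoid whose size scales
linearly with ``brain_size`` (plus a small sex offset), a bright cortical
shell whose thickness decreases linearly with age, and a pair of central
ellipsoidal "ventricle" cavities whose combined analytic volume equals the
``ventricle_volume`` covariate exactly.  A disease label carves a focal
atrophy sphere at a fixed offset.  All volumes are therefore analytically
known before noise, giving downstream morphology statistics a free oracle.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .spec import CovariateRecord, PhantomSpec, Volume, DEFAULT_RANGES

log = logging.getLogger(__name__)

# noiseless intensity bands (fixed window normalization to [0, 1])
I_BACKGROUND = 0.0
I_VENTRICLE = 0.10
I_LESION = 0.18
I_WHITE = 0.55
I_SHELL = 0.80

# ventricle ellipsoid axis ratios (a, b, c) ~ (1, ELONGATION, 1)
_VENT_ELONGATION = 1.4
# lateral offset of each ventricle from centre, as a fraction of grid size
_VENT_OFFSET_FRAC = 0.10
# lesion placement/size (fractions of grid size)
_LESION_OFFSET_FRAC = (0.18, 0.18, 0.0)
_LESION_RADIUS_FRAC = 0.09


def _record_rng(record: CovariateRecord, spec: PhantomSpec) -> np.random.Generator:
    """Generator fully determined by (record, spec.seed)."""
    bits = [np.float64(v).view(np.uint64) for v in
            (record.age, record.ventricle_volume, record.brain_size)]
    entropy = [spec.seed, record.sex, int(record.pathology == "disease")] + [
        int(b) & 0xFFFFFFFF for b in bits
    ] + [int(b >> 32) for b in bits]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _clamp_record(record: CovariateRecord, spec: PhantomSpec) -> CovariateRecord:
    updates = {}
    for name in ("age", "ventricle_volume", "brain_size"):
        lo, hi = spec.covariate_ranges.get(name, DEFAULT_RANGES[name])
        v = getattr(record, name)
        c = min(max(v, lo), hi)
        if c != v:
            log.warning("covariate %s=%.4g outside [%g, %g]; clamped", name, v, lo, hi)
            updates[name] = c
    return record.replace(**updates) if updates else record


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = 0.0
    for g, c, a in zip(grids, center, semiaxes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def ventricle_semiaxes(total_volume: float) -> tuple:
    """Semi-axes of each of the two ventricle ellipsoids.

    Each holds half the target, so (4/3)*pi*a*b*c = total/2 with the fixed
    axis ratios (1, elongation, 1) — strictly increasing in total_volume.
    """
    half = max(total_volume, 0.0) / 2.0
    r = (half / ((4.0 / 3.0) * np.pi * _VENT_ELONGATION)) ** (1.0 / 3.0)
    return (r, _VENT_ELONGATION * r, r)


def shell_thickness(age: float, spec: PhantomSpec) -> float:
    """Cortical shell thickness in voxels; linear, strictly decreasing in age."""
    lo, hi = spec.covariate_ranges.get("age", DEFAULT_RANGES["age"])
    t_young, t_old = 3.5, 1.2
    frac = (age - lo) / max(hi - lo, 1e-12)
    return t_young + (t_old - t_young) * frac


def brain_semiaxes(record: CovariateRecord, shape) -> tuple:
    base = tuple(0.40 * n for n in shape)
    sex_factor = 1.0 + 0.03 * record.sex
    return tuple(b * record.brain_size * sex_factor for b in base)


def render_phantom(record: CovariateRecord, spec: PhantomSpec) -> Volume:
    """Render one phantom volume with ground-truth region masks.

    Out-of-range covariates are clamped (with a logged warning), mirroring
    the fact that sampled conditionings at inference may extrapolate.
    """
    record = _clamp_record(record, spec)
    shape = tuple(spec.grid_shape)
    center = tuple((n - 1) / 2.0 for n in shape)

    brain = _ellipsoid_mask(shape, center, brain_semiaxes(record, shape))

    t = shell_thickness(record.age, spec)
    inner_axes = tuple(max(a - t, 0.5) for a in brain_semiaxes(record, shape))
    interior = _ellipsoid_mask(shape, center, inner_axes)
    shell = brain & ~interior

    vx, vy, vz = ventricle_semiaxes(record.ventricle_volume)
    off = _VENT_OFFSET_FRAC * shape[0]
    ventricles = np.zeros(shape, dtype=bool)
    if record.ventricle_volume > 0:
        for s in (-1.0, 1.0):
            c = (center[0] + s * off, center[1], center[2])
            ventricles |= _ellipsoid_mask(shape, c, (vx, vy, vz))
    ventricles &= brain

    lesion = np.zeros(shape, dtype=bool)
    if record.pathology == "disease":
        c = tuple(center[i] + _LESION_OFFSET_FRAC[i] * shape[i] for i in range(3))
        r = _LESION_RADIUS_FRAC * shape[0]
        lesion = _ellipsoid_mask(shape, c, (r, r, r)) & brain & ~ventricles

    data = np.full(shape, I_BACKGROUND)
    data[brain] = I_WHITE
    data[shell] = I_SHELL
    data[lesion] = I_LESION
    data[ventricles] = I_VENTRICLE

    rng = _record_rng(record, spec)
    if spec.bias_field_strength > 0:
        data = data * _bias_field(shape, spec.bias_field_strength, rng)
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=shape)
    data = np.clip(data, 0.0, 1.0)

    masks = {"brain": brain, "ventricles": ventricles, "shell": shell}
    if record.pathology == "disease":
        masks["lesion"] = lesion
    return Volume(data=data, spacing=tuple(spec.spacing), covariates=record,
                  region_masks=masks)


def _bias_field(shape, strength: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field 1 + strength * f, f in [-1, 1]."""
    grids = np.meshgrid(*[np.linspace(0, 1, n) for n in shape], indexing="ij")
    f = np.zeros(shape)
    for g in grids:
        freq = rng.uniform(0.5, 1.5)
        phase = rng.uniform(0, 2 * np.pi)
        f = f + np.cos(2 * np.pi * freq * g + phase)
    m = np.abs(f).max()
    if m > 0:
        f = f / m
    return 1.0 + strength * f


# ---------------------------------------------------------------------------
# Region measurement
# ---------------------------------------------------------------------------

# thresholds for measurement on noisy volumes without ground-truth masks;
# the bands sit between the rendering intensities so that the expected
# misclassification under the default noise_sd is a few percent at most
_T_BRAIN = 0.30      # brain tissue (filled) is above this
_T_SHELL = 0.68      # shell band
_T_CAVITY = 0.30     # any cavity is below this inside the filled brain
_T_VENT_LESION = 0.14  # ventricle band below, lesion band above
_MIN_COMPONENT = 2   # drop single-voxel noise specks


def _despeck(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if not n:
        return mask
    counts = ndimage.sum_labels(mask, labels, range(1, n + 1))
    keep = np.flatnonzero(counts >= _MIN_COMPONENT) + 1
    return np.isin(labels, keep)


def measure_regions(v: Volume) -> dict:
    """Region volumes in mm^3.

    With ground-truth masks this is exact (voxel count x voxel volume).
    Without masks, intensity thresholding plus connected components on the
    rendering intensity bands is used; zero matches produce a zero volume
    with a warning, never an exception.
    """
    if not np.all(np.isfinite(v.data)):
        raise ValueError("volume must be finite")
    voxvol = v.voxel_volume
    if v.region_masks:
        return {name: float(mask.sum()) * voxvol
                for name, mask in v.region_masks.items()}

    data = v.data
    solid = data > _T_BRAIN
    brain = ndimage.binary_fill_holes(solid)
    out = {"brain": float(brain.sum()) * voxvol}
    out["shell"] = float((data > _T_SHELL).sum()) * voxvol

    cavity = brain & (data < _T_CAVITY)
    ventricles = _despeck(cavity & (data < _T_VENT_LESION))
    lesion = _despeck(cavity & (data >= _T_VENT_LESION))
    out["ventricles"] = float(ventricles.sum()) * voxvol
    out["lesion"] = float(lesion.sum()) * voxvol
    if all(val == 0.0 for val in out.values()):
        log.warning("no voxel passed any region threshold; all volumes zero")
    return out
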