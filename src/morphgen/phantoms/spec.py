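"""Core data types: covariate records, phantom configuration, volumes."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

PATHOLOGY_LEVELS = ("normal", "disease")

#: Canonical covariate ordering used everywhere (conditioning, TSV columns).
COVARIATE_ORDER = ("sex", "age", "ventricle_volume", "brain_size", "pathology")


@dataclass(frozen=True)
class CovariateRecord:
    """Per-subject covariates driving phantom morphology and conditioning.

    Attributes
    ----------
    sex : int
        Categorical {0, 1}.
    age : float
        Years, > 0.  Controls cortical-shell thickness (older = thinner).
    ventricle_volume : float
        Target total ventricular volume in mm^3 (>= 0).
    brain_size : float
        Unitless global scale factor (> 0).
    pathology : str
        "normal" or "disease"; disease adds a focal atrophy region.
    """

    sex: int
    age: float
    ventricle_volume: float
    brain_size: float
    pathology: str = "normal"

    def __post_init__(self):
        if self.sex not in (0, 1):
            raise ValueError(f"sex must be 0 or 1, got {self.sex}")
        if not self.age > 0:
            raise ValueError(f"age must be > 0, got {self.age}")
        if self.ventricle_volume < 0:
            raise ValueError("ventricle_volume must be >= 0")
        if not self.brain_size > 0:
            raise ValueError("brain_size must be > 0")
        if self.pathology not in PATHOLOGY_LEVELS:
            raise ValueError(f"pathology must be one of {PATHOLOGY_LEVELS}")

    def replace(self, **kwargs) -> "CovariateRecord":
        return replace(self, **kwargs)


DEFAULT_RANGES = {
    "age": (40.0, 80.0),
    "ventricle_volume": (150.0, 900.0),
    "brain_size": (0.9, 1.1),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Configuration for the phantom generator.

    ``grid_shape`` entries must be divisible by ``2**levels`` where ``levels``
    is the number of encoder downsamplings the volumes will be fed through.
    """

    grid_shape: tuple = (32, 32, 32)
    spacing: tuple = (1.0, 1.0, 1.0)
    noise_sd: float = 0.02
    bias_field_strength: float = 0.05
    covariate_ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))
    disease_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.disease_fraction <= 1.0:
            raise ValueError("disease_fraction must be in [0, 1]")
        for name, (lo, hi) in self.covariate_ranges.items():
            if lo > hi:
                raise ValueError(f"invalid range for {name}: min {lo} > max {hi}")

    def validate_divisibility(self, levels: int):
        f = 2**levels
        bad = [n for n in self.grid_shape if n % f]
        if bad:
            raise ValueError(
                f"grid_shape {self.grid_shape} not divisible by 2^{levels}"
            )


@dataclass
class Volume:
    """A one-channel 3D intensity volume with covariates and optional masks."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    covariates: CovariateRecord | None = None
    region_masks: dict | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        if self.region_masks is not None:
            for name, mask in self.region_masks.items():
                if mask.shape != self.data.shape:
                    raise ValueError(f"mask {name!r} shape mismatch")

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))
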