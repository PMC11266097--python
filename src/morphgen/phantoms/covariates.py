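"""Covariate sampling for phantom corpora."""

from __future__ import annotations

import numpy as np

from .spec import CovariateRecord, PhantomSpec


def sample_covariates(n: int, spec: PhantomSpec) -> list[CovariateRecord]:
    """Draw ``n`` covariate records uniformly within the spec's ranges.

    Continuous covariates are i.i.d. uniform on their [min, max]; sex is a
    fair coin; pathology is "disease" with probability ``spec.disease_fraction``.
    Fully reproducible for a fixed ``spec.seed``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC0DA]))
    ranges = spec.covariate_ranges
    sexes = rng.integers(0, 2, size=n)
    ages = rng.uniform(*ranges["age"], size=n)
    vents = rng.uniform(*ranges["ventricle_volume"], size=n)
    sizes = rng.uniform(*ranges["brain_size"], size=n)
    disease = rng.random(n) < spec.disease_fraction
    return [
        CovariateRecord(
            sex=int(sexes[i]),
            age=float(ages[i]),
            ventricle_volume=float(vents[i]),
            brain_size=float(sizes[i]),
            pathology="disease" if disease[i] else "normal",
        )
        for i in range(n)
    ]
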