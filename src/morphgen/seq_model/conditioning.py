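"""Covariate conditioning: standardization, embedding, token construction.

The conditioning set is an *ordered* list of covariates (order fixed by the
schema, not by the caller's record) plus the augmentation parameter vector;
cross-attention layers consume one embedded token per covariate and one for
the augmentation parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..autodiff import Tensor
from ..nn import Embedding, Linear, Module
from ..phantoms.augment import PARAM_NAMES, identity_params
from ..phantoms.spec import CovariateRecord

#: schema: (name, kind); kind is "continuous" or "categorical"
DEFAULT_SCHEMA = (
    ("sex", "categorical"),
    ("age", "continuous"),
    ("ventricle_volume", "continuous"),
    ("brain_size", "continuous"),
    ("pathology", "categorical"),
)

CATEGORICAL_LEVELS = {
    "sex": (0, 1),
    "pathology": ("normal", "disease"),
}


@dataclass(frozen=True)
class CovariateStats:
    """Per-covariate mean/sd from the training corpus (continuous only)."""

    means: dict
    sds: dict

    @classmethod
    def from_records(cls, records: list[CovariateRecord],
                     schema=DEFAULT_SCHEMA) -> "CovariateStats":
        means, sds = {}, {}
        for name, kind in schema:
            if kind != "continuous":
                continue
            vals = np.array([getattr(r, name) for r in records], dtype=float)
            means[name] = float(vals.mean())
            sds[name] = float(vals.std()) or 1.0
        return cls(means=means, sds=sds)

    def standardize(self, name: str, value: float) -> float:
        return (value - self.means[name]) / self.sds[name]


@dataclass
class ConditioningSet:
    """Ordered covariate values plus augmentation parameters."""

    values: dict
    aug_params: np.ndarray = field(default_factory=identity_params)
    schema: tuple = DEFAULT_SCHEMA

    def __post_init__(self):
        self.aug_params = np.asarray(self.aug_params, dtype=float)
        if self.aug_params.shape != (len(PARAM_NAMES),):
            raise ValueError(f"aug_params must have shape ({len(PARAM_NAMES)},)")
        missing = [n for n, _ in self.schema if n not in self.values]
        if missing:
            raise ValueError(f"conditioning missing covariate(s): {missing}")


def conditioning_from_record(record: CovariateRecord,
                             aug_params: np.ndarray | None = None) -> ConditioningSet:
    values = {
        "sex": record.sex,
        "age": record.age,
        "ventricle_volume": record.ventricle_volume,
        "brain_size": record.brain_size,
        "pathology": record.pathology,
    }
    return ConditioningSet(values=values,
                           aug_params=aug_params if aug_params is not None
                           else identity_params())


class ConditioningEmbedder(Module):
    """Maps a ConditioningSet to a (num_tokens, width) key/value matrix.

    Continuous covariates (standardized) become ``value * direction + bias``;
    categorical ones are a table lookup; the augmentation parameter vector is
    projected to a single extra token.  Unknown categorical levels raise.
    """

    def __init__(self, width: int, stats: CovariateStats,
                 rng: np.random.Generator, schema=DEFAULT_SCHEMA):
        self.schema = tuple(schema)
        self.stats = stats
        self.width = width
        self.cont_proj = {}
        self.cat_emb = {}
        for name, kind in self.schema:
            if kind == "continuous":
                self.cont_proj[name] = Linear(1, width, rng)
            else:
                self.cat_emb[name] = Embedding(len(CATEGORICAL_LEVELS[name]), width, rng)
        self.aug_proj = Linear(len(PARAM_NAMES), width, rng)
        # expose dict members for parameter discovery
        for name, mod in self.cont_proj.items():
            setattr(self, f"cont_{name}", mod)
        for name, mod in self.cat_emb.items():
            setattr(self, f"cat_{name}", mod)

    @property
    def num_tokens(self) -> int:
        return len(self.schema) + 1

    def forward(self, csets: list[ConditioningSet]) -> Tensor:
        """Batch of conditioning sets -> (B, num_tokens, width)."""
        if isinstance(csets, ConditioningSet):
            csets = [csets]
        rows = []
        for name, kind in self.schema:
            if kind == "continuous":
                vals = np.array(
                    [[self.stats.standardize(name, c.values[name])] for c in csets]
                )
                rows.append(self.cont_proj[name](Tensor(vals)))
            else:
                levels = CATEGORICAL_LEVELS[name]
                try:
                    idx = np.array([levels.index(c.values[name]) for c in csets])
                except ValueError as e:
                    raise ValueError(f"unknown level for covariate {name!r}") from e
                rows.append(self.cat_emb[name](idx))
        aug = np.stack([c.aug_params for c in csets])
        rows.append(self.aug_proj(Tensor(aug)))
        return Tensor.stack(rows, axis=1)  # (B, T_cond, width)
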