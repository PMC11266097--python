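"""Run configuration: a single YAML file with per-stage sections.

Every command serializes the exact config (plus a content hash) next to its
artifacts so a run is reproducible from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from .phantoms.spec import PhantomSpec
from .seq_model.model import SeqModelConfig
from .vqvae.losses import LossWeights
from .vqvae.model import VQVAEConfig

DEFAULT_CONFIG = {
    "seed": 0,
    "phantoms": {
        "n": 200,
        "grid_shape": [32, 32, 32],
        "spacing": [1.0, 1.0, 1.0],
        "noise_sd": 0.02,
        "bias_field_strength": 0.05,
        "disease_fraction": 0.0,
        "ranges": {
            "age": [40.0, 80.0],
            "ventricle_volume": [150.0, 900.0],
            "brain_size": [0.9, 1.1],
        },
    },
    "vqvae": {
        "profile": "desk",
        "steps": 200,
        "overrides": {},
        "weights": {"alpha_pix": 1.0, "alpha_freq": 1.0,
                    "alpha_pcp": 0.001, "alpha_dis": 1.0},
    },
    "seq_model": {
        "profile": "desk",
        "steps": 500,
        "use_augmentation": True,
        "overrides": {},
    },
    "evaluation": {
        "z_threshold": 5.0,
        "max_pairs": 100,
        "feature_dim": 64,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    return cfg


def config_digest(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def save_config(cfg: dict, out_dir: str | Path):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    (out_dir / "config.hash").write_text(config_digest(cfg) + "\n")


def phantom_spec_from(cfg: dict) -> PhantomSpec:
    p = cfg["phantoms"]
    return PhantomSpec(
        grid_shape=tuple(p["grid_shape"]),
        spacing=tuple(p["spacing"]),
        noise_sd=float(p["noise_sd"]),
        bias_field_strength=float(p["bias_field_strength"]),
        covariate_ranges={k: tuple(v) for k, v in p["ranges"].items()},
        disease_fraction=float(p["disease_fraction"]),
        seed=int(cfg["seed"]),
    )


def vqvae_config_from(cfg: dict) -> VQVAEConfig:
    section = cfg["vqvae"]
    overrides = dict(section.get("overrides") or {})
    for key in ("channels", "disc_channels"):
        if key in overrides:
            overrides[key] = tuple(overrides[key])
    overrides.setdefault("seed", int(cfg["seed"]))
    if section.get("profile", "desk") == "desk":
        return VQVAEConfig.desk(**overrides)
    return VQVAEConfig(**overrides)


def loss_weights_from(cfg: dict) -> LossWeights:
    return LossWeights(**cfg["vqvae"]["weights"])


def seq_config_from(cfg: dict, grid_dims: tuple, num_tokens: int) -> SeqModelConfig:
    section = cfg["seq_model"]
    overrides = dict(section.get("overrides") or {})
    overrides["grid_dims"] = tuple(overrides.get("grid_dims", grid_dims))
    overrides.setdefault("num_tokens", num_tokens)
    overrides.setdefault("seed", int(cfg["seed"]))
    if section.get("profile", "desk") == "desk":
        return SeqModelConfig.desk(**overrides)
    return SeqModelConfig(**overrides)


def write_manifest(out_dir: str | Path):
    """Checksum every file in the directory (for rerun comparisons)."""
    out_dir = Path(out_dir)
    entries = {}
    for f in sorted(out_dir.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            entries[str(f.relative_to(out_dir))] = hashlib.sha256(
                f.read_bytes()).hexdigest()
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(entries, fh, indent=2)
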