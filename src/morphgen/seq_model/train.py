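"""Transformer training loop and checkpointing."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from ..autodiff import Adam
from ..phantoms.augment import AugmentBounds, augment, identity_params, sample_augmentation_params
from ..vqvae.train import TrainLog, volumes_to_batch
from .conditioning import ConditioningSet, CovariateStats, conditioning_from_record
from .model import SeqModelConfig, TokenTransformer, sequence_nll
from .raster import rasterize


def train_transformer_on_tokens(
    sequences: np.ndarray,
    csets: list[ConditioningSet],
    model: TokenTransformer,
    steps: int,
    seed: int = 0,
    log: TrainLog | None = None,
) -> TrainLog:
    """Fit fixed raster sequences (B, L); used by overfit sanity checks."""
    sequences = np.asarray(sequences)
    n = sequences.shape[0]
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=model.cfg.lr)
    log = log or TrainLog()
    batch = min(model.cfg.batch_size, n)
    for step in range(steps):
        idx = rng.choice(n, size=batch, replace=False)
        nll = sequence_nll(sequences[idx], [csets[i] for i in idx], model)
        opt.zero_grad()
        nll.backward()
        opt.step()
        log.append(step=step, nll=nll.item())
    return log


def train_transformer(
    volumes,
    vqvae,
    cfg: SeqModelConfig,
    steps: int,
    seed: int = 0,
    use_augmentation: bool = True,
    bounds: AugmentBounds | None = None,
    model: TokenTransformer | None = None,
    log: TrainLog | None = None,
) -> tuple[TokenTransformer, CovariateStats, TrainLog]:
    """Second-stage training on a volume corpus with an existing VQ-VAE.

    Tokens are computed on the fly so augmented volumes pass through the
    encoder and quantizer before flattening; the sampled augmentation
    parameters join the conditioning set.
    """
    records = [v.covariates for v in volumes]
    if any(r is None for r in records):
        raise ValueError("all volumes need covariate records")
    stats = CovariateStats.from_records(records)
    if model is None:
        model = TokenTransformer(cfg, stats, np.random.default_rng(cfg.seed))
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    log = log or TrainLog()
    n = len(volumes)
    batch = min(cfg.batch_size, n)

    # cache unaugmented tokens; augmented batches are re-encoded per step
    base_tokens = None
    if not use_augmentation:
        base_tokens = vqvae.tokens_for(volumes_to_batch(volumes))

    for step in range(steps):
        idx = rng.choice(n, size=batch, replace=False)
        if use_augmentation:
            aug_vols, params = [], []
            for i in idx:
                p = sample_augmentation_params(rng, bounds)
                av, p = augment(volumes[i], params=p, bounds=bounds)
                aug_vols.append(av)
                params.append(p)
            tokens = vqvae.tokens_for(volumes_to_batch(aug_vols))
            csets = [conditioning_from_record(records[i], aug_params=p)
                     for i, p in zip(idx, params)]
        else:
            tokens = base_tokens[idx]
            csets = [conditioning_from_record(records[i]) for i in idx]
        seqs = np.stack([rasterize(t) for t in tokens])
        nll = sequence_nll(seqs, csets, model)
        opt.zero_grad()
        nll.backward()
        opt.step()
        log.append(step=step, nll=nll.item())
    return model, stats, log


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------


def save_transformer(path: str | Path, model: TokenTransformer,
                     extra: dict | None = None):
    arrays = {f"w/{k}": v for k, v in model.state_dict().items()}
    meta = {
        "config": asdict(model.cfg),
        "stats": {"means": model.cond_embedder.stats.means,
                  "sds": model.cond_embedder.stats.sds},
        "extra": extra or {},
    }
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta, default=str).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_transformer(path: str | Path) -> tuple[TokenTransformer, dict]:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta_json"]).decode())
        cfg_dict = dict(meta["config"])
        cfg_dict["grid_dims"] = tuple(cfg_dict["grid_dims"])
        cfg = SeqModelConfig(**cfg_dict)
        stats = CovariateStats(means=meta["stats"]["means"],
                               sds=meta["stats"]["sds"])
        model = TokenTransformer(cfg, stats, np.random.default_rng(cfg.seed))
        model.load_state_dict(
            {k[len("w/"):]: npz[k] for k in npz.files if k.startswith("w/")})
    return model, meta
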