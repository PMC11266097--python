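"""Ancestral sampling of token sequences and volume generation.

Sampling is plain ancestral by default: one token per raster position, drawn
from the full predictive distribution at temperature 1.  Temperature and
top-k knobs exist but are off unless set in the config.
"""

from __future__ import annotations

import numpy as np

from ..autodiff import no_grad
from ..phantoms.spec import Volume
from .conditioning import ConditioningSet
from .model import TokenTransformer
from .raster import derasterize


def _draw(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Vectorized categorical draw, one per row."""
    cum = probs.cumsum(axis=1)
    cum[:, -1] = 1.0
    u = rng.random((probs.shape[0], 1))
    return (u > cum).sum(axis=1)


def sample_sequence(csets: list[ConditioningSet] | ConditioningSet,
                    model: TokenTransformer, seed: int,
                    num_positions: int | None = None) -> np.ndarray:
    """Sample raster sequences token by token; (B, L) array in [0, M).

    Deterministic given (model, conditionings, seed).
    """
    if isinstance(csets, ConditioningSet):
        csets = [csets]
    cfg = model.cfg
    L = num_positions or cfg.sequence_length
    b = len(csets)
    rng = np.random.default_rng(seed)
    seq = np.full((b, 1), cfg.bos, dtype=np.int64)
    memories = None
    with no_grad():
        for _ in range(L):
            if cfg.recurrence:
                logits, hidden = model.forward(seq, csets, memories=memories,
                                               collect_hidden=True)
                memories = model.recurrence_memories(
                    [h.detach() for h in hidden])
            else:
                logits = model.forward(seq, csets)
            last = logits.data[:, -1, :]
            if cfg.temperature != 1.0:
                last = last / cfg.temperature
            if cfg.top_k:
                kth = np.partition(last, -cfg.top_k, axis=1)[:, -cfg.top_k][:, None]
                last = np.where(last < kth, -np.inf, last)
            last = last - last.max(axis=1, keepdims=True)
            p = np.exp(last)
            p /= p.sum(axis=1, keepdims=True)
            nxt = _draw(rng, p)
            seq = np.concatenate([seq, nxt[:, None]], axis=1)
    return seq[:, 1:]


def generate_volume(csets, vqvae, model: TokenTransformer, seed: int,
                    spacing: tuple = (1.0, 1.0, 1.0)) -> list[Volume]:
    """Full purple-path inference: sample tokens, reshape to the grid, pull
    codebook vectors and decode; intensities clipped to the [0, 1] window."""
    single = isinstance(csets, ConditioningSet)
    if single:
        csets = [csets]
    seqs = sample_sequence(csets, model, seed)
    grids = np.stack([derasterize(s, model.cfg.grid_dims) for s in seqs])
    recon = vqvae.decode_tokens(grids)  # (B, 1, H, W, D)
    out = [Volume(np.clip(recon[i, 0], 0.0, 1.0), spacing=spacing)
           for i in range(len(csets))]
    return out
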