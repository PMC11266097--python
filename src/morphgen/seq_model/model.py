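"""Causal transformer over raster token sequences.

Architecture: pre-RMSNorm blocks; self-attention layers carry a causal mask
plus the 3D relative positional bias; every other layer (odd indices by
default) cross-attends to the conditioning tokens instead (no causal mask,
no positional bias there); attention outputs are folded in through learned
sigmoid gates; a plain-residual feed-forward follows every attention block.

"Enhanced recurrence" (sampling-time only): layer l may additionally attend
over the hidden states that layer l+1 produced at the previous sampling step
(the last layer wraps to itself); with it disabled the model is a plain
causal transformer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..autodiff import Tensor
from ..nn import Embedding, Linear, Module
from .conditioning import ConditioningEmbedder, ConditioningSet, CovariateStats
from .layers import GateUnit, RelPosBias3D, RMSNorm, attention


@dataclass(frozen=True)
class SeqModelConfig:
    """Full-scale reference defaults: 24 layers, width 512,
    16 heads, sequence length 1,400 (10x14x10 grid), Adam lr 0.0005,
    batch size 3."""

    grid_dims: tuple = (10, 14, 10)
    num_tokens: int = 256
    layers: int = 24
    width: int = 512
    heads: int = 16
    ff_mult: int = 4
    cross_attention_parity: int = 1
    bias_combine: str = "product"
    recurrence: bool = False
    temperature: float = 1.0
    top_k: int = 0
    lr: float = 0.0005
    batch_size: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.width % self.heads:
            raise ValueError("width must be divisible by heads")

    @property
    def sequence_length(self) -> int:
        return int(np.prod(self.grid_dims))

    @property
    def bos(self) -> int:
        return self.num_tokens

    @classmethod
    def desk(cls, **overrides) -> "SeqModelConfig":
        base = dict(grid_dims=(2, 2, 2), num_tokens=64, layers=4, width=64,
                    heads=4, batch_size=8, lr=0.003)
        base.update(overrides)
        return cls(**base)


def _split_heads(x: Tensor, heads: int) -> Tensor:
    b, t, w = x.shape
    return x.reshape(b, t, heads, w // heads).transpose(0, 2, 1, 3)


def _merge_heads(x: Tensor) -> Tensor:
    b, h, t, d = x.shape
    return x.transpose(0, 2, 1, 3).reshape(b, t, h * d)


class SelfAttnBlock(Module):
    def __init__(self, cfg: SeqModelConfig, rng: np.random.Generator):
        w = cfg.width
        self.heads = cfg.heads
        self.norm = RMSNorm(w)
        self.wq = Linear(w, w, rng)
        self.wk = Linear(w, w, rng)
        self.wv = Linear(w, w, rng)
        self.wo = Linear(w, w, rng)
        self.bias = RelPosBias3D(cfg.grid_dims, cfg.heads, rng, cfg.bias_combine)
        self.gate = GateUnit(w, rng)

    def forward(self, x: Tensor, memory: Tensor | None = None) -> Tensor:
        t = x.shape[1]
        h = self.norm(x)
        q = _split_heads(self.wq(h), self.heads)
        if memory is not None:
            ctx = Tensor.concat([self.norm(memory), h], axis=1)
        else:
            ctx = h
        k = _split_heads(self.wk(ctx), self.heads)
        v = _split_heads(self.wv(ctx), self.heads)
        causal = np.tril(np.ones((t, t), dtype=bool))
        # bias covers the current sequence prefix only (position 0 is bos:
        # give it offset-0 bias by shifting the grid bias by one)
        bias_full = self.bias(length=t)  # (heads, t, t) over raster prefix
        if memory is not None:
            tm = memory.shape[1]
            mask = np.concatenate(
                [np.ones((t, tm), dtype=bool), causal], axis=1
            )
            zeros = Tensor(np.zeros((self.heads, t, tm)))
            bias_cat = Tensor.concat([zeros, bias_full], axis=2)
            out = attention(q, k, v, mask=mask, bias=bias_cat)
        else:
            out = attention(q, k, v, mask=causal, bias=bias_full)
        sub = self.wo(_merge_heads(out))
        return self.gate(x, sub)


class CrossAttnBlock(Module):
    """Keys/values come from the conditioning tokens: no mask, no bias."""

    def __init__(self, cfg: SeqModelConfig, rng: np.random.Generator):
        w = cfg.width
        self.heads = cfg.heads
        self.norm = RMSNorm(w)
        self.wq = Linear(w, w, rng)
        self.wk = Linear(w, w, rng)
        self.wv = Linear(w, w, rng)
        self.wo = Linear(w, w, rng)
        self.gate = GateUnit(w, rng)

    def forward(self, x: Tensor, cond: Tensor) -> Tensor:
        q = _split_heads(self.wq(self.norm(x)), self.heads)
        k = _split_heads(self.wk(cond), self.heads)
        v = _split_heads(self.wv(cond), self.heads)
        sub = self.wo(_merge_heads(attention(q, k, v)))
        return self.gate(x, sub)


class FeedForward(Module):
    def __init__(self, cfg: SeqModelConfig, rng: np.random.Generator):
        w = cfg.width
        self.norm = RMSNorm(w)
        self.up = Linear(w, w * cfg.ff_mult, rng)
        self.down = Linear(w * cfg.ff_mult, w, rng)

    def forward(self, x: Tensor) -> Tensor:
        return x + self.down(self.up(self.norm(x)).relu())


class TransformerLayer(Module):
    def __init__(self, cfg: SeqModelConfig, rng: np.random.Generator, cross: bool):
        self.cross = cross
        self.attn = CrossAttnBlock(cfg, rng) if cross else SelfAttnBlock(cfg, rng)
        self.ff = FeedForward(cfg, rng)

    def forward(self, x: Tensor, cond: Tensor, memory: Tensor | None = None) -> Tensor:
        if self.cross:
            h = self.attn(x, cond)
        else:
            h = self.attn(x, memory=memory)
        return self.ff(h)


class TokenTransformer(Module):
    def __init__(self, cfg: SeqModelConfig, stats: CovariateStats,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.embed = Embedding(cfg.num_tokens + 1, cfg.width, rng)  # + bos
        self.cond_embedder = ConditioningEmbedder(cfg.width, stats, rng)
        self.blocks = [
            TransformerLayer(cfg, rng, cross=(i % 2 == cfg.cross_attention_parity))
            for i in range(cfg.layers)
        ]
        self.final_norm = RMSNorm(cfg.width)
        self.head = Linear(cfg.width, cfg.num_tokens, rng)

    # ------------------------------------------------------------------

    def _validate(self, tokens: np.ndarray):
        cfg = self.cfg
        if tokens.ndim != 2:
            raise ValueError("tokens must be (batch, length)")
        if tokens.shape[1] > cfg.sequence_length + 1:
            raise ValueError("sequence longer than configured maximum")
        if (tokens[:, 0] != cfg.bos).any():
            raise ValueError("sequences must start with the bos token")
        body = tokens[:, 1:]
        if body.size and ((body < 0) | (body >= cfg.num_tokens)).any():
            raise ValueError("token id out of range")

    def forward(self, tokens: np.ndarray, csets: list[ConditioningSet],
                memories: list | None = None, collect_hidden: bool = False):
        """Token ids (B, T), bos first -> logits Tensor (B, T, M).

        ``memories``: per-layer (B, Tm, width) hidden states from the
        previous sampling step (enhanced recurrence), or None.
        Position j's logits depend only on tokens <= j and the conditioning.
        """
        tokens = np.asarray(tokens)
        self._validate(tokens)
        cond = self.cond_embedder(csets)
        x = self.embed(tokens)
        hidden = []
        for i, block in enumerate(self.blocks):
            mem = None
            if memories is not None and not block.cross:
                mem = memories[i]
            x = block(x, cond, memory=mem)
            if collect_hidden:
                hidden.append(x)
        logits = self.head(self.final_norm(x))
        return (logits, hidden) if collect_hidden else logits

    def recurrence_memories(self, hidden: list) -> list:
        """Shift hidden states down one layer: layer l gets layer l+1's
        output from the previous step; the last layer wraps to itself."""
        n = len(hidden)
        return [hidden[min(i + 1, n - 1)] for i in range(n)]


def next_token_logits(seq: np.ndarray, cset: ConditioningSet,
                      model: TokenTransformer) -> np.ndarray:
    """Logits (T, M) for a single bos-prefixed sequence (no grad)."""
    from ..autodiff import no_grad

    seq = np.asarray(seq)
    with no_grad():
        out = model.forward(seq[None, :], [cset])
    return out.data[0]


def sequence_nll(tokens: np.ndarray, csets: list[ConditioningSet],
                 model: TokenTransformer) -> Tensor:
    """Mean cross-entropy of the true tokens under the model.

    ``tokens``: (B, L) raster sequences *without* bos; the model input is
    [bos, t_0 .. t_{L-2}] so position j predicts t_j.
    """
    tokens = np.asarray(tokens)
    b, length = tokens.shape
    inp = np.concatenate(
        [np.full((b, 1), model.cfg.bos, dtype=np.int64), tokens[:, :-1]], axis=1
    )
    logits = model.forward(inp, csets)
    logp = logits.log_softmax(-1)
    picked = logp[np.arange(b)[:, None], np.arange(length)[None, :], tokens]
    return -picked.mean()
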