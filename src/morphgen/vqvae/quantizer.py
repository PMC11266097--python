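"""Vector quantization with an exponential-moving-average codebook.

The codebook is learned online, not by gradient: per update step, per code i,

    N_i <- N_i * gamma + n_i * (1 - gamma)
    m_i <- m_i * gamma + (sum of latents assigned to i) * (1 - gamma)
    e_i <- m_i / max(N_i, epsilon)

where n_i counts the latent vectors assigned to code i this step.  The
encoder is tied to its assignments by the beta-weighted commitment loss.
"""

from __future__ import annotations

import numpy as np

from ..autodiff import Tensor

__all__ = [
    "Codebook",
    "nearest_assign",
    "ema_update",
    "quantization_loss",
    "codebook_perplexity",
]


class Codebook:
    """M embedding vectors with EMA accumulators.

    Default decay gamma = 0.25, commitment beta = 0.5.
    """

    def __init__(self, num_codes: int, dim: int, decay: float = 0.25,
                 commitment: float = 0.5, epsilon: float = 1e-5,
                 rng: np.random.Generator | None = None):
        if num_codes < 2:
            raise ValueError("codebook needs at least 2 codes")
        rng = rng or np.random.default_rng(0)
        self.vectors = rng.normal(0.0, 1.0, size=(num_codes, dim))
        self.ema_counts = np.ones(num_codes)
        self.ema_sums = self.vectors.copy()
        self.decay = decay
        self.commitment = commitment
        self.epsilon = epsilon

    @property
    def num_codes(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def init_from_latents(self, latents: np.ndarray, rng: np.random.Generator):
        """Seed the codebook with i.i.d. samples of encoder outputs (scale match)."""
        flat = latents.reshape(-1, self.dim)
        idx = rng.choice(flat.shape[0], size=self.num_codes,
                         replace=flat.shape[0] < self.num_codes)
        self.vectors = flat[idx].copy()
        self.ema_counts = np.ones(self.num_codes)
        self.ema_sums = self.vectors.copy()

    def reseed_dead(self, latents: np.ndarray, rng: np.random.Generator,
                    floor: float = 1e-3) -> int:
        """Reseed codes whose EMA count fell below ``floor``.

        Dead codes get a random encoder output; returns how many were reseeded.
        """
        dead = np.flatnonzero(self.ema_counts < floor)
        if dead.size == 0:
            return 0
        flat = latents.reshape(-1, self.dim)
        idx = rng.choice(flat.shape[0], size=dead.size, replace=flat.shape[0] < dead.size)
        self.vectors[dead] = flat[idx]
        self.ema_sums[dead] = flat[idx]
        self.ema_counts[dead] = 1.0
        return int(dead.size)

    def state_dict(self) -> dict:
        return {
            "vectors": self.vectors.copy(),
            "ema_counts": self.ema_counts.copy(),
            "ema_sums": self.ema_sums.copy(),
            "decay": self.decay,
            "commitment": self.commitment,
            "epsilon": self.epsilon,
        }

    @classmethod
    def from_state(cls, state: dict) -> "Codebook":
        vec = np.asarray(state["vectors"], dtype=np.float64)
        cb = cls(vec.shape[0], vec.shape[1], decay=float(state["decay"]),
                 commitment=float(state["commitment"]), epsilon=float(state["epsilon"]))
        cb.vectors = vec.copy()
        cb.ema_counts = np.asarray(state["ema_counts"], dtype=np.float64).copy()
        cb.ema_sums = np.asarray(state["ema_sums"], dtype=np.float64).copy()
        return cb


def nearest_assign(z: np.ndarray, cb: Codebook) -> tuple[np.ndarray, np.ndarray]:
    """Assign every latent vector to its nearest codebook row.

    ``z`` has shape (..., n_z).  Returns (quantized, tokens) where quantized
    values are copied from the codebook and ties break to the lowest index
    (argmin semantics).
    """
    z = np.asarray(z, dtype=np.float64)
    if not np.all(np.isfinite(z)):
        raise ValueError("latents must be finite")
    if z.shape[-1] != cb.dim:
        raise ValueError(f"latent dim {z.shape[-1]} != codebook dim {cb.dim}")
    flat = z.reshape(-1, cb.dim)
    # squared distances via expansion; argmin is tie-stable (lowest index)
    d2 = (
        (flat**2).sum(axis=1, keepdims=True)
        - 2.0 * flat @ cb.vectors.T
        + (cb.vectors**2).sum(axis=1)
    )
    tokens = np.argmin(d2, axis=1)
    quantized = cb.vectors[tokens].reshape(z.shape)
    return quantized, tokens.reshape(z.shape[:-1])


def ema_update(cb: Codebook, z: np.ndarray, tokens: np.ndarray) -> Codebook:
    """One EMA step over the batch of latents; updates ``cb`` in place."""
    flat = np.asarray(z, dtype=np.float64).reshape(-1, cb.dim)
    tok = np.asarray(tokens).reshape(-1)
    g = cb.decay
    counts = np.bincount(tok, minlength=cb.num_codes).astype(np.float64)
    sums = np.zeros_like(cb.ema_sums)
    np.add.at(sums, tok, flat)
    cb.ema_counts = cb.ema_counts * g + counts * (1.0 - g)
    cb.ema_sums = cb.ema_sums * g + sums * (1.0 - g)
    cb.vectors = cb.ema_sums / np.maximum(cb.ema_counts, cb.epsilon)[:, None]
    return cb


def quantization_loss(z, z_q, beta: float):
    """Commitment term beta * mean ||sg[Z_q] - Z||^2.

    The codebook-pull term of the original two-part quantization objective is
    handled by the EMA update, so only the commitment half appears here and
    the gradient flows to the encoder alone.  ``z`` may be a Tensor (graph
    kept) or an array.
    """
    zq = z_q.data if isinstance(z_q, Tensor) else np.asarray(z_q)
    if isinstance(z, Tensor):
        if z.data.shape != zq.shape:
            raise ValueError("z and z_q shapes differ")
        diff = z - Tensor(zq)
        return (diff * diff).mean() * beta
    z = np.asarray(z)
    if z.shape != zq.shape:
        raise ValueError("z and z_q shapes differ")
    return Tensor(beta * np.mean((z - zq) ** 2))


def codebook_perplexity(tokens: np.ndarray, num_codes: int) -> float:
    """exp(entropy) of empirical code usage; 1 = collapsed, M = uniform."""
    tok = np.asarray(tokens).reshape(-1)
    if tok.size == 0:
        raise ValueError("need at least one token")
    p = np.bincount(tok, minlength=num_codes) / tok.size
    nz = p[p > 0]
    return float(np.exp(-(nz * np.log(nz)).sum()))
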