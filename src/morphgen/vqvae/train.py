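"""VQ-VAE training loop, logging and checkpointing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from ..autodiff import Adam, Tensor, no_grad
from .losses import (
    LossWeights,
    discriminator_loss,
    generator_adv_loss,
    loss_freq,
    loss_pcp,
    loss_pix,
    total_vqvae_loss,
)
from .model import VQVAE, PatchDiscriminator, VQVAEConfig
from .quantizer import codebook_perplexity, ema_update, quantization_loss


class TrainLog:
    """Per-step loss records, serializable as line-delimited JSON."""

    def __init__(self):
        self.rows: list[dict] = []

    def append(self, **row):
        self.rows.append({k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                          for k, v in row.items()})

    def save(self, path: str | Path):
        with open(path, "w") as fh:
            for row in self.rows:
                fh.write(json.dumps(row) + "\n")

    def series(self, key: str) -> np.ndarray:
        return np.array([r[key] for r in self.rows if key in r])


def config_hash(cfg) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def volumes_to_batch(volumes) -> np.ndarray:
    """List of Volume (or 3D arrays) -> (N, 1, H, W, D) float array."""
    arrs = [v.data if hasattr(v, "data") else np.asarray(v) for v in volumes]
    return np.stack(arrs)[:, None, :, :, :].astype(np.float64)


def train_vqvae(
    volumes,
    cfg: VQVAEConfig,
    steps: int = 200,
    weights: LossWeights = LossWeights(),
    seed: int = 0,
    reseed_every: int = 50,
    model: VQVAE | None = None,
    disc: PatchDiscriminator | None = None,
    log: TrainLog | None = None,
) -> tuple[VQVAE, PatchDiscriminator | None, TrainLog]:
    """Train on a fixed corpus of volumes for ``steps`` optimizer steps.

    The adversarial pair is only exercised when ``weights.alpha_dis > 0``;
    every loss component is logged separately per step.
    """
    x_all = volumes_to_batch(volumes)
    n = x_all.shape[0]
    rng = np.random.default_rng(seed)
    if model is None:
        model = VQVAE(cfg, np.random.default_rng(cfg.seed))
        with no_grad():
            z0 = model.encode(Tensor(x_all[: min(n, cfg.batch_size)]))
        model.codebook.init_from_latents(z0.data, rng)
    use_adv = weights.alpha_dis > 0
    if use_adv and disc is None:
        disc = PatchDiscriminator(cfg, np.random.default_rng(cfg.seed + 1))

    gen_params = model.encoder.parameters() + model.decoder.parameters()
    opt_g = Adam(gen_params, lr=cfg.lr)
    opt_d = Adam(disc.parameters(), lr=cfg.lr_disc) if use_adv else None
    log = log or TrainLog()

    batch = min(cfg.batch_size, n)
    for step in range(steps):
        idx = rng.choice(n, size=batch, replace=False)
        x = Tensor(x_all[idx])

        z = model.encode(x)
        q_st, tokens = model.quantize(z)
        ema_update(model.codebook, z.data, tokens)
        x_hat = model.decode(q_st)

        l_quant = quantization_loss(z, Tensor(q_st.data), model.codebook.commitment)
        l_pix = loss_pix(x, x_hat)
        l_freq = loss_freq(x, x_hat)
        l_pcp = loss_pcp(x, x_hat, seed=seed * 100003 + step)
        if use_adv:
            fake_scores = disc(x_hat)
            l_adv = generator_adv_loss(fake_scores)
        else:
            l_adv = Tensor(0.0)
        total = total_vqvae_loss(l_quant, l_pix, l_freq, l_pcp, l_adv, weights)

        opt_g.zero_grad()
        if use_adv:
            for p in disc.parameters():
                p.grad = None
        total.backward()
        opt_g.step()

        l_disc = 0.0
        if use_adv:
            real_scores = disc(x)
            fake_scores_d = disc(Tensor(x_hat.data))
            d_loss = discriminator_loss(real_scores, fake_scores_d)
            opt_d.zero_grad()
            d_loss.backward()
            opt_d.step()
            l_disc = d_loss.item()

        if reseed_every and (step + 1) % reseed_every == 0:
            model.codebook.reseed_dead(z.data, rng)

        log.append(
            step=step,
            loss_total=total.item(),
            loss_quant=l_quant.item(),
            loss_pix=l_pix.item(),
            loss_freq=l_freq.item(),
            loss_pcp=l_pcp.item(),
            loss_adv=l_adv.item(),
            loss_disc=l_disc,
            perplexity=codebook_perplexity(tokens, cfg.num_codes),
        )
    return model, disc, log


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(path: str | Path, model: VQVAE,
                    disc: PatchDiscriminator | None = None,
                    extra: dict | None = None):
    """Single-archive checkpoint: weights, codebook accumulators, config."""
    arrays = {}
    for name, arr in model.encoder.state_dict().items():
        arrays[f"enc/{name}"] = arr
    for name, arr in model.decoder.state_dict().items():
        arrays[f"dec/{name}"] = arr
    if disc is not None:
        for name, arr in disc.state_dict().items():
            arrays[f"disc/{name}"] = arr
    cb = model.codebook.state_dict()
    arrays["cb/vectors"] = cb["vectors"]
    arrays["cb/ema_counts"] = cb["ema_counts"]
    arrays["cb/ema_sums"] = cb["ema_sums"]
    meta = {
        "config": asdict(model.cfg),
        "config_hash": config_hash(model.cfg),
        "codebook": {k: cb[k] for k in ("decay", "commitment", "epsilon")},
        "has_disc": disc is not None,
        "extra": extra or {},
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta, default=str).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path):
    """Restore (model, disc or None, meta) with bit-identical forward passes."""
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta_json"]).decode())
        cfg_dict = dict(meta["config"])
        for key in ("channels", "disc_channels"):
            cfg_dict[key] = tuple(cfg_dict[key])
        cfg = VQVAEConfig(**cfg_dict)
        model = VQVAE(cfg, np.random.default_rng(cfg.seed))
        model.encoder.load_state_dict(
            {k[len("enc/"):]: npz[k] for k in npz.files if k.startswith("enc/")})
        model.decoder.load_state_dict(
            {k[len("dec/"):]: npz[k] for k in npz.files if k.startswith("dec/")})
        cb_state = {
            "vectors": npz["cb/vectors"],
            "ema_counts": npz["cb/ema_counts"],
            "ema_sums": npz["cb/ema_sums"],
            **meta["codebook"],
        }
        from .quantizer import Codebook

        model.codebook = Codebook.from_state(cb_state)
        disc = None
        if meta["has_disc"]:
            disc = PatchDiscriminator(cfg, np.random.default_rng(cfg.seed + 1))
            disc.load_state_dict(
                {k[len("disc/"):]: npz[k] for k in npz.files if k.startswith("disc/")})
    return model, disc, meta
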