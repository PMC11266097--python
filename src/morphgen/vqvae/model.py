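"""Encoder / decoder / patch discriminator and the assembled VQ-VAE."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..autodiff import Tensor, no_grad
from ..nn import Conv3d, ConvTranspose3d, InstanceNorm3d, Module
from .quantizer import Codebook, nearest_assign


@dataclass(frozen=True)
class VQVAEConfig:
    """Architecture and training configuration.

    Full-scale reference defaults: four stride-2 downsamplings with 128 feature maps
    until the last level (256 there), latent feature size 32, learning rates
    0.000165 (enc/dec) and 0.00005 (discriminator), batch 8, gamma 0.25,
    beta 0.5.  ``desk()`` shrinks widths for CPU-sized experiments.
    """

    levels: int = 4
    channels: tuple = (128, 128, 128, 256)
    n_z: int = 32
    num_codes: int = 256
    gamma: float = 0.25
    beta: float = 0.5
    epsilon: float = 1e-5
    lr: float = 0.000165
    lr_disc: float = 0.00005
    batch_size: int = 8
    disc_channels: tuple = (32, 64, 128)
    seed: int = 0

    def __post_init__(self):
        if len(self.channels) != self.levels:
            raise ValueError("channels must list one width per level")

    @classmethod
    def desk(cls, **overrides) -> "VQVAEConfig":
        base = dict(levels=4, channels=(12, 16, 20, 24), n_z=8, num_codes=64,
                    disc_channels=(8, 12, 16))
        base.update(overrides)
        return cls(**base)

    @property
    def downsample_factor(self) -> int:
        return 2**self.levels

    def latent_shape(self, input_shape: tuple) -> tuple:
        """Shape contract of the encoder: (H, W, D) -> (h, w, d, n_z)."""
        f = self.downsample_factor
        bad = [n for n in input_shape if n % f]
        if bad:
            raise ValueError(
                f"input shape {tuple(input_shape)} not divisible by 2^{self.levels}")
        return tuple(n // f for n in input_shape) + (self.n_z,)

    def output_shape(self, latent_spatial: tuple) -> tuple:
        """Shape contract of the decoder: (h, w, d) -> (H, W, D)."""
        f = self.downsample_factor
        return tuple(n * f for n in latent_spatial)


class Encoder(Module):
    """Stride-2 conv stack; spatial dims shrink by 2^levels, channels -> n_z."""

    def __init__(self, cfg: VQVAEConfig, rng: np.random.Generator):
        self.cfg = cfg
        chans = (1,) + tuple(cfg.channels)
        self.convs = [
            Conv3d(chans[i], chans[i + 1], 4, rng, stride=2, pad=1)
            for i in range(cfg.levels)
        ]
        self.norms = [InstanceNorm3d(c) for c in cfg.channels]
        self.proj = Conv3d(cfg.channels[-1], cfg.n_z, 3, rng, stride=1, pad=1)

    def forward(self, x: Tensor) -> Tensor:
        f = self.cfg.downsample_factor
        bad = [n for n in x.shape[2:] if n % f]
        if bad:
            raise ValueError(
                f"input spatial shape {x.shape[2:]} not divisible by 2^{self.cfg.levels}"
            )
        h = x
        for conv, norm in zip(self.convs, self.norms):
            h = norm(conv(h)).leaky_relu(0.2)
        return self.proj(h)


class Decoder(Module):
    """Mirror of the encoder; linear output head (intensities are MSE targets,
    a squashing nonlinearity saturates and stalls the toy-scale runs)."""

    def __init__(self, cfg: VQVAEConfig, rng: np.random.Generator):
        self.cfg = cfg
        chans = tuple(reversed(cfg.channels)) + (1,)
        self.proj = Conv3d(cfg.n_z, chans[0], 3, rng, stride=1, pad=1)
        self.deconvs = [
            ConvTranspose3d(chans[i], chans[i + 1], 4, rng, stride=2, pad=1)
            for i in range(cfg.levels)
        ]
        self.norms = [InstanceNorm3d(c) for c in chans[1:-1]]

    def forward(self, q: Tensor) -> Tensor:
        h = self.proj(q).leaky_relu(0.2)
        for i, deconv in enumerate(self.deconvs):
            h = deconv(h)
            if i < len(self.deconvs) - 1:
                h = self.norms[i](h).leaky_relu(0.2)
        return h


class PatchDiscriminator(Module):
    """3D patch discriminator: 3 stride-2 levels, per-patch logits."""

    def __init__(self, cfg: VQVAEConfig, rng: np.random.Generator):
        chans = (1,) + tuple(cfg.disc_channels)
        self.convs = [
            Conv3d(chans[i], chans[i + 1], 4, rng, stride=2, pad=1)
            for i in range(len(cfg.disc_channels))
        ]
        self.head = Conv3d(chans[-1], 1, 3, rng, stride=1, pad=1)

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for conv in self.convs:
            h = conv(h).leaky_relu(0.2)
        return self.head(h)


class VQVAE(Module):
    """Encoder + EMA codebook + decoder with straight-through quantization."""

    def __init__(self, cfg: VQVAEConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.encoder = Encoder(cfg, rng)
        self.decoder = Decoder(cfg, rng)
        self.codebook = Codebook(cfg.num_codes, cfg.n_z, decay=cfg.gamma,
                                 commitment=cfg.beta, epsilon=cfg.epsilon, rng=rng)

    # volumes are handled in NCHWD; latents channel-last (..., n_z) for the
    # quantizer, matching the h x w x d x n_z latent layout

    def encode(self, x: Tensor | np.ndarray) -> Tensor:
        """(N,1,H,W,D) -> latent (N, h, w, d, n_z)."""
        if not isinstance(x, Tensor):
            x = Tensor(x)
        z = self.encoder(x)  # (N, n_z, h, w, d)
        return z.transpose(0, 2, 3, 4, 1)

    def quantize(self, z: Tensor | np.ndarray):
        """Latent -> (straight-through quantized Tensor, tokens array)."""
        z_arr = z.data if isinstance(z, Tensor) else np.asarray(z)
        z_q, tokens = nearest_assign(z_arr, self.codebook)
        if isinstance(z, Tensor) and z.requires_grad:
            # straight-through: forward value z_q, gradient copied to z
            st = z + Tensor(z_q - z_arr)
        else:
            st = Tensor(z_q)
        return st, tokens

    def decode(self, q: Tensor | np.ndarray) -> Tensor:
        """(N, h, w, d, n_z) quantized latent -> (N,1,H,W,D) reconstruction."""
        if not isinstance(q, Tensor):
            q = Tensor(q)
        return self.decoder(q.transpose(0, 4, 1, 2, 3))

    def decode_tokens(self, tokens: np.ndarray) -> np.ndarray:
        """Token grid (N, h, w, d) -> reconstructed volumes, no grad."""
        with no_grad():
            q = self.codebook.vectors[np.asarray(tokens)]
            return self.decode(Tensor(q)).data

    def forward(self, x):
        z = self.encode(x)
        q, tokens = self.quantize(z)
        return self.decode(q), z, q, tokens

    def tokens_for(self, x: np.ndarray) -> np.ndarray:
        """Volumes (N,1,H,W,D) -> token grids (N, h, w, d), no grad."""
        with no_grad():
            z = self.encode(Tensor(x))
        _, tokens = nearest_assign(z.data, self.codebook)
        return tokens
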