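"""Small-affine augmentation with recorded parameters.

The sampled parameter vector is returned alongside the transformed volume so
it can be appended to the conditioning set during sequence-model training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .spec import Volume

#: parameter vector layout
PARAM_NAMES = ("rot_x", "rot_y", "rot_z", "scale", "shift_x", "shift_y", "shift_z")


@dataclass(frozen=True)
class AugmentBounds:
    max_rotation_deg: float = 5.0
    scale_range: tuple = (0.98, 1.02)
    max_translation_vox: float = 2.0


def identity_params() -> np.ndarray:
    """Parameters of the identity transform (used at inference)."""
    return np.array([0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0])


def sample_augmentation_params(
    rng: np.random.Generator, bounds: AugmentBounds | None = None
) -> np.ndarray:
    b = bounds or AugmentBounds()
    rot = rng.uniform(-b.max_rotation_deg, b.max_rotation_deg, size=3)
    scale = rng.uniform(*b.scale_range)
    shift = rng.uniform(-b.max_translation_vox, b.max_translation_vox, size=3)
    return np.concatenate([rot, [scale], shift])


def _rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """Compose intrinsic rotations (degrees) about the three axes."""
    a, b, c = np.deg2rad([rx, ry, rz])
    Rx = np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]])
    Ry = np.array([[np.cos(b), 0, np.sin(b)], [0, 1, 0], [-np.sin(b), 0, np.cos(b)]])
    Rz = np.array([[np.cos(c), -np.sin(c), 0], [np.sin(c), np.cos(c), 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def augment(
    v: Volume,
    params: np.ndarray | None = None,
    seed: int | None = None,
    bounds: AugmentBounds | None = None,
) -> tuple[Volume, np.ndarray]:
    """Apply a small affine transform; returns (volume, parameters used).

    Either pass ``params`` explicitly or a ``seed`` to sample them.  Out of
    bounds parameters are clamped.  Identity parameters return the input
    data unchanged (no interpolation).
    """
    b = bounds or AugmentBounds()
    if params is None:
        if seed is None:
            raise ValueError("provide params or seed")
        params = sample_augmentation_params(np.random.default_rng(seed), b)
    params = np.asarray(params, dtype=float).copy()
    params[:3] = np.clip(params[:3], -b.max_rotation_deg, b.max_rotation_deg)
    params[3] = np.clip(params[3], *b.scale_range)
    params[4:] = np.clip(params[4:], -b.max_translation_vox, b.max_translation_vox)

    if np.allclose(params, identity_params()):
        return Volume(v.data.copy(), v.spacing, v.covariates, v.region_masks), params

    R = _rotation_matrix(*params[:3]) * params[3]
    center = (np.asarray(v.data.shape) - 1) / 2.0
    # affine_transform maps output coords -> input coords: x_in = A x_out + off
    A = np.linalg.inv(R)
    offset = center - A @ (center + params[4:])
    data = ndimage.affine_transform(v.data, A, offset=offset, order=1, mode="constant")
    masks = None
    if v.region_masks is not None:
        masks = {
            name: ndimage.affine_transform(
                mask.astype(float), A, offset=offset, order=0, mode="constant"
            ).astype(bool)
            for name, mask in v.region_masks.items()
        }
    return Volume(data, v.spacing, v.covariates, masks), params
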