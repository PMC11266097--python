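"""Raster (row-major) flattening of 3D token grids.

The order is frozen: axes (h, w, d) with the last axis fastest, exactly
numpy C order.  Checkpoints depend on this convention.
"""

from __future__ import annotations

import numpy as np


def rasterize(grid: np.ndarray) -> np.ndarray:
    """(h, w, d) integer grid -> 1D sequence of length h*w*d, C order."""
    grid = np.asarray(grid)
    if grid.ndim != 3:
        raise ValueError(f"expected a 3D token grid, got ndim={grid.ndim}")
    return grid.reshape(-1)


def derasterize(seq: np.ndarray, dims: tuple) -> np.ndarray:
    """Inverse of :func:`rasterize` for the given grid dims."""
    seq = np.asarray(seq)
    if seq.ndim != 1:
        raise ValueError("expected a 1D token sequence")
    if seq.size != int(np.prod(dims)):
        raise ValueError(f"sequence length {seq.size} != prod{tuple(dims)}")
    return seq.reshape(dims)
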