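"""TEM tile preprocessing: dark-pixel clipping, flat-field correction, CLAHE.

The chain removes ultra-dark artifacts (epoxy creases), divides out the
persistent multiplicative brightness pattern shared by all tiles of a
mosaic, and locally equalizes contrast.  The intended order is
clip → flat-field → CLAHE.  All intermediates are floating point;
quantize only on export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure

__all__ = ["clip_dark", "flat_field_correct", "FlatFieldResult", "equalize_clahe"]


def _dynamic_range_max(tile: np.ndarray) -> float:
    if np.issubdtype(tile.dtype, np.integer):
        return float(np.iinfo(tile.dtype).max)
    return 1.0


def clip_dark(
    tile: np.ndarray,
    lower_pct: float = 10.0,
    floor_frac: float = 0.10,
    dr_max: float | None = None,
) -> np.ndarray:
    """Raise the darkest ``lower_pct`` percent of pixels to a brightness floor.

    Pixels strictly below the ``lower_pct`` percentile are brought up to
    ``floor_frac`` of the dynamic-range maximum (dtype max for integer
    tiles, 1.0 for float tiles unless ``dr_max`` overrides).  Pixels at
    or above the percentile are untouched, so the output is ≥ the input
    elementwise and the operation is idempotent.
    """
    tile = np.asarray(tile)
    if tile.size == 0:
        raise ValueError("empty tile")
    if not 0 <= lower_pct <= 100:
        raise ValueError("lower_pct must lie in [0, 100]")
    if dr_max is None:
        dr_max = _dynamic_range_max(tile)
    floor = floor_frac * dr_max
    out = tile.astype(np.float64, copy=True)
    threshold = np.percentile(out, lower_pct)
    dark = out < threshold
    out[dark] = np.maximum(out[dark], floor)
    return out


@dataclass
class FlatFieldResult:
    """Corrected tiles plus the mean map used for the division."""

    corrected: np.ndarray  # (n, H, W)
    mean_map: np.ndarray  # pixelwise mean of the raw tiles
    global_mean: float  # mean of the mean map


def flat_field_correct(stack: np.ndarray) -> FlatFieldResult:
    """Divide each tile by the normalized pixelwise mean across tiles.

    With raw tiles R_i, mean map R̄ and its global mean µ, the corrected
    tiles are C_i = R_i / (R̄ / µ).  The pixelwise mean of the corrected
    stack is the constant µ at every pixel, i.e. any brightness pattern
    shared multiplicatively by all tiles is removed.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must be (n >= 2, H, W)")
    mean_map = stack.mean(axis=0)
    zeros = np.argwhere(mean_map == 0)
    if zeros.size:
        y, x = zeros[0]
        raise ValueError(f"mean map is zero at pixel (row={y}, col={x}); cannot divide")
    mu = float(mean_map.mean())
    corrected = stack / (mean_map / mu)
    return FlatFieldResult(corrected=corrected, mean_map=mean_map, global_mean=mu)


def equalize_clahe(tile: np.ndarray, kernel_px: int = 1000) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization, output in [0, 1].

    Thin wrapper over scikit-image's implementation with the kernel given
    in pixels.  Integer tiles are rescaled by their dtype maximum first;
    float tiles must already be non-negative (rescaled by their max if
    above 1).
    """
    tile = np.asarray(tile)
    if kernel_px > min(tile.shape):
        raise ValueError(
            f"CLAHE kernel ({kernel_px} px) exceeds tile dimensions {tile.shape}"
        )
    if np.issubdtype(tile.dtype, np.integer):
        img = tile.astype(np.float64) / np.iinfo(tile.dtype).max
    else:
        img = tile.astype(np.float64)
        if img.min() < 0:
            raise ValueError("float tiles must be non-negative")
        m = img.max()
        if m > 1:
            img = img / m
    if np.ptp(img) == 0:
        # CLAHE of a constant image is that constant; skimage would
        # stretch an empty histogram, so short-circuit.
        return img
    return exposure.equalize_adapthist(img, kernel_size=kernel_px)
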