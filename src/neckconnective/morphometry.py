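"""Per-axon morphometry from proofread label masks.

Converts binary/label masks of axon cross-sections into a per-axon table
(area, centroid, equivalent diameter), spatial distributions along the
dorsoventral and mediolateral axes, and summary statistics.  Diameters
use the equivalent-circle convention d = 2·sqrt(A/π), a lower bound on
the maximum edge-to-edge length for non-circular profiles.

Coordinate convention: the mask origin is the dorsal-medial corner;
row index (y) increases ventrally ("depth"), column index (x) increases
laterally ("span").  Everything downstream of :func:`measure` is in µm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import shapiro
from skimage import measure as skmeasure

__all__ = [
    "remove_small",
    "label_components",
    "measure",
    "area_fraction",
    "SpatialDistribution",
    "spatial_histograms",
    "summarize_diameters",
    "total_count",
]


def remove_small(mask: np.ndarray, min_area_px: int = 400) -> np.ndarray:
    """Remove connected objects with area strictly less than ``min_area_px``.

    400 px² at 5.1 nm/px is ≈ 0.01 µm², well below the smallest real
    axon cross-section; objects at exactly the threshold are kept.
    """
    mask = np.asarray(mask).astype(bool)
    labels = skmeasure.label(mask, connectivity=2)
    if labels.max() == 0:
        return mask
    areas = np.bincount(labels.ravel())
    small = np.flatnonzero(areas < min_area_px)
    out = mask.copy()
    out[np.isin(labels, small[small > 0])] = False
    return out


def label_components(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Connected-component labeling of a binary mask (labels 1..n, bg 0)."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask).astype(bool)
    return skmeasure.label(mask, connectivity=1 if connectivity == 4 else 2)


def measure(label_mask: np.ndarray, pixel_nm: float = 5.1) -> pd.DataFrame:
    """Measure every labeled axon: area, centroid, equivalent diameter.

    Returns a DataFrame with columns label, area_px, area_um2,
    cx_um (lateral span), cy_um (ventral depth), d_um, where
    d = 2·sqrt(A/π) and the centroid is the unweighted pixel mean.
    """
    if pixel_nm <= 0:
        raise ValueError("pixel size must be positive")
    label_mask = np.asarray(label_mask)
    px_um = pixel_nm / 1000.0
    props = skmeasure.regionprops(label_mask)
    rows = []
    for p in props:
        area_px = float(p.area)
        area_um2 = area_px * px_um**2
        cy, cx = p.centroid  # (row, col)
        rows.append(
            {
                "label": int(p.label),
                "area_px": area_px,
                "area_um2": area_um2,
                "cx_um": cx * px_um,
                "cy_um": cy * px_um,
                "d_um": 2.0 * math.sqrt(area_um2 / math.pi),
            }
        )
    return pd.DataFrame(
        rows, columns=["label", "area_px", "area_um2", "cx_um", "cy_um", "d_um"]
    )


def area_fraction(table: pd.DataFrame) -> float:
    """Summed axon area over the area of the convex hull of axon centroids.

    The hull of centroids is a (slight under-)estimate of the tract
    cross-section, so the fraction can marginally exceed the true packing
    fraction.  Requires at least 3 non-collinear centroids.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 axons for a convex hull")
    pts = table[["cx_um", "cy_um"]].to_numpy()
    try:
        hull = ConvexHull(pts)
    except QhullError as e:
        raise ValueError("degenerate centroid hull (collinear points?)") from e
    return float(table["area_um2"].sum() / hull.volume)  # 2-D: volume is area


@dataclass
class SpatialDistribution:
    """Histogram of axon centroids along one anatomical axis.

    ``slice_diameters[i]`` holds the diameters of the axons whose
    centroid falls in bin i, for per-slice distribution plots.
    """

    axis: str
    edges: np.ndarray
    counts: np.ndarray
    slice_diameters: list

    def __post_init__(self):
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")


def spatial_histograms(
    table: pd.DataFrame, axis: str = "depth", n_bins: int = 20
) -> SpatialDistribution:
    """Bin axon centroids along depth (dorsoventral) or span (mediolateral)."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    col = {"depth": "cy_um", "span": "cx_um"}.get(axis)
    if col is None:
        raise ValueError("axis must be 'depth' or 'span'")
    coords = table[col].to_numpy()
    counts, edges = np.histogram(coords, bins=n_bins)
    idx = np.clip(np.digitize(coords, edges) - 1, 0, n_bins - 1)
    slice_d = [table["d_um"].to_numpy()[idx == i] for i in range(n_bins)]
    return SpatialDistribution(
        axis=axis, edges=edges, counts=counts, slice_diameters=slice_d
    )


def summarize_diameters(
    table: pd.DataFrame, thresholds_um: tuple[float, ...] = (5.0, 8.0)
) -> dict:
    """Summary statistics of the diameter distribution.

    Counts above each threshold use strict ">".  A Shapiro–Wilk test of
    normality is run on ln(d) when at least 3 axons are present;
    otherwise the summary is flagged and the test omitted.
    """
    d = table["d_um"].to_numpy()
    out: dict = {
        "n": int(d.size),
        "mean_um": float(np.mean(d)) if d.size else float("nan"),
        "median_um": float(np.median(d)) if d.size else float("nan"),
        "min_um": float(np.min(d)) if d.size else float("nan"),
        "max_um": float(np.max(d)) if d.size else float("nan"),
        "counts_above": {f">{t}": int(np.sum(d > t)) for t in thresholds_um},
    }
    if d.size >= 3:
        stat, p = shapiro(np.log(d))
        out["shapiro_wilk_log_d"] = {"statistic": float(stat), "p_value": float(p)}
    else:
        out["shapiro_wilk_log_d"] = None
        out["flag"] = "too few axons for normality test"
    return out


def total_count(hemicount: int) -> int:
    """Total connective axon count from one hemiconnective count.

    Assumes bilateral symmetry: the tract has two mirror-image halves, so
    the total is exactly twice the hemicount.
    """
    if hemicount < 0:
        raise ValueError("hemicount must be >= 0")
    return 2 * int(hemicount)
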