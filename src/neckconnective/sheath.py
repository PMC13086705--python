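"""Ensheathing-glia scaling: sheath thickness from membrane traces and the
log-log fit of thickness against axon diameter.

Axon and fiber (axon + sheath) outlines are polygon traces along the
plasma membranes.  Areas come from the shoelace (trapezoid) rule, radii
from the equivalent-circle convention, and thickness is the difference
of fiber and axon radii.  Above ~2 µm diameter, sheath thickness follows
a power law log10(t) = a·log10(d) + b; below that, shared glial
processes decorrelate thickness from diameter, so those rows are
excluded from the fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "polygon_area",
    "thickness",
    "sheath_table_from_traces",
    "ScalingFit",
    "fit_scaling",
]


def polygon_area(coords) -> float:
    """Absolute area enclosed by a polygon (shoelace / trapezoid rule).

    Orientation-invariant; the polygon is closed implicitly.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 3:
        raise ValueError("need at least 3 (x, y) vertices")
    x, y = coords[:, 0], coords[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def thickness(axon_area: float, fiber_area: float) -> float:
    """Sheath thickness: equivalent fiber radius minus equivalent axon radius."""
    if axon_area < 0:
        raise ValueError("axon area must be non-negative")
    if fiber_area < axon_area:
        raise ValueError(
            "fiber area smaller than axon area — check ring assignment of traces"
        )
    return math.sqrt(fiber_area / math.pi) - math.sqrt(axon_area / math.pi)


def sheath_table_from_traces(traces: pd.DataFrame) -> pd.DataFrame:
    """Build a per-axon diameter/thickness table from long-format traces.

    ``traces`` columns: axon_id, ring ('axon' or 'fiber'), vertex_index,
    x, y (µm).  Returns columns axon_id, axon_area_um2, fiber_area_um2,
    d_um, t_um.
    """
    required = {"axon_id", "ring", "vertex_index", "x", "y"}
    missing = required - set(traces.columns)
    if missing:
        raise ValueError(f"trace table missing columns: {sorted(missing)}")
    rows = []
    for axon_id, grp in traces.groupby("axon_id"):
        areas = {}
        for ring in ("axon", "fiber"):
            ring_pts = grp[grp["ring"] == ring].sort_values("vertex_index")
            if len(ring_pts) < 3:
                raise ValueError(f"axon {axon_id}: ring {ring!r} has < 3 vertices")
            areas[ring] = polygon_area(ring_pts[["x", "y"]].to_numpy())
        d = 2.0 * math.sqrt(areas["axon"] / math.pi)
        rows.append(
            {
                "axon_id": axon_id,
                "axon_area_um2": areas["axon"],
                "fiber_area_um2": areas["fiber"],
                "d_um": d,
                "t_um": thickness(areas["axon"], areas["fiber"]),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ScalingFit:
    """OLS fit of log10(thickness) on log10(diameter)."""

    slope: float
    intercept: float
    ci_half_width: float  # 95% CI half-width on the slope
    stderr: float
    n_used: int
    d_min_um: float


def fit_scaling(table: pd.DataFrame, d_min_um: float = 2.0) -> ScalingFit:
    """Fit log10(t) = a·log10(d) + b over axons with d > d_min_um.

    The 95% CI on the slope uses the analytic OLS standard error with a
    t-quantile at n−2 degrees of freedom.  Rows at or below the diameter
    cutoff never influence the fit; zero-thickness rows below the cutoff
    are merely warned about (the small-axon regime is uncorrelated), but
    a non-positive thickness above the cutoff is an error since its log
    is undefined.
    """
    d = table["d_um"].to_numpy(float)
    t = table["t_um"].to_numpy(float)
    if np.any((t <= 0) & (d <= d_min_um)):
        warnings.warn(
            "zero/negative sheath thickness among small axons (d <= d_min); "
            "excluded from the fit",
            stacklevel=2,
        )
    keep = d > d_min_um
    if np.any(t[keep] <= 0):
        raise ValueError("non-positive thickness among axons above d_min (log undefined)")
    n = int(keep.sum())
    if n < 3:
        raise ValueError("need at least 3 axons above d_min for the fit")
    res = stats.linregress(np.log10(d[keep]), np.log10(t[keep]))
    half = stats.t.ppf(0.975, n - 2) * res.stderr
    return ScalingFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        ci_half_width=float(half),
        stderr=float(res.stderr),
        n_used=n,
        d_min_um=d_min_um,
    )
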