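"""Synthetic ground-truth generators for every pipeline stage.

Each generator produces data with the statistical structure the matching
analysis stage assumes: an axon-diameter distribution with a lognormal
body (mean ≈ 0.99 µm, median ≈ 0.69 µm, truncated to 0.1–15 µm) plus a
small giant-axon tail; a power-law sheath-thickness scaling with
lognormal scatter; spikes propagating along a multi-shank probe sampled
by a round-robin ADC; and image tile stacks sharing one multiplicative
brightness gradient.  All randomness flows through one
`numpy.random.Generator` per call; nothing touches global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .probes import ProbeGeometry, RecordingConfig, make_probe

__all__ = [
    "UnitSpec",
    "Recording",
    "default_template",
    "simulate_recording",
    "generate_axon_population",
    "render_label_mask",
    "generate_sheath_dataset",
    "generate_velocity_diameter_sample",
    "generate_tile_stack",
    "make_probe",
]

INT16_GAIN = 256.0  # ADC counts per standard deviation on export


def default_template(main_lobe_ms: float = 1.2) -> Callable[[np.ndarray], np.ndarray]:
    """Biphasic difference-of-Gaussians spike template, peak-normalized.

    Zero net area (equal-area Gaussians), so the shape survives the
    300 Hz high-pass edge of the analysis chain with little distortion.
    The support is comfortably inside a 4 ms window.
    """
    sigma1 = main_lobe_ms * 1e-3 / 6.0  # main lobe ≈ ±3 sigma
    sigma2 = 3.0 * sigma1
    peak = 1.0 - sigma1 / sigma2

    def template(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        g1 = np.exp(-0.5 * (t / sigma1) ** 2)
        g2 = (sigma1 / sigma2) * np.exp(-0.5 * (t / sigma2) ** 2)
        return (g1 - g2) / peak

    return template


@dataclass(frozen=True)
class UnitSpec:
    """A simulated axonal unit crossing the probe.

    velocity_mps is signed: positive means propagation toward increasing
    axial coordinate ("ascending").  Use ``math.inf`` for a unit that
    arrives simultaneously everywhere (e.g. a far-field artifact).
    """

    velocity_mps: float
    amplitude_sd: float = 5.0
    rate_hz: float = 10.0
    template: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self):
        if self.velocity_mps == 0:
            raise ValueError("velocity must be nonzero (propagation undefined)")
        if self.amplitude_sd <= 0:
            raise ValueError("amplitude_sd must be positive")


@dataclass
class Recording:
    """Raw int16 recording plus its JSON-able sidecar metadata."""

    data: np.ndarray  # (n_samples, n_channels) int16
    sidecar: dict
    spike_times_s: list  # per unit, array of true spike times (s)

    @property
    def fs_hz(self) -> float:
        return self.sidecar["fs_hz"]

    def as_float(self) -> np.ndarray:
        """Recording in SD units (undo the export gain)."""
        return self.data.astype(np.float64) / self.sidecar["gain_counts_per_sd"]


def simulate_recording(
    geometry: ProbeGeometry,
    units: Sequence[UnitSpec],
    config: RecordingConfig,
    rng: np.random.Generator | None = None,
) -> Recording:
    """Simulate an extracellular recording with known propagating units.

    A spike of unit *u* emitted at time *s* arrives at the channel at
    axial position x_c with delay (x_c − x_min)/velocity.  Channel *c*'s
    samples are taken at frame times offset by slot(c)/adc_hz, exactly as
    a round-robin multiplexed ADC would; the analysis chain must undo
    that skew.  Gaussian noise of sd ``config.noise_sd`` is added.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.fs_hz
    n_samples = int(round(config.duration_s * fs))
    n_ch = geometry.n_channels
    positions_m = geometry.channel_positions_um * 1e-6
    x0 = positions_m.min()
    slot_offsets_s = geometry.acquisition_order / config.adc_hz

    data = rng.normal(0.0, config.noise_sd, size=(n_samples, n_ch))

    support_s = 2e-3  # template support half-width
    margin = support_s + np.ptp(positions_m) / min(
        (abs(u.velocity_mps) for u in units), default=1.0
    )
    spike_times = []
    for u in units:
        template = u.template or default_template()
        n_spk = rng.poisson(u.rate_hz * config.duration_s)
        times = np.sort(
            rng.uniform(margin, config.duration_s - margin, size=n_spk)
        )
        spike_times.append(times)
        for c in range(n_ch):
            if math.isinf(u.velocity_mps):
                delay = 0.0
            else:
                delay = (positions_m[c] - x0) / u.velocity_mps
            for s in times:
                arrival = s + delay
                k0 = int(np.floor((arrival - support_s) * fs))
                k1 = int(np.ceil((arrival + support_s) * fs)) + 1
                k0, k1 = max(k0, 0), min(k1, n_samples)
                if k0 >= k1:
                    continue
                t_samp = np.arange(k0, k1) / fs + slot_offsets_s[c]
                data[k0:k1, c] += u.amplitude_sd * template(t_samp - arrival)

    counts = np.clip(np.round(data * INT16_GAIN), -32768, 32767).astype(np.int16)
    sidecar = {
        "fs_hz": fs,
        "adc_hz": config.adc_hz,
        "n_slots": config.n_slots,
        "gain_counts_per_sd": INT16_GAIN,
        "duration_s": config.duration_s,
        "noise_sd": config.noise_sd,
        "probe": geometry.to_dict(),
        "units": [
            {"velocity_mps": u.velocity_mps, "amplitude_sd": u.amplitude_sd}
            for u in units
        ],
    }
    return Recording(data=counts, sidecar=sidecar, spike_times_s=spike_times)


# ---------------------------------------------------------------------------
# Axon populations

#: Lognormal body calibrated so that, with the 2% giant tail mixed in,
#: the sample mean is ~0.99 µm and the median ~0.69 µm.
_BODY_MU = math.log(0.69)
_BODY_SIGMA = 0.641
_GIANT_FRACTION = 0.02
_GIANT_MU = math.log(8.0)
_GIANT_SIGMA = 0.30
_D_MIN_UM, _D_MAX_UM = 0.1, 15.0


def _truncated_lognormal(
    rng: np.random.Generator, mu: float, sigma: float, n: int,
    lo: float = _D_MIN_UM, hi: float = _D_MAX_UM,
) -> np.ndarray:
    out = np.empty(0)
    while out.size < n:
        draw = rng.lognormal(mu, sigma, size=2 * (n - out.size) + 16)
        out = np.concatenate([out, draw[(draw >= lo) & (draw <= hi)]])
    return out[:n]


def sample_diameters(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw axon diameters (µm): truncated lognormal body + giant tail."""
    n_giant = rng.binomial(n, _GIANT_FRACTION)
    body = _truncated_lognormal(rng, _BODY_MU, _BODY_SIGMA, n - n_giant)
    giants = _truncated_lognormal(rng, _GIANT_MU, _GIANT_SIGMA, n_giant)
    d = np.concatenate([body, giants])
    rng.shuffle(d)
    return d


def _pack_circles(
    radii: np.ndarray,
    span_um: float,
    depth_um: float,
    rng: np.random.Generator,
    y_windows: np.ndarray | None = None,
    max_tries: int = 5000,
    separation_um: float = 0.0,
) -> np.ndarray:
    """Random sequential placement of non-overlapping circles, largest first.

    Returns centers (n, 2) as (span, depth) µm.  ``y_windows`` optionally
    restricts each circle's depth coordinate to a (lo, hi) band.
    ``separation_um`` enforces a minimum edge-to-edge gap between circles.
    """
    order = np.argsort(radii)[::-1]
    centers = np.full((len(radii), 2), np.nan)
    px = np.empty(len(radii))
    py = np.empty(len(radii))
    pr = np.empty(len(radii))
    n_placed = 0
    for idx in order:
        r = radii[idx]
        if y_windows is not None:
            ylo = max(r, y_windows[idx, 0])
            yhi = min(depth_um - r, y_windows[idx, 1])
            if yhi <= ylo:
                ylo, yhi = r, depth_um - r
        else:
            ylo, yhi = r, depth_um - r
        placed = False
        for attempt in range(max_tries):
            if attempt == max_tries // 2:
                # depth band too crowded; relax to the full range
                ylo, yhi = r, depth_um - r
            x = rng.uniform(r, span_um - r)
            y = rng.uniform(ylo, yhi)
            if n_placed:
                d2 = (px[:n_placed] - x) ** 2 + (py[:n_placed] - y) ** 2
                if np.any(d2 < (pr[:n_placed] + r + separation_um) ** 2):
                    continue
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"circle packing failed after {max_tries} tries "
                f"(radius {r:.3g} µm, {n_placed} placed)"
            )
        centers[idx] = (x, y)
        px[n_placed], py[n_placed], pr[n_placed] = x, y, r
        n_placed += 1
    return centers


def generate_axon_population(
    n: int,
    profile: str = "uniform",
    pixel_nm: float = 5.1,
    seed: int | np.random.Generator = 0,
    render: bool = False,
    packing_fraction: float = 0.40,
    aspect: float = 2.0,
    min_gap_um: float | None = None,
) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Generate a ground-truth axon population and (optionally) its label mask.

    profile "uniform" scatters diameters independently of depth;
    "gradient" rank-orders diameters along the depth axis (dorsal large,
    ventral small) as seen in real hemiconnective cross-sections.  The
    canvas is sized so the circles occupy ``packing_fraction`` of it,
    with depth:span aspect ``aspect``.

    ``min_gap_um`` is the enforced edge-to-edge clearance between axons
    (membranes and glial processes separate real profiles).  It defaults
    to two pixels when rendering, which guarantees distinct axons stay
    distinct 8-connected components in the rasterized mask, and to zero
    otherwise.

    Returns (table, mask); mask is None unless ``render``.  Columns:
    axon_id, x_um (lateral span), y_um (ventral depth), d_um, depth_band.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if profile not in ("uniform", "gradient"):
        raise ValueError(f"unknown profile {profile!r}")

    if n == 0:
        table = pd.DataFrame(
            columns=["axon_id", "x_um", "y_um", "d_um", "depth_band"]
        )
        mask = np.zeros((16, 16), dtype=np.int32) if render else None
        return table, mask

    d = sample_diameters(n, rng)
    radii = d / 2.0
    if min_gap_um is None:
        min_gap_um = 2.0 * pixel_nm / 1000.0 if render else 0.0
    # size the canvas with gap-inflated radii so the effective packing
    # fraction (and hence feasibility) does not depend on the gap
    total_area = np.pi * np.sum((radii + min_gap_um / 2.0) ** 2)
    region_area = total_area / packing_fraction
    span_um = math.sqrt(region_area / aspect)
    depth_um = region_area / span_um
    # never let the region be tighter than the largest circle
    pad = 2.2 * radii.max()
    span_um, depth_um = max(span_um, pad), max(depth_um, pad)

    y_windows = None
    if profile == "gradient":
        # small axons ventral (deep), large axons dorsal (shallow)
        q = (np.argsort(np.argsort(d)) + 0.5) / n  # diameter quantile
        center = (1.0 - q) * depth_um
        # wide enough for the circle itself plus local crowding
        half = np.maximum(0.12 * depth_um, 3.0 * radii)
        y_windows = np.column_stack([center - half, center + half])

    centers = _pack_circles(
        radii, span_um, depth_um, rng, y_windows, separation_um=min_gap_um
    )

    band = np.minimum((centers[:, 1] / depth_um * 3).astype(int), 2)
    band_names = np.array(["dorsal", "medial", "ventral"])[band]
    table = pd.DataFrame(
        {
            "axon_id": np.arange(1, n + 1),
            "x_um": centers[:, 0],
            "y_um": centers[:, 1],
            "d_um": d,
            "depth_band": band_names,
        }
    )
    mask = render_label_mask(table, pixel_nm) if render else None
    return table, mask


def render_label_mask(table: pd.DataFrame, pixel_nm: float) -> np.ndarray:
    """Rasterize an axon table as a label image (circles of true diameter).

    A pixel belongs to a circle when its center falls inside it.  Labels
    are the table's axon_id; background is 0.
    """
    if pixel_nm <= 0:
        raise ValueError("pixel size must be positive")
    px_um = pixel_nm / 1000.0
    if len(table) == 0:
        return np.zeros((16, 16), dtype=np.int32)
    h = int(np.ceil((table.y_um + table.d_um / 2).max() / px_um)) + 2
    w = int(np.ceil((table.x_um + table.d_um / 2).max() / px_um)) + 2
    mask = np.zeros((h, w), dtype=np.int32)
    for row in table.itertuples():
        r_px = (row.d_um / 2) / px_um
        cx, cy = row.x_um / px_um, row.y_um / px_um
        x0, x1 = max(int(cx - r_px) - 1, 0), min(int(cx + r_px) + 2, w)
        y0, y1 = max(int(cy - r_px) - 1, 0), min(int(cy + r_px) + 2, h)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        inside = (yy + 0.5 - cy) ** 2 + (xx + 0.5 - cx) ** 2 <= r_px**2
        mask[y0:y1, x0:x1][inside] = row.axon_id
    return mask


# ---------------------------------------------------------------------------
# Sheath scaling

def generate_sheath_dataset(
    n: int = 137,
    slope: float = 1.12,
    intercept: float = -0.45,
    sd_log10: float = 0.05,
    d_range_um: tuple[float, float] = (10**0.35, 10**1.1),
    seed: int | np.random.Generator = 0,
    small_axon_scatter_sd: float | None = None,
) -> pd.DataFrame:
    """Diameter/sheath-thickness pairs following log10(t) = a·log10(d) + b.

    Diameters are log-uniform over ``d_range_um``; thickness noise is
    Gaussian in log10 space.  If ``small_axon_scatter_sd`` is given, rows
    with d ≤ 2 µm get that (larger) scatter instead, mimicking small
    axons sharing glial processes.
    """
    lo, hi = d_range_um
    if not (0 < lo < hi <= 20):
        raise ValueError("d_range_um must lie within (0, 20] µm")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    log_d = rng.uniform(np.log10(lo), np.log10(hi), size=n)
    sd = np.full(n, sd_log10, float)
    if small_axon_scatter_sd is not None:
        sd[10**log_d <= 2.0] = small_axon_scatter_sd
    log_t = slope * log_d + intercept + rng.normal(0.0, 1.0, size=n) * sd
    return pd.DataFrame({"d_um": 10**log_d, "t_um": 10**log_t})


# ---------------------------------------------------------------------------
# Unpaired velocity/diameter samples for the exponent MLE

def generate_velocity_diameter_sample(
    n: int = 150,
    k_true: float = 0.64,
    log_mean: float = 1.2,
    log_sd: float = 0.35,
    d_min_um: float = 3.0,
    noise_frac: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw diameters d ~ lognormal truncated to d > d_min and set
    v = d^k_true with multiplicative noise.  Returns (velocities, diameters).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = np.empty(0)
    while d.size < n:
        draw = rng.lognormal(log_mean, log_sd, size=2 * (n - d.size) + 16)
        d = np.concatenate([d, draw[draw > d_min_um]])
    d = d[:n]
    v = d**k_true * (1.0 + noise_frac * rng.standard_normal(n))
    return np.abs(v), d


# ---------------------------------------------------------------------------
# Image tile stacks

def generate_tile_stack(
    n_tiles: int,
    shape: tuple[int, int] = (96, 96),
    seed: int | np.random.Generator = 0,
    gradient: np.ndarray | str | None = "linear",
) -> tuple[np.ndarray, np.ndarray]:
    """Tile stack with a shared multiplicative brightness pattern.

    tile_i = content_i × gradient, with independent smooth positive
    contents.  gradient may be an array (broadcast over tiles), "linear"
    (0.5→1.5 left to right), or None (flat).  Returns (stack, gradient).
    """
    if n_tiles < 2:
        raise ValueError("need at least 2 tiles")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    from scipy.ndimage import gaussian_filter

    h, w = shape
    if gradient is None:
        grad = np.ones(shape)
    elif isinstance(gradient, str):
        if gradient != "linear":
            raise ValueError(f"unknown gradient {gradient!r}")
        grad = np.tile(np.linspace(0.5, 1.5, w), (h, 1))
    else:
        grad = np.asarray(gradient, float)
        if grad.shape != shape:
            raise ValueError("gradient shape must match tile shape")

    tiles = np.empty((n_tiles, h, w))
    for i in range(n_tiles):
        field_ = gaussian_filter(rng.standard_normal(shape), sigma=4.0)
        field_ = field_ / (np.abs(field_).max() + 1e-12)
        tiles[i] = (1.0 + 0.5 * field_) * grad
    return tiles, grad
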