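"""Conduction-velocity estimation from multi-shank extracellular recordings.

The chain: band-pass (300–5000 Hz) and z-score each channel, average
4 ms spike-triggered waveforms per channel, undo the round-robin ADC
sampling skew, then estimate per-pair time lags by cross-correlating
mean waveforms and refining the peak with a quadratic fit through the
top four lags.  Velocity is the mean of Δx/Δt over all eligible channel
pairs (both waveforms above an amplitude threshold, non-zero axial
separation).  Positive velocity means propagation toward increasing
axial coordinate (ascending, by this package's convention).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .probes import ProbeGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "bandpass",
    "zscore_channels",
    "WhiteningSpec",
    "modified_whitening",
    "MeanWaveformSet",
    "extract_mean_waveforms",
    "correct_round_robin",
    "LagEstimate",
    "pair_lag",
    "VelocityEstimate",
    "estimate_velocity",
    "observational_bounds",
    "round_half_up",
    "to_latency",
    "compare_directions",
    "measure_unit_velocities",
]


def bandpass(
    data: np.ndarray, fs: float, lo: float = 300.0, hi: float = 5000.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time axis (axis 0)."""
    if hi >= fs / 2:
        raise ValueError(f"upper cutoff {hi} Hz is at/above Nyquist ({fs / 2} Hz)")
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(data, float), axis=0)


def zscore_channels(data: np.ndarray) -> np.ndarray:
    """Standardize each channel to mean 0, SD 1 over the whole recording."""
    data = np.asarray(data, float)
    x = data if data.ndim == 2 else data[:, None]
    sd = x.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance channel(s): {bad.tolist()}")
    out = (x - x.mean(axis=0)) / sd
    return out if data.ndim == 2 else out[:, 0]


@dataclass
class WhiteningSpec:
    """Diagonal-weighted whitening: W_new = α·W + (1−α)·W_diag.

    W is the symmetric inverse square root of the channel covariance;
    W_diag keeps only its diagonal (pure per-channel standardization).
    α blends between z-scoring (α=0) and full whitening (α=1).
    """

    w: np.ndarray
    w_diag: np.ndarray
    alpha: float

    @property
    def w_new(self) -> np.ndarray:
        return self.alpha * self.w + (1.0 - self.alpha) * self.w_diag


def modified_whitening(covariance: np.ndarray, alpha: float = 0.1) -> WhiteningSpec:
    """Whitening matrix weighted toward its diagonal.

    High cross-channel correlation (one axon visible on every channel)
    means full whitening can cancel the signal itself; blending toward
    the diagonal preserves it while still equalizing channel scales.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    c = np.asarray(covariance, float)
    if c.ndim != 2 or c.shape[0] != c.shape[1] or not np.allclose(c, c.T):
        raise ValueError("covariance must be square and symmetric")
    vals, vecs = np.linalg.eigh(c)
    if np.any(vals <= 0):
        raise ValueError("covariance is not positive-definite")
    w = vecs @ np.diag(1.0 / np.sqrt(vals)) @ vecs.T
    return WhiteningSpec(w=w, w_diag=np.diag(np.diag(w)), alpha=alpha)


@dataclass
class MeanWaveformSet:
    """Per-channel mean spike waveforms in SD units on a shared window."""

    waveforms: np.ndarray  # (n_channels, n_samples)
    fs_hz: float
    positions_um: np.ndarray  # axial position per channel
    window_ms: float
    time_offsets_s: np.ndarray  # residual per-channel acquisition offsets
    n_spikes_used: int = 0
    n_spikes_dropped: int = 0

    @property
    def amplitudes_sd(self) -> np.ndarray:
        return np.abs(self.waveforms).max(axis=1)


def extract_mean_waveforms(
    data: np.ndarray,
    spike_samples: np.ndarray,
    fs: float,
    window_ms: float = 4.0,
    positions_um: np.ndarray | None = None,
    time_offsets_s: np.ndarray | None = None,
) -> MeanWaveformSet:
    """Average windows centered on each spike, per channel.

    ``data`` is (n_samples, n_channels), already filtered and z-scored.
    Spikes closer than half a window to either record edge are dropped
    (and counted); zero usable spikes is an error.
    """
    data = np.asarray(data, float)
    if data.ndim != 2:
        raise ValueError("data must be (n_samples, n_channels)")
    n_total, n_ch = data.shape
    half = int(round(window_ms * 1e-3 * fs / 2))
    spike_samples = np.asarray(spike_samples, int)
    ok = (spike_samples >= half) & (spike_samples < n_total - half)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("dropped %d spike(s) too close to record edges", dropped)
    centers = spike_samples[ok]
    if centers.size == 0:
        raise ValueError("no usable spikes after edge exclusion")
    idx = centers[:, None] + np.arange(-half, half + 1)[None, :]
    mean_wf = data[idx].mean(axis=0).T  # (n_channels, 2*half+1)
    if positions_um is None:
        positions_um = np.zeros(n_ch)
    if time_offsets_s is None:
        time_offsets_s = np.zeros(n_ch)
    return MeanWaveformSet(
        waveforms=mean_wf,
        fs_hz=fs,
        positions_um=np.asarray(positions_um, float),
        window_ms=window_ms,
        time_offsets_s=np.asarray(time_offsets_s, float),
        n_spikes_used=int(centers.size),
        n_spikes_dropped=dropped,
    )


def _fractional_shift(y: np.ndarray, delta: float, method: str = "sinc") -> np.ndarray:
    """Return y evaluated at sample positions k − delta (a delay by delta)."""
    n = y.size
    if method == "sinc":
        freqs = np.fft.rfftfreq(n)
        spec = np.fft.rfft(y) * np.exp(-2j * np.pi * freqs * delta)
        return np.fft.irfft(spec, n)
    if method == "cubic":
        from scipy.interpolate import CubicSpline

        return CubicSpline(np.arange(n), y)(np.arange(n) - delta)
    raise ValueError(f"unknown interpolation method {method!r}")


def correct_round_robin(
    wfset: MeanWaveformSet,
    acquisition_order: np.ndarray,
    adc_hz: float = 1.05e6,
    method: str = "sinc",
) -> MeanWaveformSet:
    """Resample each channel's mean waveform onto the common frame times.

    Channel with ADC slot *s* was actually sampled at frame time +
    s/adc_hz; its recorded samples therefore lead the nominal frame
    clock, and are shifted by s·fs/adc_hz samples (a fraction of one
    sample) onto the frame grid via band-limited interpolation.
    """
    order = np.asarray(acquisition_order, int)
    if len(np.unique(order)) != order.size:
        raise ValueError("duplicate ADC slots in acquisition order")
    if order.size != wfset.waveforms.shape[0]:
        raise ValueError("acquisition order length must match channel count")
    shifted = np.empty_like(wfset.waveforms)
    for c in range(order.size):
        delta = order[c] * wfset.fs_hz / adc_hz  # samples, in [0, 1)
        shifted[c] = (
            wfset.waveforms[c]
            if delta == 0
            else _fractional_shift(wfset.waveforms[c], delta, method)
        )
    return MeanWaveformSet(
        waveforms=shifted,
        fs_hz=wfset.fs_hz,
        positions_um=wfset.positions_um,
        window_ms=wfset.window_ms,
        time_offsets_s=np.zeros(order.size),
        n_spikes_used=wfset.n_spikes_used,
        n_spikes_dropped=wfset.n_spikes_dropped,
    )


@dataclass
class LagEstimate:
    """Cross-correlation lag between two mean waveforms.

    dt_s is the arrival-time difference (channel j minus channel i):
    positive when j lags i.
    """

    lags: np.ndarray  # integer lags (samples)
    c: np.ndarray  # cross-correlation at each lag
    lag_samples: float  # refined (sub-sample) argmax lag
    dt_s: float
    refined: bool  # whether the quadratic refinement was used


def cross_correlation(x_i: np.ndarray, x_j: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized cross-correlation c[l] = Σ_t x_i[t+l]·x_j[t].

    Lags span ±n/2 (half the waveform window each way).  No amplitude
    normalization: channels are already z-scored upstream.
    """
    x_i = np.asarray(x_i, float)
    x_j = np.asarray(x_j, float)
    if x_i.shape != x_j.shape or x_i.ndim != 1:
        raise ValueError("waveforms must be 1-D and the same length")
    n = x_i.size
    full = np.correlate(x_i, x_j, mode="full")  # index k ↔ lag k-(n-1)
    half = n // 2
    lags = np.arange(-half, half + 1)
    return lags, full[lags + n - 1]


def pair_lag(x_i: np.ndarray, x_j: np.ndarray, fs: float) -> LagEstimate:
    """Time lag between two mean waveforms with sub-sample refinement.

    A quadratic is fit through the four largest cross-correlation values
    and its vertex taken as the lag; if those four lags are not
    contiguous, the parabola opens upward, or the vertex escapes the lag
    span, the discrete argmax is used instead.
    """
    if not (np.any(x_i) and np.any(x_j)):
        raise ValueError("all-zero waveform")
    lags, c = cross_correlation(x_i, x_j)
    best = int(np.argmax(c))
    lag_star = float(lags[best])
    refined = False
    if c.size >= 4:
        top = np.sort(np.argpartition(c, -4)[-4:])
        if np.all(np.diff(top) == 1):
            coef = np.polyfit(lags[top], c[top], 2)
            a, b = coef[0], coef[1]
            if a < 0:
                vertex = -b / (2 * a)
                if lags[0] <= vertex <= lags[-1]:
                    lag_star = float(vertex)
                    refined = True
    return LagEstimate(
        lags=lags, c=c, lag_samples=lag_star, dt_s=-lag_star / fs, refined=refined
    )


@dataclass
class VelocityEstimate:
    """Signed conduction velocity with its per-pair ledger."""

    v_mps: float
    direction: str  # 'ascending' (v > 0) or 'descending'
    pairs: pd.DataFrame  # i, j, dx_um, dt_s, v_mps, used
    n_pairs: int  # pairs entering the mean
    n_near_simultaneous: int
    amp_threshold_sd: float
    flagged: bool  # |v| outside the observational bounds
    bounds_mps: tuple  # (v_max, v_min)
    unit_id: object = None


def estimate_velocity(
    wfset: MeanWaveformSet,
    geometry: ProbeGeometry,
    amp_threshold_sd: float = 1.5,
    adc_hz: float = 1.05e6,
    unit_id=None,
) -> VelocityEstimate:
    """Mean of Δx/Δt over all eligible channel pairs.

    A pair is eligible when both mean waveforms exceed the amplitude
    threshold (in SD units) and the channels' axial separation is
    non-zero.  Pairs whose |Δt| is below one ADC slot period cannot be
    resolved in time; they are logged as near-simultaneous and excluded
    from the mean rather than producing unbounded Δx/Δt values.  The
    estimate is flagged when |V| falls outside the observational bounds
    set by sample rate, probe span, and window length.
    """
    amps = wfset.amplitudes_sd
    eligible = np.flatnonzero(amps > amp_threshold_sd)
    pos = wfset.positions_um
    slot_period = 1.0 / adc_hz
    rows = []
    for a in range(len(eligible)):
        for b in range(a + 1, len(eligible)):
            i, j = int(eligible[a]), int(eligible[b])
            dx_um = pos[j] - pos[i]
            if dx_um == 0:
                continue
            est = pair_lag(wfset.waveforms[i], wfset.waveforms[j], wfset.fs_hz)
            near = abs(est.dt_s) < slot_period
            v = np.nan if near else (dx_um * 1e-6) / est.dt_s
            rows.append(
                {
                    "i": i,
                    "j": j,
                    "dx_um": dx_um,
                    "dt_s": est.dt_s,
                    "v_mps": v,
                    "used": not near,
                }
            )
    if not rows:
        raise ValueError("no eligible channel pairs (amplitude threshold / Δx=0)")
    pairs = pd.DataFrame(rows)
    used = pairs[pairs["used"]]
    n_near = int((~pairs["used"]).sum())
    if used.empty:
        raise ValueError("all pairs near-simultaneous; velocity unresolvable")
    v_mean = float(used["v_mps"].mean())
    v_max, v_min = observational_bounds(geometry, wfset.fs_hz, wfset.window_ms)
    flagged = not (v_min <= abs(v_mean) <= v_max)
    return VelocityEstimate(
        v_mps=v_mean,
        direction="ascending" if v_mean > 0 else "descending",
        pairs=pairs,
        n_pairs=int(len(used)),
        n_near_simultaneous=n_near,
        amp_threshold_sd=amp_threshold_sd,
        flagged=flagged,
        bounds_mps=(v_max, v_min),
        unit_id=unit_id,
    )


def observational_bounds(
    geometry: ProbeGeometry, fs: float, window_ms: float = 4.0
) -> tuple[float, float]:
    """(v_max, v_min) in m/s resolvable by this probe and sampling.

    The fastest observable unit traverses the probe's full axial span in
    one sample period; the slowest traverses it in the maximum usable
    lag, half the spike window.
    """
    sep_m = geometry.max_axial_separation_um * 1e-6
    if sep_m == 0:
        raise ValueError("zero axial separation: bounds undefined")
    v_max = sep_m * fs
    v_min = sep_m / (window_ms * 1e-3 / 2.0)
    return v_max, v_min


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero (0.225 → 0.23), as figures print.

    The scaled value is cleaned to 9 decimals first so that exact-half
    values stored as 0.224999...  still round up.
    """
    factor = 10.0**decimals
    scaled = round(abs(x) * factor, 9)
    return math.floor(scaled + 0.5) / factor * (1 if x >= 0 else -1)


def to_latency(velocity_mps: float, length_m: float = 0.01) -> float:
    """Travel latency (ms) over a tract of the given length (default 1 cm)."""
    if velocity_mps == 0:
        raise ValueError("zero velocity has undefined latency")
    return length_m / abs(velocity_mps) * 1e3


def required_velocity(length_m: float, deadline_s: float) -> float:
    """Velocity needed to traverse a tract within a deadline (m/s)."""
    if deadline_s <= 0:
        raise ValueError("deadline must be positive")
    return length_m / deadline_s


def compare_directions(
    velocities_ascending: np.ndarray, velocities_descending: np.ndarray
) -> dict:
    """Two-sample KS test on speed magnitudes, Shapiro–Wilk on pooled |V|."""
    asc = np.abs(np.asarray(velocities_ascending, float))
    desc = np.abs(np.asarray(velocities_descending, float))
    if asc.size < 3 or desc.size < 3:
        raise ValueError("need at least 3 velocities per direction")
    ks = stats.ks_2samp(asc, desc)
    pooled = np.concatenate([asc, desc])
    sw = stats.shapiro(pooled)
    return {
        "ks_statistic": float(ks.statistic),
        "ks_p_value": float(ks.pvalue),
        "shapiro_statistic": float(sw.statistic),
        "shapiro_p_value": float(sw.pvalue),
        "n_ascending": int(asc.size),
        "n_descending": int(desc.size),
    }


def measure_unit_velocities(
    data_sd: np.ndarray,
    fs: float,
    spikes_by_unit: dict,
    geometry: ProbeGeometry,
    adc_hz: float = 1.05e6,
    window_ms: float = 4.0,
    amp_threshold_sd: float = 1.5,
    lo_hz: float = 300.0,
    hi_hz: float = 5000.0,
) -> list[VelocityEstimate]:
    """Full per-unit velocity chain on a raw (float, SD-ish) recording.

    Band-pass, z-score, average spike-triggered waveforms, undo the
    round-robin sampling skew, then estimate velocity per unit.
    """
    filtered = zscore_channels(bandpass(data_sd, fs, lo_hz, hi_hz))
    positions = geometry.channel_positions_um
    offsets = geometry.acquisition_order / adc_hz
    estimates = []
    for unit_id, spike_samples in spikes_by_unit.items():
        wfset = extract_mean_waveforms(
            filtered, spike_samples, fs, window_ms, positions, offsets
        )
        wfset = correct_round_robin(wfset, geometry.acquisition_order, adc_hz)
        estimates.append(
            estimate_velocity(
                wfset, geometry, amp_threshold_sd, adc_hz, unit_id=unit_id
            )
        )
    return estimates
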