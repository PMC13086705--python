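# Methods

This document describes the models and numerical choices implemented in
`neckconnective`. All empirical numbers quoted here are computed by the
package's own tests (`tests/`) or by `scripts/acceptance.py`.

## 1. TEM tile preprocessing (`preproc`)

Cross-section mosaics arrive as overlapping camera tiles sharing a
fixed multiplicative brightness pattern (vignetting, sensor gain).

- **Dark clipping** (`clip_dark`): pixels strictly below the p-th
  percentile (default 10) are raised to `floor_frac · dtype_max`
  (default 0.10). The operation is idempotent.
- **Flat-field correction** (`flat_field_correct`): each tile `R_i` is
  divided by the pixelwise mean across tiles normalized to its own
  global mean, `C_i = R_i / (R̄ / µ_R̄)`. Consequence (tested exactly):
  the pixelwise mean of the corrected stack equals `µ_R̄` at every
  pixel. A zero anywhere in the mean map raises an error naming the
  offending pixel (`row=…, col=…`).
- **CLAHE** (`equalize_clahe`): scikit-image's
  `equalize_adapthist`; constant images are returned unchanged, and a
  kernel larger than the image dimensions is an error.

## 2. Axon morphometry (`morphometry`)

Input is a label (or binary) mask of axon cross-sections.

- **Small-object removal** is a strict `area < min_area_px` filter
  (default 400 px at 5.1 nm/px): a 399 px component is removed, a
  400 px one kept. It is implemented directly via connected-component
  labeling + `bincount` because library alternatives use ≤ semantics.
- **Labeling** uses 8-connectivity by default (two pixels touching only
  diagonally form one component).
- **Equivalent diameter** d = 2·√(A/π) from the pixel area and the
  pixel pitch. Exactness on rendered disks is tested to within 2 px.
- **Counts**: the hemiconnective count is the number of retained
  components; the total assumes bilateral symmetry,
  `total = 2 × hemicount` (e.g. 4437 → 8874). Diameter-threshold counts
  use strict `>`.
- **Area fraction** is total measured axon area over the convex hull of
  the centroids; log-diameter normality is assessed with Shapiro–Wilk
  on ln(d).

## 3. Sheath scaling (`sheath`)

Glial sheaths are traced as inner (axon) and outer (fiber) polygons.

- Polygon area is the shoelace formula; thickness is the difference of
  equivalent radii, `t = √(A_fiber/π) − √(A_axon/π)`.
- The scaling fit is OLS of log10(t) on log10(d) **restricted to
  d > 2 µm**: below that, sheath thickness decouples from diameter and
  would bias the slope. Non-positive thickness above the cutoff is an
  error; below the cutoff it only warns (those rows never enter the
  fit).
- The reported half-width is the analytic 95% CI,
  `t_{0.975, n−2} · stderr` of the slope.

## 4. Conduction velocity (`probes`, `ephys`)

### Probe model

`make_probe()` builds the reference geometry: 4 shanks at 150 µm pitch
(max axial separation 450 µm), 4 sites per shank. Acquisition uses one
ADC at 1.05 MHz multiplexed round-robin over 35 slots → 30 kHz per
channel; each channel's true sample time is offset by
`slot / adc_hz` within the frame.

### Preprocessing

Band-pass 300–5000 Hz (4th-order Butterworth, zero-phase `sosfiltfilt`),
per-channel z-scoring, and optionally a **diagonal-weighted whitening**
`W_new = α·W + (1−α)·W_diag` with `W = C^(−1/2)` (symmetric inverse
square root via eigendecomposition) and `W_diag = diag(W)`. α defaults
to 0.1: with a single axon visible on every channel, full whitening
(α=1) cancels the common signal; α=0 reduces to per-channel scaling
(pure z-scoring when the covariance is diagonal).

### Velocity estimation

1. **Mean waveforms**: per channel, spikes are averaged on a 4 ms
   window (`half = round(window·fs/2)` samples each side, length
   2·half+1). Averaging K spikes shrinks noise ~1/√K (tested).
2. **Round-robin correction**: each channel's mean waveform is shifted
   by its slot delay (`slot·fs/adc_hz` samples) using an FFT fractional
   delay (multiply the rfft by `exp(−2πi f δ)`); measured RMS error for
   slot 17 on a band-limited waveform is 0.0028 (≪ 1%).
3. **Pairwise lags**: unnormalized cross-correlation
   `c[l] = Σ_t x_i[t+l]·x_j[t]`, lags ±n//2, validated exactly against
   a brute-force oracle. Sub-sample refinement fits a quadratic through
   the four largest correlation values; if those are not contiguous or
   not concave, the discrete argmax is used instead. Sign convention:
   `dt_s = −argmax_lag / fs`, so positive Δt means channel j lags i.
4. **Eligibility**: a channel pair enters the estimate only if both
   mean waveforms exceed 1.5 SD amplitude and the axial separation is
   non-zero. Pairs with |Δt| below one ADC slot period are excluded as
   near-simultaneous and counted separately.
5. **Velocity**: `V = mean(Δx/Δt)` over eligible pairs; the sign gives
   direction (ascending/descending). Estimates outside the
   observational bounds are flagged, not dropped.

Recovery on simulated units is within 5% over 0.33–5 m/s (tested at
0.33, 0.5, 1, 2, 5 m/s; e.g. 2 m/s → 2.008 m/s from 96 pairs).

### Observational bounds

`v_max = max_sep / sample_period` = 450 µm × 30 kHz = **13.5 m/s**;
`v_min = max_sep / (window/2)` = 450 µm / 2 ms = **0.225 m/s** (printed
0.23 with half-up rounding). `round_half_up` cleans its scaled argument
to 9 decimals first so exact halves stored as 0.224999… still round up.

Derived quantities: latency over a path (default 1 cm), e.g. 2 m/s →
5 ms; and the sufficiency velocity to traverse a length within a
deadline, e.g. 220 µm in 5 ms → 0.044 m/s (one significant figure
0.04). Ascending/descending speed distributions are compared with a
two-sample KS test; pooled |V| normality with Shapiro–Wilk.

## 5. Velocity–diameter exponent (`mle`)

Velocities and diameters come from different axons, so for each
candidate exponent k on a grid (default [0.4, 1.5], step 0.005,
endpoints included) the velocities are mapped to implied diameters
`d_est = |v|^(1/k)`; a Gaussian KDE of `d_est` with the classic
Silverman bandwidth `0.9·min(sd, IQR/1.34)·n^(−1/5)` scores the
measured diameters:

`LL(k) = Σ_i log max(KDE_k(d_i), 10⁻³⁰⁰)`.

Only diameters above `d_min` (default 3 µm) enter: the extracellular
probe resolves only large axons, so only the large-diameter tail is
comparable. The floor keeps the log finite for diameters far outside
the KDE support. The estimate is the grid argmax; exact ties break
toward the smaller k (logged). The whole grid is evaluated as one
(n_grid × n_d × n_v) broadcast (~tens of MB at the default sizes,
~25 ms per fit).

**Confidence intervals** are BCa bootstrap: velocities are resampled
with replacement (diameters held fixed, since the anatomical sample is
the larger, better-determined one), the grid search repeated (default
`n_boot` 10 000; the pipeline and acceptance tests use 500), bias
correction `z0` from the bootstrap CDF at the point estimate (with a
0.5·P(boot = k_hat) midpoint term and clipping), and acceleration from
a jackknife over velocities. A degenerate bootstrap distribution
collapses to a point interval with a warning.

Measured recovery at n = 150 with 5% velocity noise: |k̂ − k_true| of
1–2 grid steps across seeds (e.g. seed 0: k̂ = 0.645, 95% BCa CI
(0.640, 0.655) at n_boot = 500).

## 6. Synthetic data (`synth`): what it does and does not emulate

### Axon populations

Diameters are a two-component lognormal mixture — body
µ = ln 0.69 µm, σ = 0.641, plus a 2% giant tail (µ = ln 8 µm,
σ = 0.30) — truncated to [0.1, 15] µm. A 4437-draw sample gives mean
0.983 µm and median 0.687 µm (tested within 10% / 15% of 0.99 / 0.69).
Cross-section geometry is random sequential circle packing (largest
first) at packing fraction 0.40 in a 2:1 depth:span canvas; the
"gradient" profile rank-orders diameters along depth (large dorsal)
via per-circle depth windows, relaxing to the full range if a band is
too crowded. When rendering, a minimum edge-to-edge gap of 2 px is
enforced (membrane/glia clearance) so distinct axons stay distinct
8-connected components after rasterization; the canvas is sized with
gap-inflated radii so feasibility does not depend on the gap.

*Not emulated*: non-circular profiles, segmentation errors, glial and
tracheal territory (so area fractions are packing-fraction artifacts,
~0.39, not anatomical estimates), mosaic stitching seams.

### Recordings

Each unit is a Poisson spike train propagating at a fixed signed
velocity along the shank axis; every channel receives a biphasic
zero-net-area difference-of-Gaussians template (so it survives the
300 Hz high-pass) at the arrival time implied by velocity and position,
sampled at that channel's true ADC slot time; white Gaussian noise is
added and the result quantized to int16 (gain 256).

*Not emulated*: waveform change along the axon, amplitude decay with
distance, overlapping-spike interference, correlated noise, electrode
drift. These are exactly the confounds the eligibility rules
(amplitude threshold, near-simultaneous exclusion) address on real
data; here they mainly serve to validate the plumbing.

### Sheath and exponent samples

Sheath pairs: log10(d) uniform on [0.35, 1.1], log10(t) on the
generating line plus N(0, sd) (default 0.05); an optional inflated
scatter below 2 µm mimics the small-axon decoupling regime. Exponent
samples: diameters lognormal (log-mean 1.2, log-sd 0.35) truncated to
d > 3 µm; velocities are the *same* diameters raised to k_true with 5%
multiplicative Gaussian noise — i.e. paired generation of nominally
unpaired samples, which makes recovery tighter than fully independent
draws would be.

### Tile stacks

Lognormal-intensity texture tiles sharing one multiplicative gradient
(linear by default), for exercising the flat-field pipeline.

## 7. Reproducibility

All generators accept integer seeds or `numpy` Generators. The
pipeline fans a master seed out to per-stage seeds with
`SeedSequence.spawn`, records versions, config, and timings in
`report.json`, and same-seed runs are byte-identical (tested on the
written CSV/binary outputs). Hypothesis property tests run
derandomized. `scripts/acceptance.py --seed S --out F` recomputes the
exponent-recovery (t5) and sheath-slope (t6) numbers from scratch in a
few seconds on one CPU.

## 8. Known limitations

- The exponent MLE's grid step (0.005) bounds resolution; the BCa
  interval is discrete at grid points and may collapse for very clean
  data.
- The analytic OLS CI for the sheath slope assumes homoscedastic
  Gaussian residuals in log space — true of the generator, approximate
  for real traces.
- Velocity estimation assumes a single straight propagation axis and a
  stable template; curvature or waveform evolution would bias Δx/Δt
  averaging.
- `pair_lag`'s 4-point quadratic is never exactly symmetric about the
  peak, so even identical waveforms yield a ~10⁻³-sample residual lag.
- The flat-field mean map is estimated from finitely many tiles, so a
  residual correlation with the true gradient (|r| < 0.2 at 8 tiles in
  tests) remains in corrected tiles.
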