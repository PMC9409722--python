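# Methods

## Processing model

The chain estimates per-pixel tissue perfusion from single-channel raw
speckle frames. For each frame, the spatial speckle contrast
K = σ/⟨I⟩ is computed over a sliding square window (default 7 × 7 px),
using the population standard deviation (divide by n = 49; the sample
flavor would differ by < 2 % but the convention is fixed so hand
computations are exact). Window statistics come from uniform running-sum
filters with edge-reflection padding, so the output has the input's
dimensions; the (w−1)/2-pixel rim, and any window with zero mean, is
flagged in a border mask and carries no perfusion meaning. The filtered
implementation is required — and tested — to match explicit per-window
evaluation to ≤ 1e−8 relative at every interior pixel.

Contrast is mapped to laser speckle perfusion units as **LSPU = 1/K²**,
saturated at a cap (default 10⁴) where K ≈ 0. The underlying device
reports LSPU only as "inversely correlated" with K; 1/K² is our explicit
convention, chosen because under the Lorentzian model in the strong-blur
regime T ≫ τc it is proportional to 1/τc and hence to scatterer speed.
A 1/K alternative is available (`form="k1"`). Per-frame LSPU maps from a
20 fps stream may be averaged pixelwise (validity intersects).

Perfusion is displayed relative to healthy tissue: the reference value is
a statistic (default: 95th percentile, a robust "maximum perfusion in
healthy tissue"; mean available) of LSPU over a reference ROI, or over
all valid pixels when no ROI is given, and every pixel is expressed as a
percentage of it. Classification uses two thresholds, default 30 / 60 %:
percent < 30 → poor, 30–60 → marginal, ≥ 60 → well. **These defaults are
illustrative conventions, not clinically validated ischemia thresholds**;
establishing such thresholds requires pathology-anchored studies.
Underexposure masking (window-mean below 2 % of full scale) runs on the
same window as the contrast computation; masked pixels are labeled
invalid, rendered exact black, and excluded from all statistics.
Demarcation lines are extracted by marching squares on the label grid (at
midpoints between the label codes present), not on raw LSPU, so contours
coincide with the announced classes; invalid regions are NaN-masked and
contours cannot cross them.

## Simulation model

The simulator provides ground-truth phantoms: a per-pixel decorrelation
time map τc(x), region labels, and an illumination field (quadratic
radial falloff reaching 1 − falloff at the corners, emulating the
underexposed periphery of a laparoscopic field).

Fully developed speckle is synthesized as a circular complex Gaussian
random field band-limited by a circular Fourier aperture; intensity is
the squared magnitude, unit mean. The aperture radius is mapped
analytically to the speckle size (FWHM of the normalized intensity
autocovariance): for a uniform circular aperture of radius f_r cycles/px
the field autocorrelation is jinc(2π f_r r), giving
FWHM = 1.61634/(π f_r). The size estimator (autocovariance via FFT, row
and column profiles through the peak, sub-pixel linear interpolation)
closes the loop to within ±25 %.

Temporal dynamics follow a first-order autoregressive update of the
complex field, E ← ρE + √(1−ρ²)·ε with per-pixel ρ = exp(−Δt/τc) and
independent band-limited innovations ε — i.e. a Lorentzian field
correlation g₁(t) = exp(−t/τc), the model under which the closed form

K²(T, τc) = β·[τc/T + τc²/(2T²)(e^(−2T/τc) − 1)]

holds; the test suite verifies this form against direct numerical
integration of (2/T)∫₀ᵀ(1−t/T)|g₁|²dt. Finite exposure is integrated by
averaging n_subframes instantaneous intensities across the exposure.
Accuracy of the discrete integral requires Δt_sub ≤ τc/4, so
n_subframes defaults to auto-resolution, clip(⌈4T/τc_min⌉, 16, 256);
an explicit coarser value is honored with a warning. Where Δt/τc falls
below 1e−7 the update is snapped to the exact static limit so enormous
τc yields bit-identical frames. Frames are scaled by the illumination
field and target mean counts, optionally degraded by Poisson shot noise
(unit gain), Gaussian read noise and a dark offset, then clipped and
quantized to the requested bit depth (16-bit default) as the final step.

The coherence factor β is imposed by mixing the speckle intensity with an
incoherent constant background, I = √β·I_s + (1−√β), which scales
ensemble contrast by √β exactly. The *effective* asymptote seen by the
windowed estimator — which also carries a ~5 % depression from estimating
σ and ⟨I⟩ locally over ~10 independent speckle cells per 7 × 7 window at
the default 2 px speckle size — is calibrated empirically once per
(speckle size, window, β) as the squared mean interior contrast of static
frames, cached, and used as β_eff in all closed-form comparisons and τc
inversions. Using the same statistic for calibration and measurement
avoids a ~2 % Jensen-gap bias that a mean-K² calibration would introduce.

## Default phantom presets

The three-tier demonstration scene uses τc = 1 ms (well, background),
2.5 ms (marginal ellipse) and 50 ms (poor rectangle) at T = 20 ms —
values straddling the exposure so the tiers are distinct. With LSPU =
1/K², the marginal tier then sits near 42 % of the well tier's perfusion
and the poor tier near 6 %, placing them inside the marginal (30–60 %)
and poor (< 30 %) classification bands with comfortable margins against
per-pixel estimation noise. A marginal τc of 5 ms would land at ≈ 22 %
relative — inside the *poor* band under the default thresholds — which is
why 2.5 ms is the preset; all presets are configurable and none is
claimed to match in vivo bowel values (τc ranges, wavelength and β for
porcine bowel are not published for this device).

## Problem sizes and numerical choices

Simulation-based checks run on 256 × 256 frames (512 × 512 for global
statistics such as the energy and fully-developed-contrast checks), 4
frames per uniform-τc condition and 20 frames for the end-to-end phantom,
sizes at which ensemble statistics are stable to a few percent. τc
inversion brackets log τc over [1e−6 T, 1e6 T] (expanded as needed near
the K → √β asymptote) with Brent's method at machine-precision tolerance;
round trips are exact to 1e−6 relative. Contrast computation normalizes
by the frame maximum before filtering (K is scale invariant; this keeps
the variance subtraction well conditioned). Zero-mean windows define
K = 0 with validity false rather than 0/0 — such pixels are underexposed
and masked downstream anyway. Rectangles are half-open in 0-based
(row, col) coordinates; later phantom regions overwrite earlier ones.

## What the simulator does and does not emulate

It emulates: controllable speckle size with Nyquist-compliant sampling
(size ≥ 1 px), finite-exposure temporal integration, per-pixel
decorrelation encoding perfusion tiers, vignetting-driven underexposure,
and sensor shot/read noise on a quantized output. It does **not** model:
laparoscope optics or illumination geometry, multiple scattering or
tissue depth (one effective τc per pixel), static scatterer fractions
(no partially fluid voxels; the closed form carries no static term),
motion artifacts, or white-light scene content (a flat gray placeholder
stands in for side-by-side composition). Passing phantom-recovery tests
therefore demonstrates the correctness of the processing chain on data
obeying the stated speckle statistics — not clinical performance on
in vivo bowel, where β, τc ranges and artifacts differ.

## Known limitations

- LSPU values are relative, arbitrary units; cross-device or cross-study
  comparability is not implied.
- The 30/60 % classification thresholds and the 95th-percentile reference
  are conventions for phantom work, configurable per study.
- τc recovery assumes the Lorentzian model and a calibrated β_eff;
  model mismatch (e.g. Gaussian field correlation, static scattering)
  biases recovered τc.
- Temporal and spatio-temporal contrast estimators and multi-exposure
  imaging are out of scope; the chain is spatial-contrast only.
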