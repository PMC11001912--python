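# Methods

This note documents the models behind `reframan`: what the simulator
emulates, how each processing stage works, the defaults that matter, and the
limits of what the synthetic studies can show about real hardware.

## Instrument model

The simulated instrument is a dispersive dual-channel spectrometer: one
diode laser illuminates both the sample and a fixed polystyrene chip, and a
transmission grating images both Raman spectra onto separate row bands of a
single CMOS sensor covering roughly 800–960 nm.

**Laser** (`LaserModel`). A Fabry–Pérot diode at 785 nm (200 mW max, 0.2 nm
linewidth); a second 675 nm diode covers the high-frequency range on the same
sensor band. Three instabilities are modelled:

- *Thermal drift*: wavelength follows λ₀ + Δ·(1 − e^(−t/τ)) during warm-up.
  Defaults Δ = 0.3 nm, τ = 60 s — a warm-up on the minutes scale with a
  drift of a few cm⁻¹, the regime the calibration is designed for.
- *Mode hops*: with probability `hop_probability` per frame the emission
  jumps by ± one free spectral range, default 0.1 nm (typical for a short
  Fabry–Pérot cavity). A hop inside an exposure yields a multi-component
  `LaserState` (pre/post-hop wavelengths with a random time split, at most 3
  components) — the physical origin of hop-blurred spectra.
- *Power fluctuation*: relative power is a stationary AR(1) around 1
  (std `power_rel_std`, lag-1 correlation 0.9).

**Sensor** (`SensorModel`). 64 × 2000 binned pixels of 4 µm. QE is piecewise
linear through (840 nm, 60%) and (940 nm, 40%). Gaussian dark+read noise has
std 12 counts/pixel at 1 s, scaled with √exposure (dark-current shot-noise
scaling); the value is chosen so that desk-scale row-compression experiments
are dark-noise-dominated. Static per-pixel gain variation (σ_QE, the
pixel-to-pixel QE variation of 0.1–0.5%) is a map drawn once per instrument
instance — it cannot be averaged away in time, which is precisely why
drift-averaging matters. Shot noise is Poisson; hot pixels are injected at a
configurable fraction; counts clip at 16 bits.

**Optics** (`OpticsModel`). Pixel→wavelength map λ(c) = 800 + 0.08·c +
10⁻⁷·c² nm over 2000 columns (spans the sensor band; the real dispersion
geometry is not fully constrained, so the map is a plausible stand-in and is
treated as factory-known). The apparatus blur is the 5.4 µm slit image
convolved with the 4 µm pixel aperture; throughput 0.92. Reference band rows
8–13, main band rows 40–45, offset (out-of-focus fluorescence, SORS-like)
rows 50–61.

**Rendering.** Lines are converted per emission component to absolute
wavelength (λ = 10⁷/(10⁷/λ₀ − Δν)), mapped to columns, blurred with the
apparatus kernel, scaled by component weight × power × exposure ×
throughput × QE(λ), deposited uniformly over the band rows, multiplied by
the gain map, and noised. Line intensities are integrated areas, so
band-summed expected counts obey photon conservation exactly; with noise
off, rendering is deterministic and linear in exposure, power and line
area — those invariants anchor the test suite. The built-in polystyrene
reference renders at 2×10⁵ counts/s total: a solid scatterer centimeters
from the detector is bright, and this puts the reference channel SNR near
400 at 1 s so calibration noise never limits the chain.

## Wavenumber and intensity calibration

Reference lines use the ASTM E1840 consensus polystyrene positions (620.9,
1001.4, 1031.8, 1155.3, 1450.5, 1583.1, 1602.3, 2852.4, 2904.5,
3054.3 cm⁻¹); relative intensities and widths in the bundled line list are
representative values for the bulk polymer, with 1001.4 the strongest line.

Each catalog line is fitted with a pseudo-Voigt plus constant in a pixel
window around its predicted position. The fitted center is bounded to the
laser search range (±1 nm by default) around the prediction so a stronger
neighbor (1001.4 next to 1031.8, 1583.1 next to 1602.3) cannot capture the
fit. Per line, ν_laser = 10⁷/λ(c_fit) + Δν_catalog; the estimate is the
median over lines after one >3×MAD rejection pass (robust to a single
corrupted peak), requiring ≥ 3 usable lines and a residual spread below
5 cm⁻¹. Only the laser wavenumber is re-estimated per acquisition; the
optics map is monolithic and treated as fixed.

The calibrated axis is ν̂_laser − 10⁷/λ(c), resampled to a uniform
0.5 cm⁻¹ grid (≥ 10 points per ~7 cm⁻¹ resolution element). Counts per
pixel are converted to counts per cm⁻¹ through the local dispersion so line
areas survive resampling.

Intensity normalization divides by the integrated area of the 1001.4 cm⁻¹
reference line relative to a baseline acquisition. A single strong line is
used rather than the whole band because it is robust to fluorescence
baseline; the area itself is quadrature above a linear baseline fitted on
10 cm⁻¹ flanks outside the integration window — wide flanks keep baseline
noise below the peak's own shot noise (an edge-median baseline, and a fitted
pseudo-Voigt area, were both measurably noisier).

## Mode-hop deconvolution

The hop kernel k (integer pixel offsets, ≤ 15-pixel support, unit sum) is
estimated on the reference band by non-negative least squares of
observed ≈ clean ⊛ k, where "clean" is the hop-free reference model at the
estimated laser position. A ridge (Tikhonov) term is chosen by the
discrepancy principle: the largest weight whose residual stays within the
noise floor estimated from second differences. The estimate fails loudly
("kernel unreliable") when the residual exceeds both 10% of the observed
energy and 1.3× the noise floor, or when the observed band carries no
signal above noise at all.

The pipeline deconvolves only when a pure delta kernel *cannot* explain the
observed reference within noise: on hop-free frames the NNLS solution
spreads weight among near-collinear shifted columns (neighboring shifts of
a several-pixel-wide line are nearly identical regressors) and applying it
would sharpen spectra spuriously. Sub-pixel hops (the 0.1 nm spacing is
1.25 pixels) are approximated by weight splitting across adjacent offsets;
occasionally the residual then exceeds the reliability threshold and the
frame is processed without deconvolution, with a warning.

Deconvolution itself is 1-D Richardson–Lucy, authored in-package: inputs are
edge-padded by the kernel length to suppress boundary ringing, iterations
stop early when the relative update falls below 10⁻⁵ (default 30
iterations), non-negativity is preserved by construction and the output is
renormalized to the input flux (conservation within 0.1% is asserted in
tests).

## Apparatus function and deblurring

The line-spread function is measured from a line of known natural width —
diamond, Lorentzian FWHM 1.8 cm⁻¹ — by Wiener-regularized division in the
Fourier domain, with sub-pixel alignment via the line centroid, clipping to
non-negative and renormalization to unit area. The Wiener constant adapts to
the estimated noise-to-signal ratio (floor 10⁻³ for clean data): a fixed
constant either biases the width down on noisy data or blurs the estimate on
clean data. Deblurring is the same Richardson–Lucy engine with the apparatus
kernel (default 30 iterations; the resolution studies use more because
convergence of narrow features is slow). Resolution is reported from a Voigt
fit (lmfit; FWHM via the Olivero–Longbothum approximation) and the ASTM-style
quadrature rule resolution = √(measured² − intrinsic²).

## SERDS separation

On the calibrated shift axis the Raman spectrum is static while fluorescence,
fixed in absolute wavelength, moves by the excitation offset δᵢ =
ν_laser,i − ν_laser,1 (taken directly from the per-acquisition calibration;
offsets below one grid step are rejected as unidentifiable). The estimator
minimizes Σᵢ‖Sᵢ − R − TᵢF‖² + λ‖D²F‖² with R ≥ 0, where Tᵢ is a
linear-interpolation shift operator.

Numerically the problem is solved through the differences Sᵢ − S₁ =
(Tᵢ − T₁)F, in which the Raman part cancels exactly; F follows from a single
sparse penalized least-squares solve, then R = max(0, meanᵢ(Sᵢ − TᵢF)), with
the additive constant the differences cannot see fixed by putting R's
baseline at zero, and a few monotone alternating refinements. A naive
alternation starting from R = mean(S) is near-degenerate (a smooth static
component fits either R or F almost equally well) and converges to R
absorbing the fluorescence; the difference formulation avoids that entirely.
F is parameterized on the shift axis of the first acquisition — the same
linear operator as an absolute-wavelength parameterization, without an axis
conversion. λ defaults to 10⁴ per grid step, leaving F roughly 10 effective
degrees of freedom across a fingerprint band; a classical two-spectrum
difference mode (`serds_difference`) is kept for comparison.

## QE drift-averaging

After recalibration, a given wavenumber falls on a different physical pixel
in each drift-shifted acquisition, so the static gain pattern enters each
spectrum through different, independent gains. The pointwise mean over M
distinct alignments reduces the gain noise by ≈ √M (verified against the
simulator's gain-free truth); with no drift the same pixels repeat and
nothing is reduced — the pipeline warns in that case. The reported
diagnostic metric is the std of the residual after a Savitzky–Golay smooth
(window 11, order 3) in a peak-free window; note that averaging consecutive
alignments also correlates neighboring grid points, so this smoother-based
metric can exceed the √M pointwise factor.

## Quantification

PLS1 (scikit-learn, mean-centered, no scaling) maps calibrated spectra to
concentrations. Automatic model order minimizes leave-one-level-out CV RMSE
with a one-standard-error parsimony rule; all replicates of a concentration
level are held out together so replicate noise cannot leak. Detection limits
follow the blank-replicate convention, LoD = 3σ_blank/slope and LoQ =
10σ_blank/slope, with the slope from the low quarter of the calibrated
range. SERS maps are aggregated as the pointwise mean over quality-masked
map points. No SNV or other preprocessing is applied beyond the calibration
chain itself, so quantification performance is attributable to the
instrument model.

## Simulation studies and their scope

`reframan.studies` packages the headline experiments at desk scale
(seconds each, one CPU):

- *Calibration stability*: 50 frames, 0.3 nm drift, τ = 60 s, noisy
  reference (SNR ≈ 400); polystyrene in the main channel stays within
  ±2 cm⁻¹ of catalog and the laser wavenumber is recovered to ≤ 1.5 cm⁻¹.
- *Intensity normalization*: 20 bright acquisitions with power spread
  ±10%; normalized line areas agree within ±1%.
- *Row compression*: 500 replicates, identical total signal in 1 vs 20
  rows with 12 counts/pixel dark noise; the SNR ratio approaches the
  closed-form √20 ≈ 4.47 and always exceeds 3.
- *Deblurring*: 10 cm⁻¹ Gaussian apparatus on a 1.8 cm⁻¹ line at SNR 300;
  post-deblur fitted FWHM ≤ 7 cm⁻¹.
- *Reference identity*: the noiseless full pipeline puts the strongest
  polystyrene peak at 1001 cm⁻¹ to the nearest integer.

**What these do not show.** The simulator has no stray light, no speckle, no
sensor smear or blooming, no wavelength-dependent apparatus function (a
single worst-case profile is assumed column-invariant), no photobleaching
kinetics in SERDS, no radiative-transfer model behind the offset
fluorescence band, and a pixel→wavelength map that is plausible rather than
measured — so the printed pixel-limited resolution figures of a physical
unit are not reproduced, and detection limits on real samples cannot be
inferred from the synthetic mixture studies. Hop kernels are restricted to
integer pixel offsets; sub-pixel hops are only approximated. Passing studies
demonstrate that the *algorithms* achieve the stated tolerances under the
modelled noise processes, not that a particular physical unit does.

## Numerical conventions

Axes are stored ascending; pixel axes are integer-valued. Degenerate inputs
fail loudly: flat reference spectra, < 3 usable calibration peaks, residual
spreads above 5 cm⁻¹, zero reference-line area, non-overlapping resampling,
all-masked maps. Noise-free renders keep float precision (integers only when
noise is simulated) so exactness tests are meaningful. All randomness flows
through explicit seeds or `numpy.random.Generator` instances; identical
seeds give byte-identical pipeline outputs.
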