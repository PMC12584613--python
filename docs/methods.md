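# Methods

## Quantification model

All quantitative results rest on internal-standard normalisation of
Raman peak areas.  For species *a* (analyte) and *b* (internal standard)
measured in one spectrum, the area ratio is

A_a / A_b = (C_a / C_b) · (F_a / F_b),

where C is concentration and F the quantification factor — the product
of the Raman scattering cross-section σ and the instrument-response
coefficient η.  Neither σ nor η is identifiable on its own from ratio
data, and the package never estimates them individually: with the N₂
internal standard held at constant amount (0.3 MPa headspace), the whole
factor (F_a/F_b)/C_b is absorbed into the calibration slope *k* of

A_SO4 / A_N2 = k · C_SO4 + b.

*k* and *b* are estimated by ordinary least squares of ratio on
concentration, using all replicate points individually (not replicate
means).  Concentration is predicted by algebraic inversion,
C = (ratio − b)/k; the regression direction matches how calibration
data are plotted and printed.  Estimates outside the calibrated
concentration span are flagged `extrapolated` but not rejected, because
time-course concentrations may drift out of range.  Replicates are
aggregated on the concentration scale (mean ± sample SD over per-replicate
predictions), the quantity actually reported.

Peak areas enter the ratio from Gaussian fits, not raw integration;
trapezoidal integration (`peak_area_numeric`) is retained as a
model-free cross-check oracle.  For a Gaussian of height h and full
width at half maximum w the analytic area is h·w·√(π/(4 ln 2)), and
every fitted `Peak` satisfies this identity exactly by construction.

## Processing chain

Order is fixed: **despike → baseline → (optional) wavenumber
calibration → average**.  Spikes corrupt baseline estimates, so they are
removed first.

**Despiking.**  Cosmic rays strike 1–2 CCD columns, so a spike is an
impulse in the first-difference series: a large jump up immediately
followed by a large jump down (or the reverse for negative artefacts).
Both jumps are scored robustly — modified-z style — against the median
|difference| of the surrounding channels (default radius 10 channels),
floored by the global median |difference| so the noiseless limit cannot
divide by zero.  The local scaling is what lets a spike riding on a band
slope remain an outlier relative to that slope, while genuine bands,
which at 3× oversampling of the 3 cm⁻¹ instrument resolution rise over
many channels, never look impulse-like; a plain global z-score on first
differences flags band slopes on low-noise spectra.  Detection iterates
(≤ 4 passes) because repairing one channel of a two-channel artefact
exposes the second.  Flagged channels are replaced by the median of the
surrounding window (default 5 channels), spike channels excluded.
Default threshold z = 8.

**Baseline.**  Default method is asymmetric least squares (Whittaker
smoother, second-difference penalty λ = 10⁵, 10 iterations).  The
asymmetry was set to p = 0.001: with the conventional p = 0.01 the
baseline bulges ~3·10⁻³ of the band height under strong peaks, which
leaks band area into the baseline; at p = 0.001 the residual bulge is
~4·10⁻⁴ of band height while quadratic fluorescence-like backgrounds are
still tracked to < 1% of band height.  An iteratively clipped polynomial
(degree ≤ 6) is provided as a transparent fallback.  The decomposition
`corrected + baseline == input` is enforced bit-exactly (the fitted
baseline is nudged by at most 1 ulp per channel; channels whose
intensity is subnormal — band-tail underflow in noiseless synthetic
spectra — admit no exact two-float split against an O(1) baseline and
keep their full value in the corrected trace with baseline 0).

**Wavenumber calibration.**  The dominant band of a single-crystal
silicon reference spectrum is fitted in 470–570 cm⁻¹; the offset is the
fitted centre minus 520 cm⁻¹ and is subtracted from the axis.  The
correction is idempotent and a sanity bound |offset| < 50 cm⁻¹ guards
against fitting a non-silicon feature.

**Averaging.**  Replicate spectra acquired at distinct positions are
averaged elementwise with per-channel sample SD (ddof = 1); axes must
match exactly.

## Peak fitting

Fits are windowed sums of 1–5 Gaussians (FWHM parameterisation) via
Levenberg–Marquardt (lmfit).  A local linear baseline — the chord across
the window endpoints, with endpoint levels taken as the mean of the
outermost 3 channels to damp single-channel noise — is removed before
fitting even after global baseline correction, since the global step
cannot be assumed perfect; this also makes fits invariant to constant
offsets.  Parameters are bounded (centres inside the window, FWHM
between 2× channel spacing and the window width, heights ≥ 0) to prevent
component swapping during deconvolution.  Initialisation comes from the
n largest local maxima, or from explicit seed bands; the optimizer
restarts up to 5 times with seeded jitter on failure.  After
deconvolution of the sulfate window (default 930–1,030 cm⁻¹, 2
components when carotenoids are present) the component nearest
980 cm⁻¹ is labelled sulfate and the one nearest 1,005 cm⁻¹ carotenoid
overlap — a deterministic tie-break for downstream quantification.
Default windows and component counts are package conventions chosen to
isolate each marker band.

## Synthetic scenes

The generator emulates spectra at the gas–solid interface of a
solidified seawater medium under an N₂ headspace:

* **Axis** 200–2,500 cm⁻¹ at 1 cm⁻¹ spacing (3× oversampling of the
  3 cm⁻¹ spectral resolution keeps fits well conditioned).
* **Band shape** Gaussian — matching the fitting model, so recovery is
  exact in the noiseless limit and fit bias is measurable separately
  from model mismatch.
* **Band table** N₂ at 2,332 cm⁻¹ (FWHM 10, height 2,000 counts, fixed:
  the headspace pressure is constant by design); sulfate at 980 cm⁻¹
  (FWHM 8) with height chosen so the analytic area ratio sits exactly on
  the calibration line 0.01802·C − 0.04239; S₈ at 470 cm⁻¹; carotenoids
  at 1,005 / 1,157 / 1,523 cm⁻¹.  Only the 1,523 cm⁻¹ polyene C=C band
  is a printed assignment; the two companions are standard carotenoid
  bands included so the overlap-deconvolution scenario exists.  Absolute
  heights are generator conventions (no absolute intensities are
  published) and are recorded in truth JSON.
* **Baseline** polynomial in the wavenumber (default mild slope
  30 + 0.004·ν counts); **noise** additive i.i.d. Gaussian on counts
  (no published noise characterisation exists; shot-noise scaling is
  deliberately out of scope); **spikes** single-channel additive
  impulses, 2,000–8,000 counts, 30% per calibration spectrum.
* **Noise levels** `NOISE_SD_MID = 12.5` and `NOISE_SD_LOW = 2.5`
  counts: Monte Carlo calibrated so the pipeline-fitted sulfate area at
  50 mmol/L has ~0.5% and ~0.1% relative SD respectively.
* **Kinetics** logistic,
  c(t) = c0 + (c_max − c0)/(1 + exp(−rate·light_factor·(t − t_mid))),
  defaults c0 = 30, c_max = 70 mmol/L, t_mid = 40 h, rate = 0.15 h⁻¹.
  The defaults reproduce the three observed growth phases (moderate
  production to ~32 h, acceleration to ~48 h, slowing thereafter); no
  kinetic model is published, so the logistic is a package convention.
  `light_factor` multiplies the rate (dark < 1; 0.4 for the paired
  comparisons).

What passing tests on these scenes do **not** show: robustness to
non-Gaussian line shapes (Voigt/Lorentzian), fluorescence
photobleaching, detector nonlinearity, depth-dependent signal loss, or
spatially correlated noise — none of which the generator emulates.

## Time-course statistics

Rates are model-free: the maximum over sliding-window (default 3-point)
least-squares slopes of mean concentration versus time, ties broken to
the earliest window.  The "synthesis-cycle length" surrogate is the
midpoint-crossing time — the linearly interpolated time at which the
mean curve first reaches halfway between its initial and final values.
Paired light/dark analyses sample at 16–76 h every 12 h: a grid
symmetric about t_mid would make both conditions cross their midpoints
at exactly t_mid (a degeneracy of the logistic), whereas this grid,
beginning after the dark curve has already risen appreciably, separates
the crossings by ~2.6 h in truth.

## Problem sizes and numerical conventions

The acceptance script uses 5 concentrations × 3 replicates (15 spectra,
2,301 channels each) per calibration run and completes in seconds; the
paired light/dark ordering property in the test suite uses 100 runs of
6 time points × 2 replicates per condition.  Optimizer tolerances are
lmfit/MINPACK defaults; fitted-parameter standard errors are NaN when
the covariance is singular (exact noiseless fits).  File formats write
floats with `%.17g`, guaranteeing bit-exact text round-trips; map CSV
rows are ordered row-major by ascending y then x so outputs are
byte-reproducible.
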