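# Methods

This note records the models, numerical choices and validation logic behind
`fpolimg`, in the spirit of a software methods section.

## Fluorescence polarization model

A polarized-fluorescence imager splits emission into co- and cross-polarized
channels recorded by two detectors. The polarization of a pixel (or of a
pair of mean intensities) is

    Fpol = (I_co − G·I_cross) / (I_co + G·I_cross),

with the G-factor `G > 0` correcting the unequal sensitivity of the two
detection paths. `Fpol` lies in [−1, 1] whenever both intensities are
nonnegative and not both zero; the implementation raises on a zero
denominator rather than reporting a silent 0.

**Thresholding.** Pixels are valid when their value lies within inclusive
bounds (default low 2, high 254) in *both* channels. The joint rule is a
deliberate choice: a saturated or empty pixel in either channel corrupts the
ratio, so per-channel validity would leak corrupted pixels into the other
channel's statistics. The inclusive semantics match common image-analysis
thresholds (2 and 254 are kept; 0–1 background and 255 saturation are
dropped).

**Per-cell statistics.** For a compartment (whole cell, cell minus nucleus,
nucleus) the mean `I_co` and mean `I_cross` are taken over valid pixels and
the Fpol formula is applied once to the means — an intensity-weighted
estimate that matches the averaging protocol of quantitative Fpol imaging.
Averaging per-pixel Fpol values instead would weight dim pixels equally with
bright ones and differs under heterogeneity; it is available as an explicit
`pixelwise=True` option for sensitivity analysis, never as the default.
Compartments with fewer than `min_pixels` (default 20) valid pixels are
dropped — a floor chosen to bound the variance of the compartment means —
and cells touching the image border are excluded by default, as in standard
ROI practice. Pixels thresholded out inside an ROI are excluded from the
means (the alternative — including them — is not implemented; the choice is
visible in `n_valid_pixels`).

**Fpol is computed in floating point** from the integer channels. The
classic ImageJ route (8-bit emission and difference images, then a ratio)
re-rounds intermediates; tests assert agreement of the two conventions only
to ±0.01, which is the 8-bit quantization bound.

**G calibration.** A homogeneous solution of a freely rotating dye has
known polarization (0 in a non-viscous solvent), so
`G = mean(I_co)/mean(I_cross)` over valid pixels; the general known-`P0`
form is implemented. Calibration refuses references with fewer than 100
valid pixels (unstable ratio). With Poisson noise at ~100 counts/pixel and
10⁵ pixels, the estimate is reproducibly within 1% of truth; the residual
error is dominated by 8-bit rounding of the reference intensities.

**Rendering.** Fpol maps are displayed through a 256-entry pseudo-color
LUT (black → violet → blue → cyan → green → yellow → orange → red) over a
clamped display range, default [0, 0.34]: values ≤ 0 render black, values ≥
0.34 render red, invalid pixels render black. Any monotone black-to-red
LUT satisfies the same contract; the value→index mapping is linear.

## Co-localization

Per cell, co-localization of the dye channel with an organelle channel is
the sample Pearson correlation over the cell's whole-mask ROI. Whole-cell
ROIs were chosen over organelle-thresholded sub-ROIs because they are
reproducible without a segmentation rule and because the synthetic ground
truth (channel co-occupancy) is defined at the cell level; an Otsu sub-ROI
helper is provided for sensitivity analysis. Raw intensities are used
(no background subtraction). Degenerate ROIs — too small, or with a
constant channel — raise instead of returning a meaningless coefficient.
Only Pearson's R is reported; Manders/Costes statistics are out of scope.

## FLIM: bi-exponential reconvolution

TCSPC decay histograms are modeled as

    mu_j = [IRF ⊛ (a1·e^(−t/τ1) + a2·e^(−t/τ2))]_j + b,

with amplitudes in counts/ns, so `a1τ1 + a2τ2` is the expected signal
count. Photon counts are Poisson, so parameters are estimated by minimum
Poisson deviance (maximum likelihood) rather than unweighted least squares.

Numerical choices, in decreasing order of consequence:

- **Bin-integrated convolution.** The exponential is integrated
  analytically over half-shifted bins before discrete convolution with the
  center-sampled binned IRF. This makes the discrete sum an exact
  quadrature of the reconvolution integral and removes the half-bin
  alignment bias that point sampling introduces — material for lifetimes
  within an order of magnitude of the bin width (e.g. 0.27 ns on 6 ps bins).
- **Profiled amplitudes.** For fixed lifetimes the model is linear in
  (a1, a2, b); these are profiled out with a monotone multiplicative EM
  update (Richardson–Lucy form), which preserves nonnegativity without
  constraints. Lifetimes are then optimized by Nelder–Mead on log(τ),
  with a polish restart from the first optimum.
- **Deterministic initialization.** τ₂ from a log-linear fit of the tail
  half of the post-peak, counts ≥ 10 region; a first-quarter slope seeds
  τ₁, clamped to [Δt, τ₂/1.5]. No randomness enters the fit.
- **Mono-exponential guard.** A mono fit always runs first; if the second
  component fails to improve the deviance by the χ²(2 dof) 99% quantile
  (9.21), or the two fitted lifetimes coincide within 1%, the fit is
  flagged `effectively_mono` and reported with `a2 = 0` — avoiding the
  arbitrary amplitude split that a degenerate two-component optimum
  produces.
- **IRF handling.** A measured (binned) IRF is used when supplied. With
  `irf_mode="fitted_gaussian"` or no IRF, a Gaussian IRF (center, FWHM) is
  fitted jointly with the decay — the minimal-assumption stand-in for
  software-reconstructed IRFs.
- **Goodness of fit.** Reduced χ² is Neyman-weighted (variance
  `max(count, 1)`) over bins where the fitted model expects ≥ 10 counts,
  with dof = used bins − free parameters. The floor exists because
  Neyman weighting is badly biased in near-empty tail bins; with it, the
  statistic is calibrated (mean ≈ 1.0 on well-specified simulations,
  within [0.9, 1.1] in the test grid). A fit is `accepted` when reduced
  χ² lies in the inclusive gate [1.0, 1.5]; values below 1 are logged as
  possible overfits but not auto-rejected in simulations.

The amplitude-weighted lifetime `τ = (a1τ1 + a2τ2)/(a1 + a2)` summarizes a
cell; per-cell lifetimes come from aggregated per-cell decays (better
photon statistics than averaging pixel-wise fits; the alternative is noted,
not implemented). FLIM maps color each cell by τ clamped to [0.2, 1.0] ns
through a blue-to-red LUT.

At 10⁶ photons with a 0.12 ns FWHM IRF, both lifetimes of a
(0.27, 0.75) ns decay with a1/a2 = 1.5 are recovered to well under 5%
(typically < 1% for τ₂); the test grid bounds the median relative error at
5% (lifetimes) and 3% (amplitude-weighted lifetime).

## Group statistics

Per-cell values are summarized as mean ± SE, with SE = sample sd
(ddof = 1)/√N — the convention of `scipy.stats.sem`. Cancer-vs-normal
contrast is the percent difference `100·(mean_cancer − mean_normal)/
mean_normal`, i.e. the normal line is the denominator; this convention
reproduces all of the published percent ranges (12–20% whole cell, 13%
smallest nucleus-excluded, 8–14% nuclei) from the published group means.
Display values round half-up to integer percent; unrounded values are kept.
One published upper bound (22% for the nucleus-excluded compartment) is not
derivable from the corresponding printed means under any plain
percent-difference convention (they give ≈ 20%); the package reproduces
what the means imply and does not special-case the discrepancy.

**Hierarchical permutation test.** Cells within an imaging experiment are
correlated, so cell-level permutation overstates significance. The test
statistic is the difference of group means; the null is generated by
permuting group labels *within* experiments when the two groups share
experiments (paired replicate design), or by reassigning whole experiments
to groups when the experiments are disjoint. With as few as 5 experiments
per group, experiment-level reassignment has only C(10,5) = 252 distinct
outcomes, so very small p-values are attainable only in the paired design —
a structural property of the design, not of the implementation. Without
usable replicate structure the test falls back to cell-level permutation
with an explicit pseudo-replication warning. Two-sided p-values use the
add-one convention (never 0, never below 1/(B+1)); B defaults to 10⁴.
Type-I error is verified by simulation (200 nulls with experiment random
intercepts: rejection at α = 0.05 within [0.02, 0.09]) and power exceeds
0.9 at α = 0.001 for a +0.03 Fpol shift at N = 100 cells/group across 5
shared experiments. A random-intercept linear mixed model (statsmodels) is
available as a cross-check, not as the validated surface.

## Synthetic data: what it emulates, and what it does not

- **Polarized pairs.** Cells are non-overlapping ellipses (bounding-circle
  packing by rejection sampling; an explicit `PackingError` replaces
  silent overlap) with strictly interior elliptical nuclei. Intensities
  invert the Fpol formula — `I_co = k(1+P)`, `I_cross = k(1−P)/G` with
  `k = total_intensity/2` per compartment — so analysis with the same `G`
  returns the prescribed `P` exactly before noise and quantization; the
  noiseless round trip is exact to ≤ 0.01 (8-bit bound). Defaults
  (cytoplasm 0.20, nucleus 0.24, G = 0.75, ~150 total counts/pixel,
  Poisson noise) put fields at the per-cell Fpol scale of breast epithelial
  cells with the nucleus the more polarized compartment. The instrument's
  actual photon budget is unpublished; the noise level is a free parameter,
  not an estimate of any specific PMT.
- **Co-localization stacks.** Organelle puncta are disks scattered in the
  cell; the dye channel places a `co_occupancy` fraction of its punctate
  signal on those disks and the rest on decoy disks kept disjoint from
  them. Expected per-cell Pearson R therefore increases strictly with
  co-occupancy, from slightly negative (disjoint supports) to 1 (identical
  supports) — the property the acceptance suite tests.
- **Decays.** Expected curves are evaluated in closed form as
  exponentially-modified-Gaussian mixtures (stable `erfcx` evaluation),
  scaled to the photon budget, with Poisson sampling per bin. The
  generator's continuous forward model is deliberately *not* the fitter's
  discrete convolution, so recovery tests are not a self-inverse exercise.
  A window shorter than 5·τ₂ triggers a truncation-bias warning.
- **Not modeled:** point-spread-function optics, confocal sectioning,
  spectral bleed-through, irregular cell shapes, spatial intensity
  gradients, detector afterpulsing, and IRF asymmetry. Passing tests
  therefore demonstrate correctness of the estimators under the stated
  noise models, not robustness to every instrument artifact.

Determinism: every generator takes a seed and identical (spec, seed) pairs
produce bit-identical outputs; the CLI records seeds and a spec hash in the
fixture manifest.

## Problem sizes used in the validation suite

The test suite favors the smallest sizes at which the statistical
assertions are stable: 100-cell Poisson fields (512²) for Fpol recovery,
40 cells per co-occupancy level, 20-seed calibrations, 20 decay fits at
10⁶ photons for lifetime recovery, and 200 null simulations with B = 999
permutations (B = 4999 for the power check). The acceptance script uses
20 replicate decays at the full 25 ns / 4096-bin resolution.

## Known limitations

- Registration of the co/cross channels is assumed perfect (simultaneous
  two-detector acquisition); no registration step is provided.
- No numerical-aperture depolarization correction or flat-field
  correction; anisotropy (r) is not offered as an alternative statistic.
- Pixel-wise FLIM fitting and ≥3-exponential models are out of scope.
- The Otsu-plus-watershed segmentation helper is a convenience for real
  data, not part of the validated surface — masks are inputs.
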