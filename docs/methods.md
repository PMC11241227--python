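# Methods

`mircoag` implements the chemometric workflow used to build and judge
mid-infrared (MIR) prediction models of milk coagulation traits — rennet
coagulation time (RCT, min), curd-firming time (k₂₀, min) and curd firmness 30
minutes after rennet addition (a₃₀, mm) — from bulk-milk absorbance spectra
recorded as log(1/T) over 5000–900 cm⁻¹ (1060 points). This note records the
model, its assumptions, the numerical conventions, and what the synthetic
testbed does and does not establish.

## Data model and censoring

Spectra are stored with an ascending wavenumber axis regardless of file
order; one canonical orientation keeps the derivative operators unambiguous.
Water-dominated regions are excised before modelling as closed intervals
(inclusive endpoints): 1566–1712, 1817–2696 and 2975–3700 cm⁻¹ by default.
The third interval covers the broad O–H stretch; all three are configurable.

Milk that fails to clot within the 30-minute Formagraph window is *censored*:
its coagulation traits are unknown, not equal to 30. Records carry a
`coagulated` flag and censored records hold no trait values at all, so a
sentinel can never leak into a regression. Censored samples are discarded
before any modelling, matching practice for this assay.

## Preprocessing

Scatter corrections operate per spectrum:

- **SNV** centres each spectrum and scales it to unit sample standard
  deviation (ddof = 1; fixed for bit-reproducibility).
- **Detrend** removes the degree-2 polynomial baseline by OLS on
  {1, w, w²}, with the wavenumber regressor centred and scaled before the fit
  for conditioning (the residuals are unchanged by this rescaling).
- **SNV+D** is SNV followed by detrending, in that order.
- **MSC** regresses each spectrum on a reference (the calibration-set mean
  unless supplied) and inverts the fitted affine distortion; a slope below
  1e-8 in magnitude is an error naming the offending row.

Math treatments use the four-digit code (d, gap, s1, s2): a running-mean
smooth over s1 points, d applications of a gap difference across `gap`
points, then a running-mean smooth over s2 points. After the first smoothing
the gap difference equals the difference of two s1-point segment averages
whose starts are `gap` points apart, which is the heritage "gap–segment"
derivative. (0,0,1,1) is the identity. Only indices where every window fits
are kept — no padding or extrapolation — and the axis is trimmed to the
window-centre wavenumbers. Whether the first smoothing precedes or is folded
into the derivative is a convention; the one chosen here is documented above
and locked by loop-oracle tests. Scatter correction is applied before the
math treatment.

## Modified PLS

The regression is single-response PLS1 by NIPALS with the Shenk–Westerhaus
modification: after each latent factor is extracted, the X-residual at every
wavelength is divided by the standard deviation of the residuals at that
wavelength before the next factor is computed. Later factors therefore see a
re-weighted residual space in which no wavelength region dominates by
variance alone. y-residuals are not rescaled. With the standardization
switched off the algorithm reduces *exactly* to conventional PLS1, which is
the lever the test suite uses: an independent NIPALS implementation
(scikit-learn's `PLSRegression`, scale off) must agree to 1e-8.

Composite coefficients are accumulated for every factor count k, so a single
fit yields predictions for all candidate model sizes:
ŷ = ȳ + (x − x̄)·b_k. Residual-scaling vectors are floored at a tiny
relative value (1e-12 of their maximum) to stay strictly positive; if the
residual collapses earlier (rank-deficient data) extraction stops with a
warning and the model truncates.

Conventions for the statistics:

- SEC = √(RSS / (N − LF − 1)) — the extra −1 accounts for the intercept.
- SECV = √(pooled out-of-fold RSS / N) from seeded 15-fold CV with fold
  sizes differing by at most one; every fold model is a full mPLS refit.
- R²CrV = squared Pearson correlation of pooled out-of-fold predictions with
  the reference values (a 1 − RSS/TSS variant is selectable).
- The factor count (LF) is the smallest k whose SECV lies within 2% of the
  curve minimum, capped at 16. The 2%-band rule is this package's declared
  stand-in for the proprietary WinISI selector; the cap of 16 comfortably
  exceeds the 6–13 factors typical for these traits.

## Outlier elimination

Screening runs in the usual order, and cross-validation is re-run after each
elimination round (this is how the "iterative" cross-validation is read
here):

1. **Global H** — the model is fitted once, samples are scored in factor
   space, and GH = D²/LF is computed with the maximum-likelihood score
   covariance, so mean GH over the calibration set is exactly 1. Samples with
   GH > 3.0 are removed in a single pass. Removing more than half the set
   aborts with a diagnostic (data and model are then inconsistent).
2. **T rounds** — up to three rounds: refit with CV, form
   T = |ŷ − y| / SEC on the calibration samples (SEC of the current round's
   model; a SECV denominator is available), remove T > 3.0, stop early when a
   round removes nothing (further rounds would be no-ops).

The audit report stores every per-sample statistic per stage, so removal
percentages can be computed jointly or per stage.

## Validation statistics

The 75/25 calibration/validation split draws 200 seeded random candidate
splits and keeps the one minimising the summed standardized discrepancy of
per-trait means and SDs — a best-of-candidates search rather than explicit
stratification. On the validation side: bias = mean(ŷ − y);
slope = OLS slope of y on ŷ; SEP = √(Σ(ŷ − y − bias)²/(n−1)) (the
bias-corrected "SEP(C)" convention); R²ExV = squared Pearson correlation;
RPD = SD(y)/SEP, reported as +∞ when SEP is 0. The identity RPD·SEP = SD
holds to machine precision by construction.

Usability bands map (R²ExV, RPD) to a category: *not recommended* when both
R²ExV < 0.66 and RPD < 0.75; otherwise each statistic maps to its published
band — screening (0.66–0.81 / 1.7–2.2), caution (0.83–0.90 / 2.3–3.5), most
applications (0.92–0.96 / 3.6–4.9), any application (> 0.98 / > 5.0) — and
the lower category wins. Values in the gaps between published bands take the
band below; the gap beneath the screening band is labelled *below screening*,
a label this package adds because the published scale leaves that interval
unnamed. Slope adequacy: |slope − 1| ≤ 0.05 adequate, ≤ 0.15 acceptable,
otherwise imprecise at the extremes of the range.

## Study sweep

`run_study` crosses five scatter options with five math treatments (25
candidates per trait), runs censoring, the balanced split, preprocessing
(MSC reference learned on the calibration rows only), outlier elimination,
and the final CV fit in every cell, then validates externally. The winner per
trait is the candidate with the lowest SECV at its selected factor count
(ties: fewer factors, then grid order). Choosing on a validation statistic
would leak the held-out set into model selection, so the winner is decided on
calibration information alone. A failing cell is logged and skipped. All
randomness derives from one top-level seed via deterministic substreams, so a
report is bit-reproducible.

## Synthetic testbed

The generator emulates the statistical structure the analysis assumes:

- **Composition** — truncated normals with the survey moments
  (fat 7.87 ± 1.19%, protein 4.64 ± 0.35%, casein 3.68 ± 0.36%,
  lactose 4.64 ± 0.18%, truncated at the observed minima/maxima); casein is
  correlated with protein (ρ = 0.85); SCC is a clipped lognormal matched to
  mean 181.5 and SD 274.1 cells/µL.
- **Spectra** — Beer–Lambert sums of Gaussian bands per constituent at the
  wavenumbers where milk constituents absorb (lactose 1045/1076/1157/1250,
  protein ~1550, fat 1390/1454/1743/2862/2927 cm⁻¹), plus strong water bands
  centred inside the masked regions, a random quadratic baseline, a
  per-sample multiplicative factor (SD 2%), and white noise (SD 1e-3
  absorbance). Band widths are configuration, chosen so the neighbouring
  lactose bands partially overlap; they are not claims about real milk.
- **Traits** — linear in standardized latent composition plus Gaussian
  noise, with total SD held at the survey value. RCT decreases and a₃₀
  increases with casein; these directions are a modelling choice that makes
  recovery testable, not an asserted mechanism. SCC carries no spectral
  signature and no trait loading by default, mirroring how weakly MIR sees
  somatic cells.
- **Censoring** — a Bernoulli 3.38% of samples are non-coagulating; their
  noise-free RCT is drawn above 30 min and their observed traits are absent.

Each trait's `noise_fraction` ν splits the SD between signal (√(1−ν²)) and
noise (ν), making prediction difficulty a single monotone dial.
`calibrate_noise_for_target` bisects ν until a quick pipeline (generate →
censor → mask → split → preprocess → 15-fold CV fit → external validation;
outlier stages skipped, since the generator plants none and the evaluator
runs inside a bisection loop) attains a requested external R². The shipped
defaults were fixed this way against the survey's reported performance
(R²ExV 0.40 / 0.41 / 0.57): ν = 0.72 (RCT), 0.73 (k₂₀), 0.576 (a₃₀).
Between-seed scatter of the achieved R² is roughly ±0.05 at n = 600.

What passing on this testbed shows: the pipeline recovers linear
composition→trait structure through realistic scatter artifacts, selects
sensible model sizes, and degrades gracefully to the reported difficulty when
noise is dialled in. What it does not show: performance on real milk, where
the trait–spectrum dependence is unknown (that uncertainty is precisely why
bulk-milk MIR coagulation models are hard), where herd/season structure
induces correlated errors, and where instrument drift is not white.

## Problem sizes and numerical choices

Defaults follow the emulated study: n = 1736 samples, 1060-point axis,
15-fold CV, 16-factor cap, GH/T thresholds 3.0, three T rounds, 200 split
candidates. Tests and the acceptance script use n = 400–600 for replicated
checks and the full n = 1736 with the complete 25-cell grid for the
end-to-end study. Degenerate inputs fail loudly: constant spectra under SNV,
near-zero MSC slopes, constant y, singular score covariances, and masks that
would remove every wavenumber all raise informative errors. Model
serialization is JSON with full-precision floats and round-trips bit-exactly.

## Known limitations

- The gap-segment windowing and the LF-selection band are documented
  conventions validated against internal oracles, not against the
  proprietary reference software.
- The published interpretation scale has unnamed gaps; the "below screening"
  category is this package's addition.
- The printed non-coagulation percentage (3.38%) and count/total (58/1736 =
  3.34%) disagree slightly in the source survey; the generator uses the
  printed rate.
- Trait generation is linear in composition; any nonlinear dependence of
  coagulation on milk chemistry is outside the testbed.
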