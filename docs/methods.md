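# Methods

`hrvbold` implements an analysis pipeline linking heart-rate
variability (HRV) to voxelwise BOLD signal variability (SD_BOLD) in
resting-state fMRI, together with a synthetic-data generator that
plants the effect structure the analysis is designed to detect. This
note records the models, the parameters that matter, the numerical
choices, and what the synthetic validation does and does not show.

## SD_BOLD

SD_BOLD quantifies a voxel's temporal BOLD variability while
suppressing slow scanner drift. For a run of T volumes (the first 5
discarded as T1-saturation transients):

1. the series is cut into blocks of `block_len = 10` volumes; trailing
   volumes that do not fill a block are dropped (padding would give the
   last block unequal variance weight);
2. each block is multiplied by `100 / (block 4D mean)` so its mean over
   in-mask voxels and block time points is exactly 100 — this removes
   global gain and step drift. The 4D mean is taken over in-mask voxels
   by default (out-of-brain zeros would distort the factor); a config
   flag (`scale_masked_only=False`) computes it over the whole field of
   view instead, since the original description of the method does not
   settle the point;
3. each voxel's within-block temporal mean is subtracted, the blocks
   are concatenated, and the SD of the concatenated residuals is the
   voxel's SD_BOLD.

The map is invariant to a global intensity gain and maps any signal
constant within every block to zero; both properties are asserted
numerically (1e-8 relative) in the tests, along with exact agreement
with a brute-force transcription of the three steps on a toy run.

The SD divisor is population (n) by default, matching common
implementations of the method; `divisor="sample"` selects n-1. With
10-point blocks, demeaning shrinks the expected SD by
sqrt((L-1)/L) = 0.9487 relative to the generating noise SD — this
factor matters when interpreting planted amplitudes.

For windowed analyses, SD_BOLD is recomputed from each window's own
volumes (blocks formed within the window) so that every window is a
self-contained observation.

## HRV measures

Input is a series of NN (normal-to-normal) inter-beat intervals with a
per-interval validity flag; artifact segments marked upstream are
invalid but retained, preserving the temporal structure.

* **SDNN** — sample SD (n-1) of valid intervals, ms. The divisor is a
  convention choice (the field's tooling mostly uses n-1); it is
  configurable nowhere because it only rescales by a constant factor
  for fixed n.
* **RMSSD** — root mean square of successive differences over pairs of
  *adjacent valid* intervals; pairs spanning an invalid interval are
  excluded.
* **LF / HF power** — the tachogram (interval vs. beat onset time) is
  cubic-spline interpolated to a uniform 10 Hz grid, mean-removed, and
  an FFT periodogram is integrated by the rectangle rule over
  0.04-0.15 Hz (LF) and 0.15-0.40 Hz (HF). Absolute power in ms² is
  reported, not normalized units, and no window function is applied
  beyond mean removal — the simplest faithful reading of an
  FFT-periodogram specification; both choices are surfaced in the
  config. Interpolation is restricted to contiguous valid spans with
  at least 4 beats; gaps are never bridged, and spans are combined by
  a duration-weighted average of their band powers. A span must cover
  two cycles of the band's lower edge (50 s for LF), otherwise the
  measure is signalled undefined.
* All analyses use natural-log-transformed measures (HRV distributions
  are right-skewed); the base is a monotone-equivalent convention.
  A log of a non-positive raw value is NaN, the per-field
  undefined-measure signal.

A minimal peak detector (local maxima over an adaptive quantile
threshold with a 300 ms refractory period) is provided for synthetic
pulse waveforms only; cleaning of real photoplethysmography is
expected upstream.

## Behavioral PLS

Predictors (age and/or the four log HRV measures) and per-voxel
SD_BOLD values are z-scored across subjects (divisor n-1), so the p×v
cross-product matrix `R = X'Y/(n-1)` holds exact Pearson correlations.
SVD of R yields latent variables: predictor saliences (U), unit-length
voxel-salience patterns (V), and singular values whose normalized
squares are the fraction of cross-block covariance explained. Brain
scores are `Yz V`; z-scored voxel data are used for both R and the
scores. Single-block models are interpreted on LV1; the joint
age+HRV model on LV1 and LV2.

Numerical conventions:

* **Sign**: each LV is scaled so its largest-magnitude predictor
  salience is positive — SVD signs are otherwise arbitrary and
  platform-dependent.
* **Permutation test** (default 1000 iterations): subject rows of X
  are permuted with Y fixed (row permutation of z-scored columns needs
  no re-standardization), the SVD refitted, and permuted singular
  values compared rank-matched per LV index;
  `p = (#{s_perm >= s_obs} + 1)/(n_perm + 1)` (add-one convention, so
  p is never 0).
* **Bootstrap** (default 1000 iterations): subjects resampled with
  replacement jointly in X and Y, re-standardized within the replicate
  so R remains a correlation matrix; each replicate's voxel-salience
  column is sign-aligned to the original by the sign of their dot
  product (a full Procrustes rotation is not needed for per-LV ratio
  maps and would break determinism guarantees). The bootstrap ratio is
  mean replicate salience over its SD across replicates; |BSR| > 2.70
  approximates a 99% CI. Voxels with zero bootstrap SE are flagged
  non-significant (the ratio is undefined); replicates with a
  zero-variance predictor column are redrawn and counted.
* **Effect direction**: `sign(voxel salience) x sign(slope of brain
  scores on the raw predictor)`; +1 means the predictor is associated
  with increased SD_BOLD at that voxel.

Under a null cohort the add-one permutation p is slightly conservative
by construction (rejection probability 10/201 at alpha = .05 with 200
permutations), and the null BSR flag rate at 2.70 runs near 2% rather
than the Gaussian 0.7% — the sign-alignment step fattens the tails of
null salience distributions slightly. Both calibrations are measured
in the acceptance tests.

## Concordance

Each voxel is classified by the agreement of the age and HRV effect
directions: concordant positive, concordant negative, opposite, or
negligible (either direction zero, or below an optional |BSR| cutoff —
no cutoff by default, so the four percentages partition 100%). Two
modes are exposed, because direction can be read from the signed
effect direction or from the raw LV1 salience sign, and published
descriptions of this analysis are ambiguous between the two; the mode
is recorded on the result and both appear in the pipeline output.

## Sliding-window within-person analysis

The scan is cut into 4-minute windows at 50% overlap (three windows
for an 8-minute scan, starting at 0, 120, 240 s). An HRV interval
belongs to the window containing its onset; overlapping windows share
intervals by design. Windows with more than 120 s of artifact time
are excluded, as are windows where an HRV measure or a full SD_BOLD
block cannot be computed (rows keep a reason code).

Per subject and HRV measure, person-centering subtracts the subject
mean and divides by the subject SD across valid windows (sample
divisor — with three windows the divisor materially changes the scale,
so it is explicit and configurable in one place). Subjects need at
least 2 valid windows and nonzero within-subject variance, otherwise
they are dropped with a log entry. Spectral measures on 4-minute
windows have half the frequency resolution of the full scan; they are
computed identically, and the resolution difference is simply a
property of the windowing.

The mixed model per HRV measure is

    mean_sd_bold ~ person_centered + person_mean + age + sex + race
                   + (1 + person_centered | subject)

fitted by REML. Three observations per subject often cannot identify
a random-slope variance; on non-convergence the model falls back to a
random intercept only and the fit is flagged. The age model (age is
constant within subject) uses a random intercept only. Sex and race
enter as binary indicator codes throughout.

## Between-subject regressions

Each log HRV measure is regressed on age by OLS in a separate model
(avoiding collinearity among HRV indices), with sex and race as
covariates and two-sided p-values. Benjamini-Hochberg step-up FDR
correction is applied across the four HRV outcomes within a sample.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
at desk scale: 60 subjects aged 26-76 (uniform), sex/race Bernoulli
(47% male, 69% white), 240-volume runs at TR 2 s on a 12³ grid with an
all-true mask — large enough for a stable SVD, small enough for
resampling on one CPU. Paper-scale voxel counts are unnecessary for
validating the math.

* **Covariates**: each log HRV measure is a baseline (log 45 ms SDNN,
  log 35 ms RMSSD, log 600 ms² LF, log 300 ms² HF) plus an age trend
  of `age_hrv_slope = -0.01`/year (doubled for the power measures,
  which live on a squared-amplitude scale), a shared subject deviation
  (SD 0.2, truncated at ±3 SD — QC-style outlier exclusion that also
  keeps the SD plant below positive-definiteness limits), and
  measure-specific noise.
* **Tachograms**: intervals are mean RR (drawn ~N(900, 80) ms) plus
  0.10 Hz and 0.25 Hz sinusoids whose amplitudes are set from the
  subject's target LF/HF powers, plus white jitter sized so total
  interval variance matches the subject's target SDNN². Intervals are
  floored at 1% of mean RR, so the series is strictly positive under
  any jitter level.
* **BOLD runs**: voxel series are `offset + sigma_v * g(t) * N(0,1)`
  with `offset = 1000` (so block scaling is well-conditioned, mimicking
  arbitrary scanner units), independent across voxels, with an optional
  shared global component. For a fixed 70% of voxels (the affected set
  is derived from the cohort seed, hence identical across subjects),
  `sigma_v = noise_sd * (1 + 0.2 z(log SDNN) - 0.05 z(age))`; a
  negative implied SD is rejected with an error. With `noise_sd = 10`,
  baseline mean SD_BOLD on the scaled intensity scale is
  10 · (100/1000) · 0.9487 ≈ 0.95.
* **Within-person plant**: per subject, a window profile (z-scored
  across the three windows) modulates both the tachogram jitter
  (relative amplitude `within_hrv_mod = 0.2`, a plausible within-scan
  HRV swing) and the BOLD noise amplitude. Because windows overlap
  50%, amplitudes are piecewise constant on the half-window segment
  grid and segment variances are solved exactly (the linear system has
  one free parameter, chosen mid-feasible-interval) so that each
  window's average noise variance hits its target. The BOLD targets
  are calibrated so window mean SD_BOLD shifts by
  `within_coupling = 0.01` SD_BOLD units per z-unit of the profile —
  the quantity the mixed model estimates.

Every generator is a pure function of its arguments including the
seed (per-subject streams are spawned from a `SeedSequence`, so runs
are bit-reproducible). BOLD noise is generated in float32 for
throughput; all SD computations upcast to float64.

**What the synthetic validation shows**: that the estimators recover
exactly the structure they target (planted couplings, calibrated
nulls) at study-like n. **What it does not show**: robustness to
hemodynamic response shape, pulse waveform morphology, motion or
drift artifacts, spatial autocorrelation, or non-Gaussian BOLD noise
— none of which the generator models (drift within blocks is exactly
what SD_BOLD is designed to remove, and confound regression is
assumed done upstream). Passing tests validate the arithmetic and the
inference machinery, not the physiology.

## Problem sizes in the validation suite

The resampling-calibration tests use 100 null cohorts (n = 60, 12³
voxels, 200 permutations) for the permutation type-I check and 10
null cohorts × 200 bootstrap replicates for the BSR false-positive
rate; planted-effect recovery uses 20 seeded cohorts shared between
the PLS and within-person checks. The acceptance script runs one full
cohort with 1000 permutations and 1000 bootstrap iterations per
model. These sizes keep the whole suite within a few minutes on one
CPU while leaving the binomial acceptance bands meaningful.

## Known limitations

* The periodogram has no tapering or Welch segmentation; very long
  series with strong nonstationarity would benefit from both.
* Band power over gappy series averages per-span periodograms; spans
  shorter than two cycles of the band's lower edge contribute nothing,
  so heavily fragmented recordings can render LF power undefined.
* The mixed model's random-slope variance is weakly identified with
  three windows per subject; the intercept-only fallback changes the
  fixed-effect SEs slightly.
* `inject_artifacts` marks whole intervals invalid; sub-interval
  artifact overlap is not prorated.
* The within-window variance plant is exact only for 0% or 50% window
  overlap; other overlaps raise an error rather than planting an
  approximation.
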