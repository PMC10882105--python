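# Methods

This note records the models `cdaction` implements, the numerical choices
behind the implementation, what the synthetic-data generators do and do
not emulate, and the package's known limitations.

## Model and assumptions

Correlated drug action is an *independent joint action* model: neither
drug changes what the other would have done to a given patient or cell;
the unit simply benefits from whichever drug serves it best.  The
temporal model assigns each patient latent survival times `t_A, t_B`
under either monotherapy and sets the combination outcome to
`t_AB = max(t_A, t_B)`; the dose-space model assigns each cell latent
lethal doses `δ_A, δ_B` and declares the cell dead when either applied
(and, for positive correlation, *enhanced*) dose exceeds its lethal dose.
The single parameter is the Spearman correlation `ρ` of the latent pair
across the population, capturing confounders (tumor aggressiveness,
cell size, mitochondrial content) that make one unit respond well or
poorly to both drugs at once.

Key assumptions, in decreasing order of strength:

1. **Interpolation form.** Between the exactly solvable cases
   `ρ ∈ {−1, 0, 1}` the combination curve is a mixture weighted by
   `α(ρ) = |ρ|`.  This weight is exact for the mixture joint distribution
   in which a fraction `|ρ|` of units lies on the matched-quantile curve
   and the rest pair independently; for other joint distributions with
   the same Spearman correlation it is an approximation.  The window-swap
   simulator exists precisely to probe this: it produces a qualitatively
   different joint distribution, and the fitted `ρ` still tracks the
   target (R² ≈ 0.99 in the recovery experiment), though with a slope
   slightly below one at large |ρ| — the approximation is weakest near
   the endpoints.
2. **No direct interaction.** Any real pharmacokinetic or mechanistic
   interaction shows up as lack of fit (and, in dose space, as non-zero
   EOCDA), not as a model term.
3. **Static correlation.** `ρ` does not vary with time or dose.

## Fitting, with parameters that matter

**Temporal (`fit_tcda`).** Arms are linearly regridded to a common time
step `dt` (default 0.05 months) and truncated to their shared support, so
a trial that stopped reporting early cannot bias the tail.  `ρ` is chosen
from `grid_size` (default 200) equally spaced candidates on [−1, 1] by
minimizing the RMSE between predicted and observed combination curves;
RMSE ties break toward the smallest `|ρ|` (prefer the less structured
explanation), then toward the smaller candidate, which makes the argmin
deterministic.  The default grid spacing (≈0.01) is far below every other
uncertainty in the problem.

**Bootstrap (`bootstrap_rho_ci`).** Survival times are resampled from
each arm's curve by the step-inverse of `1 − S(t)` at that arm's trial
cohort size (`n_patients`), the empirical curves rebuilt on the same
grid, and `ρ` refitted; the 2.5/97.5 percentiles over `n_boot` (default
5000) replicates form the 95% interval.  Resampling at the true cohort
size is what keeps the replicate-to-replicate scatter commensurate with
the original trial's sampling noise.  Inverse-transform levels beyond the
observed event fraction map to the last grid time: the curve is treated
as right-censored at truncation, and the empirical-curve builder counts
samples at the truncation time as still alive there, so the convention
is self-consistent on both sides.

**Goodness of fit (temporal).** The predicted and observed curves are
each represented by `n_AB` deterministic quantile samples (levels
`(i − 0.5)/n_AB` through the step-inverse) and compared by a two-sample
Kolmogorov–Smirnov test with the asymptotic p-value (cohort sizes make
the exact method intractable, and ties rule it out anyway).  The
deterministic construction makes the p-value a pure function of its
inputs — rerunning a report never changes it.  When a batch tests `m`
combinations, the family-wise threshold is `α/m` (single corrected
threshold; default family `α` 0.05).

**Dose-space (`fit_dcda_pipeline`).** Hill curves are fitted to the two
monotherapy vectors; the correlation is grid-searched exactly as in the
temporal case with RMSE taken over all matrix cells; outliers are then
flagged by externally studentized residuals from the regression of
observed on predicted (t cutoff at `1 − 0.05/(2n)` with `n − 3` degrees
of freedom, a two-sided Bonferroni criterion), and `ρ` refitted without
them.  Goodness of fit and excess-over-Bliss validity are two-sided
paired t-tests on (predicted − observed), against the fitted model and
against the `ρ = 0` (Bliss) prediction respectively; EOB validity uses
the fixed 0.01 threshold, as does the local analysis below.

**Hill fitting (`fit_hill`).** The starting estimate follows a simple
recipe: interpolate the experimental viabilities onto a dense dose grid
(200 points), rescale to 0–100, regress on dose, and read the EC50 off
the line's 50% crossing, `k = (50 − intercept)/slope`; then scan the
steepness grid `n ∈ [0.05, 10]` (step 0.01) for the RMSE minimizer at the
experimental doses.  This recipe alone is not accurate enough to support
correlation estimation: on log-spaced dose designs the line crossing
over- or under-shoots the EC50 by 10–20%, and we measured that a 1% EC50
error already moves the fitted `ρ` by about 0.02.  `fit_hill` therefore
polishes both parameters by bounded nonlinear least squares from that
starting point (default `refine=True`; `refine=False` reproduces the
plain recipe).  Monotherapy values above 1 (normalization noise) are
kept as-is; the Hill form itself never predicts above 1.

**Local synergy flags (`local_dcda_flags`).** Applied when the global
fit is adequate: residuals over non-outlier cells are summarized by a
normal MLE `(μ̂, σ̂)`; each cell is held out, `ρ` refitted without it, the
cell re-predicted, and its residual converted to `z = (μ̂ − r_i)/σ̂` with
a two-sided normal p-value.  Cells at `p ≤ 0.01` are labeled non-CDA,
with the EOCDA sign deciding synergistic vs antagonistic.  `σ̂ = 0`
(numerically exact fits) means every cell is consistent.  Because the
candidate-grid predictions are precomputed once, the leave-one-out loop
costs almost nothing.

## Pairing simulators

Both start from the two sorted time vectors (the `ρ = 1` configuration)
and never change either marginal.

* **Coin (mixture) construction.** Each index independently *stays*
  rank-matched with probability `|ρ|`; the remaining indices have their
  `t_B` values permuted uniformly among themselves en bloc; for negative
  targets the result is reversed.  The expected Spearman correlation of
  the mixture equals `ρ` exactly, so no iteration is needed.  Permuting
  the marked subset en bloc (rather than pairwise swaps, which displace
  their swap partners) is what realizes the mixture distribution exactly.
* **Window swap.** Each pass visits every index and swaps `t_B[i]` with a
  random position in the clamped window `[i − w, i + w]`.  After a pass,
  if the achieved correlation is still above target the pass is kept and
  `w` grows (doubling by default; a ±1 stepping variant is available);
  if it overshoots below target the pass is discarded and `w` shrinks.
  Convergence is `|achieved − |ρ|| ≤ tol` (default 1%); non-convergence
  within `max_iter` passes raises an error carrying the best value
  reached.  The initial window is `N/10`.

Achieved-correlation calibration of the coin method (iterating until the
realized Spearman matches the target within tolerance) is deliberately
not performed: the coin draw is the model's assumed distribution, and
recalibrating it would change the sampling distribution the bootstrap
relies on.

## Synthetic data: what it emulates, what it does not

The generators exist so every fitting and testing path can be exercised
with known ground truth and no external data.

* **Lethal-dose pairs** are drawn from the mixture: marginals are the
  Hill-implied lethal-dose distributions, sampled in closed form
  (`δ = k (u/(1−u))^{1/n}`); a fraction `|ρ|` of cells sits exactly on
  the matched-quantile curve `V_A(δ_A) = V_B(δ_B)` (anti-matched for
  negative `ρ`).
* **Combination matrices** count surviving cells per dose pair, applying
  the enhanced doses `D_A + g(D_B)`, `D_B + f(D_A)` to the correlated
  component only — mirroring how the closed form weights its branches,
  and one admissible choice given that the dose-enhancement functions
  are only pinned down at `ρ ∈ {−1, 0, 1}`.  The counting estimate
  therefore converges to the closed form, which the test suite verifies
  directly.
* **Noise** is Gaussian per replicate (`noise_sd`, default 0), with each
  reported well the average of 3 combination or 2 monotherapy
  replicates, matching a typical viability-assay protocol; reported
  values are clipped to the plate-reader range [0, 1.5].  Default dose
  grids are 10 log-spaced doses spanning 0.25–4× each drug's EC50
  (viability ≈ 0.89 down to ≈ 0.1), the design of the denser time-course
  screens this models; a 6×6 screen with monotherapies approximated from
  the lowest-dose slices can be produced by passing explicit grids.
* **Trial sets** sample latent times from Hill-shaped survival curves
  over a 0–36-month grid (0.05-month steps), truncating at the grid end
  (≈5% censoring at the defaults), pair them with either simulator, and
  return all three arms as *empirical* curves from the same draws, so a
  synthetic trial carries internally consistent sampling noise.

What the generators do **not** emulate: digitization error of scraped
survival plots beyond simple monotonicity jitter, patient censoring
before the truncation time, covariate or biomarker structure,
dose-dependent or time-varying correlation, and systematic plate effects
(edge effects, drift).  Passing tests on synthetic data therefore shows
the estimators are correct *under the model's own assumptions and
realistic noise*, not that real screens are free of those artifacts.

## Numerical conventions and degenerate inputs

* Digitized survival input may rise by at most 0.02 above its running
  minimum (digitizer jitter); such excursions are monotonized by running
  minimum, larger ones are rejected.  Duplicate times collapse to their
  minimum survival.  Percent scale is auto-detected (max > 1.5).
* Survival values are percent or fraction on input, always fractions
  internally; matrices may contain values in [0, 1.5].
* RMSE is unweighted over the common truncated grid (temporal) or over
  non-excluded cells (dose-space).
* Grid-search ties: smallest `|ρ|`, then the smaller candidate.  Note the
  200-point grid does not contain 0; an exactly-Bliss input fits to
  `ρ = ±0.005`.
* Zero-variance paired t-tests: all-zero differences give p = 1
  (perfect fit); constant non-zero differences are rejected as
  degenerate rather than reported as p = 0.
* Perfect regression fits short-circuit outlier flagging (studentized
  residuals would be 0/0).
* A flat survival curve at 1.0 cannot be sampled (no events) and is
  rejected; a dose-response that never crosses 50% viability or is
  non-decreasing fails the Hill fit with a specific error.

## Design choices that were genuinely open

* **Coin-method orientation.** Reading the coin flip as "swap with
  probability `α`" contradicts the mixture theory it implements (at
  `α = 1` it would randomize a perfectly correlated pair); the kept
  fraction must be `|ρ|`.  Implemented as keep-with-probability-`|ρ|`.
* **Goodness-of-fit operands (temporal).** A KS test needs samples; the
  deterministic-quantile construction at the combination cohort size was
  chosen over random resampling to make reports reproducible without a
  seed.
* **Outlier cutoff.** The two-sided Bonferroni criterion
  `t(1 − 0.05/(2n), n − 3)` is the standard externally-studentized
  outlier rule for a one-covariate regression and yields sub-one outlier
  counts per matrix at realistic noise.
* **Multiple-testing correction.** A single corrected threshold `α/m`
  across a batch (Bonferroni-style), rather than a step-up procedure.
* **EC50 window.** The dense interpolation for the line fit spans the
  full experimental dose range; restricting it to a band around 50%
  viability was tried and is more accurate on clean data but unstable
  under noise, and the nonlinear polish supersedes both.
* **Multi-drug arms.** A published arm that itself combines several
  drugs is treated as one pseudo-monotherapy; no recursive composition.

## Problem sizes used in validation

The recovery experiments use 4000 patients per simulated arm over a
7-point correlation sweep (temporal) and 10×10 matrices with 10⁴ cells
per well at per-replicate noise 0.02 (dose-space, median over 5 screens);
simulator-versus-formula checks use 10⁴ patients and 10⁵ cells.  These
sizes put sampling error well below the tolerances being checked while
keeping the full suite fast.

## Known limitations

* The fitted `ρ` is identified only through the model; when the fit is
  poor its value has no interpretation, and even for good fits it is a
  population summary, not evidence about mechanism.
* Near `|ρ| = 1` the interpolation is least reliable and the window-swap
  recovery slope drops below one; confidence intervals from the
  bootstrap inherit whatever bias the point estimator has.
* The dose-space model requires the full matrix to estimate `ρ`
  (unlike per-cell excess-over-Bliss) and assumes Hill-shaped
  monotherapies; strongly non-Hill dose responses (biphasic, partial
  efficacy plateaus above zero) violate its premises.
* Correlation estimates are sensitive to monotherapy calibration: a 1%
  EC50 error moves `ρ̂` by ≈0.02, so noisy or sparse monotherapy data is
  the dominant error source in practice.
* The temporal bootstrap treats the digitized curve as the truth being
  resampled; digitization bias common to all arms is invisible to it.
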