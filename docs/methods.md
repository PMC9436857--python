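# Methods

This note documents the models, numerical choices and simulation
conditions behind `bisectlab`, in the spirit of a statistical package's
methods appendix.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Observer model and psychometric fitting

The observer is a two-parameter logistic,
`psi(x; alpha, beta) = 1/(1 + exp(-beta (x - alpha)))`, with guess and
lapse rates fixed at 0 in fitting.  Per-level response counts are
treated as independent binomials (product-binomial likelihood; the
binomial coefficients are omitted from the reported log-likelihood as
they cancel in every deviance).  Derived indices: BP = alpha,
DL = ln(3)/beta (half the distance between the 75 % and 25 % points),
WF = DL/BP.  WF is undefined for alpha <= 0 and raises.

**Optimizer.** A vectorized multi-start grid — 11 alphas spanning the
level range x 15 log-spaced betas whose difference limens span 5x the
level range down to range/200 — seeds a Nelder–Mead refinement on
(alpha, log beta) with a 1e-8 log-likelihood tolerance.  The slope is
bounded in [1e-5, 1e3] per stimulus unit; an estimate pinned at a bound,
data with all per-level proportions identical (unidentifiable), or
perfectly separable step data (every proportion 0 or 1, so the slope MLE
is +inf) are reported with `converged = False`, and exclusion is the
caller's decision.  This derivative-free construction is reproducible
and robust to the plateaus a 6-point binomial likelihood can have.

**Batch refits.** Deviance bootstraps and population-scale cohorts need
tens of thousands of refits, for which the same likelihood is maximized
by a vectorized Newton (IRLS) iteration on the logistic-regression
parameterization `eta = b0 + b1 x` (alpha = -b0/b1, beta = b1), with
weighted-least-squares initialization on continuity-corrected empirical
logits and step-halving.  Newton converges quadratically at interior
optima, so both routes agree to well below the reporting precision; this
equivalence is asserted in the test suite.  Rare batch failures fall
back to the grid + Nelder–Mead path.

**Goodness of fit (pDev).** `n_sim` datasets (default 1,000) are
simulated from the fitted function at the observed per-level counts,
refitted, and pDev is the proportion of simulated deviances >= the
observed deviance (ties count as extreme — conservative).  The saturated
log-likelihood uses observed proportions with 0*log 0 = 0.  Simulations
whose refit fails are dropped from the proportion, with a warning above
5 %.  Under the true model the pDev < .05 exclusion rate is calibrated
(checked at 5 % ± 2 % over 500 replicates); under a 20 %-lapse observer
fitted lapse-free the exclusion rate is elevated but modest (~10 % at
design-scale counts) because the lapse-free logistic absorbs most of the
distortion by flattening its slope — the test suite validates the
simulated rate against an independent noncentral-chi-square oracle for
the projected misfit rather than assuming the check has high power.

## Eyeblink rate

A blink is a maximal run of >= 3 consecutive missing samples at 500 Hz
(6 ms); runs of 1–2 samples are tracker noise and ignored; runs touching
the recording boundaries count if long enough.  No merging of
near-adjacent runs is applied — only the run-length rule is specified by
the protocol, so runs separated by even one detected sample are distinct
blinks.  EBR = blinks/min over minutes 3–8 of an 8-minute recording
(first 3 minutes discarded for light adaptation).  Window membership is
by blink *onset*: unambiguous and order-preserving; the protocol is
silent on boundary-straddling blinks, so this is a package decision.
Recordings shorter than the window are processed with a warning and a
pro-rated window; participants without a recording are carried with
missing EBR and excluded only from correlational analyses.

## Synthetic cohorts

The generator reproduces the statistical structure the analysis assumes;
its defaults are the study conditions, not tuning knobs.

* **Designs.** Temporal: levels 300, 433, 567, 700, 833, 967 ms
  (anchors 300/967).  Color: 22, 34, 45, 55, 66, 78 % blue (anchors
  22/78).  Three blocks of 76 trials: 2 reminders per anchor at block
  start, then 16 repetitions of each of the four middle levels and 4 of
  each anchor, shuffled.  Training: 20 anchor trials, extended one trial
  at a time until the last 20 reach 80 % accuracy or a 6-minute cap
  (~4 s/trial nominal, i.e. 90 trials) is hit.
* **Responses.** One Bernoulli draw per trial with
  `P(positive) = (1 - 2 lapse) psi + lapse` (lapse defaults to 0 and is
  only raised in robustness simulations).  The positive label is
  "long"/"red" and follows the upper anchor as a coding convention; the
  analysis never depends on the label direction.  Response times are
  shifted-lognormal plumbing (0.25 s shift, log-mean −0.7, log-sd 0.4)
  for format completeness only.
* **Population.** BP alpha ~ Normal(633, 60) ms truncated to the level
  range; true WF ~ LogNormal(median 0.15, log-sd 0.35); slope derived as
  beta = ln(3)/(alpha * wf); EBR ~ Gamma(mean 15, sd 8) blinks/min.
  These resemble typical bisection and eyeblink literature values and
  are configurable.  Color-task parameters: alpha ~ Normal(50, 5) % blue
  truncated to [22, 78], WF lognormal as above, independent of EBR.
* **Coupling.** EBR and *true* temporal WF share a Gaussian copula with
  latent Pearson `r = 2 sin(pi rho_s / 6)` (the inverse of the
  Spearman–Pearson relation for bivariate normals), giving the target
  population Spearman rho exactly in distribution; coupling to the true
  WF rather than the fitted one makes estimation attenuation itself
  measurable.  Targets of |rho| = 1 yield exactly comonotone ranks.
* **Pupil streams.** Candidate blink onsets form a Poisson process at
  the participant's true EBR; candidates within a refractory period
  (default 100 ms, plus one detected sample) of the previous offset are
  thinned.  Durations are uniform on 100–300 ms (>= 3 samples enforced;
  a requested minimum below 6 ms at 500 Hz is rejected as undetectable).
  The dead time makes the realized rate a few percent below nominal
  (renewal rate = lambda/(1 + lambda * dead)); the mapping is monotone,
  so rank-based coupling is preserved.  Ground truth is returned with
  every stream and detection recovers it exactly by construction.

What the generator does **not** emulate: gaze position, pupil diameter,
calibration drift, sequential trial-order effects, learning or fatigue,
and any dependence of blink timing on task events.  Passing tests
therefore validate the statistical machinery, not eye-tracker artifact
handling on real recordings.

## Correlational inference

Spearman rho is computed as the Pearson correlation of average ranks,
using exact integer-valued rank sums so monotone data give exactly ±1;
two-tailed p-values use `t = rho sqrt((n-2)/(1-rho^2))` on n−2 df
(asymptotic-t, the robust-correlation toolbox convention; bootstrap CIs
are reported alongside, not used for p).

**BCa intervals** resample pairs with replacement (default 10,000), take
the bias correction z0 from the proportion of bootstrap replicates below
the point estimate (clipped away from 0/1 by half a replicate), the
acceleration from jackknife skewness, and adjust the percentile
endpoints.  A degenerate bootstrap distribution returns a point-mass
interval with a warning.  Coverage is validated at rho = .3, n = 69
(target band [.92, .97]).

**Bivariate outliers** (reported pre and post removal): both variables
are centered on medians and scaled by normalized MADs (IQR/1.349
fallback at zero MAD), and the 1.5-IQR boxplot rule is applied to the
two orthogonal diagonal projections of the standardized cloud — the
principal axes of an elliptical scatter.  A point flagged on either
projection is an outlier; >25 % flagged triggers a misuse warning.  The
rule is deliberately simple and swappable.

**Partial / semi-partial rank correlations** apply the standard
first-order formulas to the rank correlations; the semi-partial removes
the control only from the designated variable and p-values use n−3 df.
The pipeline's "controlling for the other task" rows use the
semi-partial construction for both WFs and BPs.

**Dependent-correlation comparison.** The difference
`rho(x, y_a) − rho(x, y_b)` gets a percentile bootstrap CI with
participants resampled jointly (significance = CI excludes 0), plus the
Fisher-z difference.  The accompanying t and d_z summarize the jackknife
pseudo-value distribution of the difference with df = n − 3 and
d_z = t/sqrt(df); no standard formula exists for this quantity, so the
output tags it as a reconstruction.

**Paired t-test** on task WFs uses all participants with converged fits
in both tasks (no pDev or EBR requirement — the comparison concerns task
difficulty, not the correlational sample), with d_z = t/sqrt(n).

**Exact power / sample size.** The sampling density of the correlation
under bivariate normality is evaluated in log space via Hotelling's
hypergeometric form; power integrates it over the rejection region whose
critical value comes from the exact null (t-transform), and the required
n is the smallest integer reaching the target.  For r = .33, alpha =
.05 two-tailed, power .80 this gives 69 (the Fisher-z approximation
gives 70; agreement within ±2 is asserted).

## Bayes factors

Correlation BFs integrate the exact sampling density of r against a
stretched symmetric Beta(1/kappa, 1/kappa) prior on (−1, 1) (kappa = 1 =
uniform, the default); one-sided factors renormalize over a half-line,
so BF10 = (BF+0 + BF−0)/2 holds by construction.  Quadrature is
adaptive with a 1e-9 relative tolerance and the Gauss-2F1 factor
switches to arbitrary precision (mpmath) above n = 100.  |r| = 1 returns
unbounded evidence on the matching side.  Rank-based BFs evaluate the
same integral at the Spearman coefficient ("parametric yoking") and are
tagged `rank-based`; this approximates latent-normal Gibbs approaches
well at moderate rho but is not identical to any particular sampler, so
reproductions of published rank-BF values are band targets, not
equalities.

t-test BFs are JZS defaults: Cauchy(0, sqrt(2)/2) prior on the
standardized effect, marginal likelihood integrated over the noncentral-t
density.  The noncentral-t log-pdf uses scipy up to df = 500 and a
signed log-sum-exp series above (scipy's boost backend overflows at
population-scale df); each half-line is split at the likelihood peak
delta ≈ t/sqrt(n) so adaptive quadrature cannot step over it.

Sensitivity curves evaluate the relevant BF over a width grid and flag
when the evidence category (>3 / <1/3 / between) changes across the
grid.

## Pipeline

`run_study` derives per-stage seeds (population, trials, streams, pDev,
bootstrap) from one master seed via `SeedSequence.spawn` in fixed order,
so stages are independently reproducible and reports are byte-identical
across reruns.  Analysis Ns are complete-case per variable set:
task-wise N = cohort − missing EBR − that task's pDev/convergence
exclusions; cross-task rows use the intersection.  EBR terciles are
formed after exclusions, sorted by (EBR, participant id) so boundary
ties break deterministically, and summarized as mean positive-response
proportion per level.  Winsorization is treated as a plotting-only
device and never applied to inference.

## Problem sizes in the validation suite

The statistical property checks run at deliberately chosen scales:
parameter recovery over 200 observers at design-scale counts; pDev null
calibration over 500 replicates with n_sim = 200; BCa coverage over
1,000 replicates with 2,000 resamples; Spearman type-I error over 5,000
replicates; copula recovery at n = 10,000; blink detection against a
brute-force scanner on 1,000 random streams; and one end-to-end study at
n = 2,000 participants (bootstrap 200, n_sim = 100) checking that the
estimated EBR x temporal-WF correlation matches the attenuation-adjusted
truth within .05 while the control task stays at zero.

## Known limitations

* The lapse-free logistic is the only fitted family; free lapse/guess
  rates exist solely as simulation misspecifications.
* Rank-based BFs are yoked approximations (see above).
* The outlier rule is a single fixed choice among many robust variants.
* The exact-power search is for the Pearson correlation under bivariate
  normality; it is used as the planning convention for rank correlations
  as well, as is standard practice.
* Blink detection assumes a clean binary pupil-detected flag; no
  artifact reconstruction (half-blinks, partial occlusions) is
  attempted.
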