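# Methods

This note documents the statistical procedures implemented in `extcox`, the
default parameters and the reasoning behind the open design choices.

## Cohort model and the synthetic generator

The unit of analysis is a breast-cancer surgical cohort: one row per
patient with histological grade (I-III), histological type, TNM/T/N stages,
lymphovascular invasion, p53 status, the percentage markers Ki67, ER and PR
(1-100, ER >= 1% by the ER/PR-positive cohort definition), age at surgery,
follow-up in weeks and a breast-cancer-specific-mortality (BCSM) event
flag. Complete cases only; there is no missing-data handling.

`make_fixture()` returns a deterministic 335-patient cohort whose
univariate marginals — overall and within the censored (n=307) and died
(n=28) groups — equal the published characteristics of the motivating
cohort exactly. Covariates are coupled by independent seeded permutation
within each vital-status group: the joint distribution is a convention, not
a reconstruction, and nothing downstream should be read as evidence about
the real joint structure. The age multiset is constructed so that
data-driven partition enumeration reproduces the canonical 40 age cutoffs
{37, ..., 75, 77}. Death times are fixed values up to 341 weeks; censored
times comprise 24 early "lost to follow-up" patients and administrative
censoring at 352-402 weeks, which puts the fixture's Kaplan-Meier survival
at 341 weeks near 91.3%.

`generate_cohort(SimulationConfig(...))` simulates cohorts under a
change-point proportional-hazards truth. Covariates are sampled
independently from the fixture marginals (integer ages; percentages on the
observed grids, so partition enumeration behaves realistically); an
optional exchangeable Gaussian copula correlates the four continuous
factors for stress tests. Event times are drawn by inversion from a
piecewise-constant baseline hazard (default: a single rate of 4.4e-5 per
week with a breakpoint placed at the 164-week threshold) multiplied by
`exp(A)` before the threshold and `exp(A + 1.594 * x8)` after it, where the
default coefficients of `A` are the published extended-model values
(grade 1.329 per step, N 0.972 per step, Ki67>=60% 1.650, PR>=20% -1.802,
age>=55 1.378, age>=41 -1.563) and `x8` indicates age >= 41 & PR >= 20%.
Censoring is the minimum of a uniform administrative horizon on 350-402
weeks (a one-year accrual window against a fixed study end) and an
exponential loss-to-follow-up time at rate 2e-4/week (~7% lost). The
default baseline rate was calibrated once by Monte Carlo so that the
default conditions give ~8% cumulative BCSM by 341 weeks and a censoring
fraction near 91.6%; it is configurable.

What passing tests on these cohorts do *not* show: robustness to covariate
dependence (real grade/N/Ki67 are correlated), to informative censoring, or
to non-proportional hazards beyond the single modeled change point.

## Design expansion

Continuous factors are dichotomized at every admissible partition point:
each distinct observed value `c` with at least `min_group_size = 10`
patients on both sides of the `>= c` split. Indicators are closed on the
right (`1{value >= c}`). Two partition modes exist: `"auto"` (data-driven
enumeration) and `"reference"`, the canonical printed grids (14 Ki67, 15
ER, 15 PR, 40 age cutoffs) used for replication; the reference grids are
treated as fixed inputs because they cannot be re-derived without the
original data, and one of them (Ki67 at 1%) predates the minimum-size rule
— the penalized fitter screens such degenerate columns instead.

Categorical factors enter as single integer-scored columns (grade 0-2,
N 0-3, T 0-3, TNM 0-2, binary LVI/p53, histotype as a category code),
because the downstream models use one coefficient per ordinal factor
(the published grade-III hazard ratio equals `exp(2 * beta_grade)`); this
is also what makes the candidate count come out at 7 + 4 + 84 = 95.
Interaction families add the T x N ordinal product and, for ER x PR,
age x ER and age x PR, all pairwise products of {raw column, every cutoff
indicator} from the two parents — (15+1)(15+1) = 256 and 2 x (40+1)(15+1)
= 1312 columns, totalling 1664. Column metadata records the source
factor(s) and cutoff(s) so every column can be rebuilt from the cohort
exactly.

## SCAD-penalized Cox fitting

The penalty is the smoothly clipped absolute deviation with shape
`a = 3.7`: linear `lam*|b|` up to `lam`, quadratically clipped on
`(lam, a*lam]`, constant `lam^2 (a+1)/2` beyond. Optimization is by local
linear approximation (LLA): the penalty is majorized at the current
coefficients by a weighted L1 penalty with weights `p'_lam(|b_j|)`, and
each weighted-lasso Cox subproblem is solved glmnet-style — iteratively
reweighted least squares on the Breslow partial likelihood's diagonal
Hessian, with cyclic coordinate descent and an active-set strategy inside.
Columns are standardized to unit variance internally (binary columns
included) and coefficients reported on the original scale; thresholded
coordinates are exact zeros. At `lam = 0` the subproblem is the plain
partial-likelihood maximization and is solved directly by Newton-Raphson.

The penalty level is chosen by BIC, `-2 logPL + k log(#events)`, over a
50-point log-spaced grid descending three decades from the smallest
`lam` that zeroes all coefficients (the tuning rule of the original
analysis is unstated; BIC is the standard consistent choice for
folded-concave paths). The path stops early once the active set reaches
the event count — denser fits are unidentifiable and cannot win the BIC
comparison. Per-`lam` LLA traces are recorded and the penalized objective
is required to be non-increasing; a `lam` that violates this is flagged
and excluded from selection. Binary columns with fewer than 10 ones or
zeros never enter (group-size guard). No hierarchy constraint ties raw
columns to their indicators; the penalty decides.

Ties: Breslow throughout the penalized path (week-scale times tie
heavily); the unpenalized Newton fitter used for refits and the extended
model also implements the Efron correction (`ties="efron"`), verified
against lifelines.

## Change-point (extended) Cox model

Follow-up is split at a threshold `tau` into counting-process episodes
`(0, tau]` and `(tau, t]`; the interaction column is zero in pre-threshold
episodes and equals the patient's age>=41 & PR>=20% indicator afterwards,
so a standard episode-table Cox fit maximizes the two-regime partial
likelihood. The boundary convention puts `t = tau` itself in the first
regime. `tau` is selected by the smallest AIC over candidates drawn from
the distinct observed times (deaths and censorings) that leave at least
one event and ten subjects on each side; because the partial likelihood
only changes when `tau` crosses an event time, the AIC profile is a step
function and the grid may be thinned (`max_candidates`) without losing
structure. AIC counts the interaction coefficient but not `tau` itself —
the comparison is between fixed-threshold fits — a deliberately
anti-conservative convention; the null-case behavior is therefore tested
at a fixed threshold. Ties in the profile break to the smallest `tau`.

Survival prediction integrates the Breslow baseline piecewise:
`H(t|x) = H0(min(t,tau)) e^A + (H0(t) - H0(tau))_+ e^(A + beta8 x8)`,
continuous in `t` at the threshold; horizons beyond the observed follow-up
raise rather than extrapolate.

## Evaluation

Kaplan-Meier curves carry Greenwood variances with log-scale 95% bands.
Time-dependent discrimination uses the cumulative-case / dynamic-control
ROC at fixed horizons (default 52/156/260 weeks — the week equivalents of
1/3/5 years) with inverse-probability-of-censoring Kaplan-Meier weights;
with no censoring this reduces exactly to the concordance-pair AUC of the
binary outcome "event by the horizon". Optional CIs come from a seeded
patient bootstrap. The marker is the model-predicted event probability by
the horizon, which correctly incorporates the post-threshold regime for
the 5-year horizon.

Calibration: patients are ranked by predicted event probability and split
into 10 near-equal groups; expected deaths are within-group sums of the
predictions, observed deaths default to `n_g (1 - KM_g(horizon))` (robust
to censoring; a raw-count option exists). The statistic is
`sum (O-E)^2 / E` with df = groups - 1 (a variance-standardized variant is
available); zero-expectation groups are merged with a warning and df
reduced. The df convention is fixed by the requirement that a statistic of
7.37 on 10 groups corresponds to an upper-tail probability of ~0.6.

## Nomogram

Per standard construction, each predictor row's reference level is the one
minimizing its coefficient contribution (points are nonnegative) and the
row with the largest contribution range spans 0-100 points; with the
published coefficients that row is N stage (range 3 x 0.972). The default
build has eleven rows: points, six predictor rows (grade, N, Ki67 status,
PR status, age group, age-PR interaction), total points, and three
survival rows. Points are rounded to 0.1; survival tables are tabulated on
a 200-step total-points grid. Because the interaction acts only after the
threshold, post-threshold survival tables are stored per interaction
status and `score_patient` selects the branch from the patient's
covariates — a folded single-table lookup cannot represent the two-regime
hazard exactly. The round trip against direct model prediction is within
0.005 survival probability.

## Simulation studies (test conditions)

Problem sizes were chosen to exercise each property at meaningful power on
a single CPU:

* selection consistency: n = 2000, truth {grade, N, Ki67>=60, PR>=20,
  age>=55} among the 95 reference candidates, baseline 4e-4/week (~50%
  events — a realistic yield for a long-follow-up registry; the default
  ~8% censored-heavy conditions leave too few events for exact-set
  recovery at this n), 20 seeded replicates, >= 80% exact recovery;
* threshold recovery: n = 5000 under the full default coefficients at the
  same elevated baseline, 21-candidate grids, recovery within one grid
  step of 164 weeks in >= 80% of 20 replicates;
* coefficient recovery: n = 5000 at the *default* conditions, point
  estimates pooled over three replicates, each within 2 single-fit SE;
* calibration: level (scores from the generating model accepted) and power
  (doubled coefficients rejected) in >= 18/20 replicates at n = 5000.

## Known limitations

* The synthetic covariate space is an independent coupling of marginals;
  interactions estimated on it are exactly those built into the hazard.
* A single change point with one switchable coefficient; no confidence
  interval for `tau`; no competing risks, delayed entry or time-varying
  covariates beyond the threshold split.
* SCAD tuning by BIC is one defensible rule among several; fitted
  coefficient values on any real cohort will depend on it.
* The GOF statistic uses the simple `(O-E)^2/E` form by default; both it
  and the standardized form are approximations under censoring.
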