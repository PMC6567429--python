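# Methods

This note records the statistical conventions, the synthetic-data model
and the design choices behind the package. It documents what the code
computes; every number quoted here is produced by the test suite or the
analysis scripts at run time.

## Population and data model

The unit of analysis is one survey respondent aged 45+, with two binary
utilization outcomes (outpatient visit in the last month, inpatient
visit in the last year), need covariates (gender, 60+ age band,
self-assessed health on a 1–5 scale, chronic morbidity), socioeconomic
covariates (marital status, four-level education, per-capita household
income, three-region indicator, town-center community indicator), an
insurance scheme (URRBMI or NCMS) and a positive sampling weight.
Inclusion is complete-case: any missing analysis variable, negative
income, or a scheme outside the two target schemes excludes the row,
and every exclusion is counted by reason. No imputation is attempted.
Zero income is allowed (the published quintile note places the lowest
bound at 0).

Dummy coding uses fixed reference categories: female, age 45–59,
self-assessed health "poor", no chronic disease,
single/divorced/widowed, illiterate, lowest income quintile, east
region, rural community. Income enters the regression only as four
quintile dummies; the *continuous* income is used for ranking. The
fixed quintile cutpoints are the published bounds 17 / 495 / 2587 /
9992 yuan with the lowest interval closed on both ends and the others
left-open/right-closed (read literally from the published table note);
a weighted-quantile mode recomputes the 20/40/60/80th weighted
percentiles and applies the same interval logic.

## Fractional rank

Ranks are midpoint cumulative weighted population shares: sorting by
income ascending, `r_i = (W_below + w_tie/2) / W_total`, with tied
incomes sharing the midpoint of their combined weight. This is the
standard convention in the inequality literature; it guarantees
`mean_w(r) = 1/2` exactly, reduces to `(2i-1)/(2n)` for equal weights
and distinct values, and is permutation-invariant up to floating-point
summation order. Weighted ranks are the pipeline default because the
survey weights every respondent by sampling probability; unweighted
ranks are available as a switch.

## Concentration index

`C = (2/mu) * cov_w(y, r)` with the *population* (divide-by-total-
weight) weighted covariance. The population form, not `n-1`, is
deliberate: the decomposition's adding-up identity only holds when the
index, the regressor indices and the means use one consistent
convention. The concentration curve is accumulated over respondents
sorted by rank, and `ci_from_curve` computes twice the area between the
curve and the diagonal by trapezoid quadrature. The two routes are
algebraically equivalent for midpoint fractional ranks — the randomized
cross-check in the tests observes gaps at machine precision, far inside
the conservative 2/n tolerance asserted — which is exactly why the
curve construction serves as an independent oracle for the covariance
implementation rather than a second production path.

No Erreygers or Wagstaff normalization is applied to `C` for binary
outcomes; the published values that this pipeline's conventions mirror
are raw covariance-form indices. `|C| <= 1` for outcomes in `[0, 1]`,
and for binary outcomes with equal weights the sharper finite-sample
bound `|C| <= 1 - mu + 1/n` is enforced in the property tests.

## Outcome model and marginal effects

Each outcome is fitted by weighted logit, maximizing the
weight-multiplied Bernoulli log-likelihood via IRLS (statsmodels GLM
with a binomial family; weights enter as variance weights, so scaling
all weights by a constant leaves the fit unchanged). Convergence
requires the deviance to stabilize within 100 iterations; any
coefficient with |b| > 15 triggers a separation error naming the
columns, since a genuinely diverging dummy coefficient means a cell
with no events (or no non-events).

Categorical levels in which *no* respondent has the event are removed
before fitting — both the level's rows and its dummy column — matching
the published handling of a best-health category with zero inpatient
events (a 3593-row group shrinks to 3555 when its 38-member zero-event
level is dropped). The drop log is carried into the report so group
sizes remain auditable. A zero-event *reference* level cannot be
repaired this way and surfaces as a separation error instead.

Marginal effects are average marginal effects over the sample
(weighted), the convention of the software family that prints "dy/dx":
discrete change `mean_w[p(x=1) - p(x=0)]` for indicator regressors,
`mean_w[p(1-p)] * b` for continuous ones. Standard errors use the delta
method with the analytic gradient, verified against a central
finite-difference oracle at step 1e-6; 95% intervals use the normal
quantile 1.959964. Whether the published regressions were weighted is
ambiguous in the source tables, so both modes exist; weighted is the
default for the regression, ranking, index and decomposition stages,
while the descriptive chi-square stage is unweighted — recomputing the
published comparison table from its printed counts reproduces all
eleven chi-square statistics to printed precision only without weights
and without continuity correction, so that is what the descriptives do.

## Decomposition and HI

With `AME_j` the average marginal effect of regressor `j`,

contribution_j = `AME_j * xbar_j / ybar * C_j`, where `C_j` is the
regressor's concentration index computed against the same rank vector
and weights as the outcome's. The residual `GC_u / ybar` is defined as
the remainder `C - sum_j contribution_j` rather than as a separate
generalized concentration index of residuals: for a nonlinear model the
AME linearization is approximate, and defining the residual as the
remainder keeps the adding-up identity exact (the tests require
`need + socioeconomic + residual = C` to 1e-10; in practice the error
is at machine epsilon). Contribution percentages are signed,
`100 * contribution / C`, so individual percentages may be negative or
exceed 100 when contributions of opposite sign cancel in `C`.

`HI = C - need_total`. The sign is reported as pro-rich (positive) or
pro-poor (negative). The index `C` of each outcome is computed on the
full retained group sample, while the decomposition necessarily runs on
the regression sample after any zero-event drop; both values appear in
the report, and the HI always refers to the decomposition sample so the
identity `HI = C - need` holds within one sample.

## Synthetic survey generator

The generator is the package's stand-in for the restricted survey
microdata; its frozen preset encodes the study conditions:

- **Group sizes** exactly 3593 (URRBMI) and 5409 (NCMS); a total-size
  override rescales both proportionally.
- **Income** is a two-part mixture: with probability 0.193 a draw from
  Uniform(0, 17) (an atom of near-zero per-capita incomes), otherwise
  LogNormal(mu=7.728, sigma=2.248). The parameters minimize the squared
  log-distance between the mixture's 20/40/60/80th percentiles and the
  published bounds 17/495/2587/9992 yuan; a single log-normal cannot
  place the 20th percentile at 17 yuan with a median near 2600. A
  seed-1 draw realizes bounds 17/508/2226/9914.
- **Covariates** have prevalences linear in the fractional income rank,
  `P(x=1|r) = a + b(r - 1/2)` (multi-level variables interpolate a
  base distribution with a zero-sum slope vector). Linearity is chosen
  so each covariate's concentration index is available in closed form
  (`C_x = b/(6a)` for a binary covariate), which the recovery tests
  exploit. Baseline prevalences match the published margins (chronic
  0.77 with a mild pro-poor gradient, 60+ 0.51, male 0.48, married 0.88
  and town-center 0.05 with pro-rich gradients, education strongly
  pro-rich, self-assessed health mildly pro-rich).
- **Outcomes** are conditionally independent Bernoulli draws from the
  logit-linear forward model over the encoded design. Coefficient signs
  follow the published marginal-effect tables (worse self-assessed
  health and chronic disease raise utilization; a positive top-quintile
  effect for outpatient, a negative one for inpatient; age raises
  inpatient use). Intercepts are calibrated once, on a 200k-respondent
  draw, to outpatient ~20% and inpatient ~13%, then frozen.
- **Weights** are constant by default (the weight distribution of the
  real survey is undocumented); a log-normal option exercises every
  weighted code path.

What the preset does *not* emulate: the real survey's multi-stage PPS
design (no strata or cluster structure, hence no design-based variance
testing), household clustering, item missingness, and any dependence
between the two outcomes beyond shared covariates. Passing recovery
tests therefore demonstrate correctness of the estimators under the
stated generating process, not robustness to the full complexity of
real survey data.

## Problem sizes and numerical choices

The simulation tests use the study size (9002) for pipeline checks,
20,000 respondents and 8–20 seeded replicates for null/recovery checks,
and 50,000 with 100 replicates for interval coverage — sizes at which
Monte-Carlo error is small relative to the effects asserted while the
whole suite stays fast. Under the null configuration (all
socioeconomic coefficients zero) the estimated HI is required to fall
within 3 Monte-Carlo standard errors of zero; with an injected
top-quintile outpatient effect (+0.5 on the logit scale) the estimated
HI must be positive in essentially every replicate and agree with the
generator's ground-truth HI (computed from the true probabilities and
true-coefficient AMEs, removing Bernoulli and estimation noise) within
Monte-Carlo error.

Percentages in descriptive tables are rendered with half-up rounding to
2 decimals via exact decimal arithmetic, matching the published table's
display convention (e.g. 734/3593 → 20.43). Report tables round
indices and contributions to 3 decimals for display only; all internal
arithmetic is double precision.

## Known limitations

- Standard errors and dominance tests for `C` and HI are out of scope
  (none are published for the quantities mirrored here); a bootstrap
  would be the natural extension.
- The decomposition inherits the AME linear approximation; its
  adequacy is checked empirically (residual small, null recovery
  unbiased) but not bounded analytically.
- Scheme comparisons are descriptive only: no propensity matching or
  causal identification is attempted.
- The published regression and decomposition tables themselves cannot
  be reproduced without the restricted microdata; the pipeline instead
  reproduces every quantity derivable from printed inputs and validates
  the estimators on the synthetic population.
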