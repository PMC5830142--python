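# Methods

## Model and estimands

The package measures income-related inequality in areal health-workforce
densities.  Units (cities) are ranked by a living-standards variable
(per-capita GDP, column `pergdp`); the health variable `h` (doctors or
nurses per 10,000 residents) has concentration index

    C = (2/μ) · cov(h, r),        μ = mean(h) > 0,

with `r` the fractional rank.  All covariances in the package are
population covariances (divide by N, not N−1).  This is not cosmetic: the
decomposition below is an exact algebraic identity only if the same
covariance convention is used for the outcome, the covariates and the
residuals.

**Rank conventions.**  The default is the midpoint rank
`r_i = (i − 1/2)/N`, which centres ranks at 1/2 and keeps `C` within
[−1, 1] for nonnegative `h`.  The alternative `paper` convention
`r_i = i/N` is retained because some applied studies use it; the two
differ by `O(1/N)` in `C`.  Ties in the ranking variable receive the mean
of the ranks they span, making results invariant to input row order.
Weighted midpoint ranks (cumulative weight to the unit's midpoint over
total weight) are available; the default treats cities as equal units.

**Curve.**  The concentration curve is the piecewise-linear interpolant
of the knots `(k/N, Σ_{i≤k} h_(i) / Σh)`.  With midpoint ranks the
covariance formula and "one minus twice the trapezoid area under the
curve" are algebraically identical (not merely asymptotically equal), so
the curve-area route is used as an independent oracle in the tests.
Curve position against the diagonal is classified at the interior knots
with tolerance 1e-9 into coincident / above (pro-poor) / below
(pro-rich) / crossing.

**Standard errors.**  The sampling variance of `C` is estimated two ways:

* `convenient_regression` (default): OLS of `(2·var(r)/μ)·h_i` on `r_i`.
  The slope equals `C` exactly (the ratio of sample to population
  moments cancels), and its HC1 heteroskedasticity-robust standard error
  is the reported SE.
* `bootstrap`: resample units with replacement, recompute ranks within
  each resample, SE = standard deviation of the draws (seeded, ≥100
  draws).

Both report `C ± 1.96·SE`.  A constant health variable returns
`C = 0, SE = 0` by convention.  Which flavour a published interval used
is often unstated; the two agree in order of magnitude and the choice is
recorded in the result object.

## Regression

`y_i = α + Σ_k β_k x_ki + u_i` is fitted by OLS (statsmodels).  Because
the model is linear in parameters, marginal effects dy/dx coincide with
the coefficients; the `marginal_effects` accessor is kept as a separate
contract so a non-linear fitter could slot in behind the same interface.
Categorical covariates enter as indicators for every non-reference level
(references: youngest age band, shortest service band, men, Han, lowest
education, East China).  Design-column order is deterministic: continuous
covariates in spec order, then each categorical's non-reference levels in
level order.

Standard errors default to HC1 (areal data are rarely homoskedastic);
classical errors are available via `cov_type="nonrobust"`.  Significance
flags use strict inequalities: `*` p<0.05, `**` p<0.01, `***` p<0.001.

Indicator columns that are constant in the data (a level no city takes)
are dropped with a warning — small tables hit this routinely — and any
remaining rank deficiency raises an error naming the collinear terms.

## Decomposition

For the OLS fit, the outcome index decomposes exactly:

    C = Σ_k (β_k x̄_k / μ) C_k + GC_u / μ,

with `C_k = 2·cov(x_k, r)/x̄_k` the covariate's own concentration index
against the *shared* rank vector and `GC_u = 2·cov(u, r)` the generalized
(mean-free) concentration index of the residuals.  Continuous covariates
and category dummies are handled by one loop over design columns — for a
dummy, `x̄_k` is the level's prevalence and `C_k` measures how the level
concentrates across the wealth ranking.  The additivity gap
`Σ contributions + residual − C` is exposed on the results object and is
at machine precision (≈1e-16) on every input; the test suite asserts
1e-10.

**Percent denominators.**  Each row's percentage contribution divides its
absolute contribution by the *outcome's own* `C`.  (A widely-cited 2014
nationwide city analysis prints a doctor percent column that is
numerically consistent with dividing by the nurse outcome's index
instead; the package treats that as an inconsistency and does not
replicate it — the acceptance tests pin both arithmetics down.)  When
`|C|` is numerically zero the percentages are undefined and reported as
NaN rather than inventing a denominator.

**Degenerate columns.**  A design column with (numerically) zero mean has
no defined `C_k`; its row is flagged, its contribution reported as zero,
and a warning notes that exact additivity is then not guaranteed.  In
practice only hand-constructed inputs reach this path: dummies are
dropped earlier if empty, and the schema forbids zero-mean continuous
covariates.

## Synthetic city tables

The generator emulates a 2014 mainland-China prefecture-level panel so
downstream estimators can be tested against a known truth:

* **Marginals** (moment-matched to the published nationwide summary
  statistics): per-capita GDP lognormal (mean 46,836.71 yuan, sd
  10,628.22 — right-skewed like real GDP data); geographical size,
  population size and fiscal revenue lognormal; population density and
  the two percentage shares truncated normal on their supports.
* **Dependence**: one latent standard normal drives the ranking; each
  continuous covariate is a Gaussian-copula transform of a latent normal
  correlated with it.  Latent correlations are pre-warped
  (`2·sin(π·ρ/6)`) so the *Spearman* correlation hits its target (±0.1
  checked at n ≥ 500).  Defaults (urbanization 0.55, revenue 0.45,
  density 0.25, population 0.10, area −0.20, health-expenditure share
  −0.25) are illustrative: real covariate–rank correlations for this
  panel are not published.
* **Categoricals** are independent of the ranking by default; the study
  scenario (`default_study_config`) adds per-level rank tilts
  (`p_l ∝ p_l·exp(δ_l z)`) so that, e.g., Southwest cities concentrate
  among the poor and post-retirement-age mayors in poorer cities — giving
  dummy `C_k` values of realistic sign and size.  Level frequencies come
  from the published official-cohort counts.
* **Outcomes**: `y = α + Σ β_k·(design column) + N(0, σ)`, floored at
  0.01 density to preserve positivity.  Default effect sizes are set once
  to the published marginal-effect magnitudes for doctor and nurse
  densities; `σ = 8` per-10k units; intercepts 32 (doctors) and 26
  (nurses) put the mean densities near their 2014 national values
  (≈21/20 per 10k).

One `numpy` generator seeded once per table makes generation a pure
function of (config, seed).

**What the generator does not emulate** — and therefore what passing
tests do *not* establish about real data: spatial autocorrelation and
province-level clustering; measurement error in yearbook figures;
covariate–covariate dependence beyond what the shared ranking latent
induces; any non-linearity in the outcome process.  The positivity floor
makes the process piecewise-linear: when a configuration pushes cities to
the floor, OLS estimates a censored mean and is mildly biased for the
generating coefficients.  The estimator-recovery tests therefore run in a
raised-intercept regime where the floor never binds; the default study
scenario clips only in the extreme lower tail.

**Ground truth** (`true_decomposition`): Monte-Carlo expectation of every
decomposition quantity over replicate tables, computed with the *true*
coefficients (contribution `β_k·GC_{x_k}/μ`, residual from the true
linear part) — deliberately independent of the OLS fitter it is used to
judge.  It reports both the between-replicate standard deviation (the
scale on which a single table scatters) and the standard error of the
Monte-Carlo mean.

## Numerical choices and problem sizes

* Population covariance everywhere; additivity asserted at 1e-10, row
  arithmetic at 1e-12, percentage identities at 1e-6.
* Zero-mean design-column threshold 1e-12; curve classification
  tolerance 1e-9; probability vectors must sum to 1 within 1e-12.
* Ties: average-rank assignment (deterministic, order-independent).
* Test problem sizes: unit tests run at n = 4–322; the simulation
  studies use n = 2000 with 200 replicates (coefficient coverage),
  n = 800 with 60 truth replicates and 40 estimate replicates
  (decomposition recovery), n = 2000–5000 one-shot checks for
  convergence properties, and 100 random tables of n = 60–260 for the
  additivity sweep.  The reproduction script runs the full pipeline at
  the study size n = 322.

## Known limitations

* No bounded-variable (Wagstaff/Erreygers) correction: outcomes are
  unbounded densities, so none is needed; applying the package to
  bounded outcomes (e.g. coverage proportions) would require one.
* No dominance testing between curves; position classification only.
* No survey weights in the regression (ranks can be weighted; the
  fitter treats units equally).
* The convenient-regression SE ignores the sampling variability of the
  ranks themselves; the bootstrap, which re-ranks every draw, is the
  more conservative choice when the two disagree materially.
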