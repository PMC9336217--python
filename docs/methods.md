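# Methods

## Model

A binary outcome for respondent i in county j follows a random-intercept
logistic model,

    Y_ij | re_j ~ Bernoulli(expit(X_i β + re_j)),    re_j ~ N(0, σ²_re).

The fixed-effects design uses reference-cell dummy coding — age group 1
(18–24), male, and non-Hispanic white are the references — giving
1 + 12 + 1 + 7 = 21 demographic columns, plus one continuous county-level
covariate (percent of adults below 150% of the poverty line, on the 0–100
scale), 22 columns in all.  An explicit intercept is used; cell-means
coding would give identical cell probabilities, so the choice is cosmetic
but fixed.  Survey design weights are *not* used in the model fit; they
feed only the direct estimator.

Post-stratification converts parameters into prevalences: for each census
cell k of county j with population N_kj,

    p_kj = expit(X_k β + re_j),
    P_county(j) = Σ_k p_kj N_kj / Σ_k N_kj,

and the state estimate is the aggregation over all counties' cells, which
equals the population-weighted mean of the county estimates.  Cells with
N_kj = 0 are dropped; cells absent from the survey but present in the
census are still predicted — that is the point of post-stratification.

## Maximum marginal likelihood with adaptive Gauss–Hermite quadrature

The marginal likelihood integrates each county's random intercept out of
a product of Bernoulli terms.  Because the random effect is scalar, the
integral is one-dimensional per county and adaptive Gauss–Hermite
quadrature is both fast and essentially exact: nodes are centred at the
conditional posterior mode of u_j (found by a globally convergent Newton
iteration — the log-integrand is strictly concave) and scaled by the
curvature there.  Fifteen nodes keep the error below 1e-6 even for
counties contributing hundreds of observations; the test suite checks
agreement with dense-grid integration to 1e-4 and with R lme4 (`glmer`,
`nAGQ = 15`) to 0.02 on the coefficients.

Optimisation alternates (a) re-adapting the quadrature grid at the
current parameters with (b) an L-BFGS-B solve of the fixed-grid surrogate
using its exact analytic gradient (gradient tolerance 1e-8, outer loop
until the parameters move < 1e-8, up to 50 outer rounds, one restart from
a perturbed start on failure).  σ²_re is optimised on the log scale with
a floor of 1e-8; an estimate at the floor is reported as a boundary fit
(σ̂² = 0) and flagged.  Likelihood evaluations aggregate respondents with
identical (county, covariate-row) into binomial rows — exact, and two to
three times faster on survey data where many respondents share a
demographic cell.

Two deliberate additions to plain maximum likelihood:

* **Weak L2 penalty.**  A ridge with prior variance 10,000 per
  coefficient (matching the Bayesian prior) is added to the objective and
  to the observed information.  It is numerically irrelevant for
  identified coefficients (shifts < 1e-4) but keeps the fit finite and
  the covariance well defined when a rare race/ethnicity level is empty
  or perfectly separated — routine in small or resampled surveys.  The
  reported log-likelihood and the `marginal_loglik` function remain
  unpenalised.
* **EBLUPs and uncertainty.**  Random-effect predictions are the
  conditional posterior modes at the fitted parameters; their prediction
  variances come from the curvature at the mode.  The fixed-effect
  covariance is the β-block of the inverse observed information of the
  marginal likelihood in (β, log σ²), obtained by central-differencing
  the analytic gradient, so σ²-uncertainty propagates into Σ̂_β.  The
  β–re cross-covariance is not produced; linear-predictor standard errors
  set that term to zero and record the fact.

## Interval constructions

All methods end in the same operator: the equal-tailed empirical interval
with order statistics ⌈0.025·B⌉ and ⌈0.975·B⌉ of the B simulated
prevalences (at B = 1000: the 25th and 975th values).  At least 40 values
are required.

**Monte Carlo parameter simulation** (default R = 1000): β* drawn from a
multivariate normal with the full estimated covariance — component-wise
independent draws would mis-state the variance of any functional of β —
and re*_j drawn independently from N(re_j, v̂_j); β* and re* mutually
independent.  Each draw is post-stratified.  No refitting, so this is by
far the cheapest model-based interval.

**Parametric bootstrap** (default B = 1000; 200 at benchmark scale): each
respondent's linear predictor is perturbed, η*_ij ~ N(η̂_ij, σ̂²_ij),
outcomes are regenerated as Bernoulli(expit(η*)), and the model is refit
and post-stratified.  η* is drawn independently per respondent; since
σ̂²_ij contains the county-level prediction variance as a shared
component, independent draws average that shared uncertainty away within
a county — the structural reason this method yields visibly narrower
county intervals than every alternative, a pattern the benchmark
reproduces (median county width ratio ≈ 0.8–0.95 vs the non-parametric
bootstrap).

**Non-parametric bootstrap**: respondents resampled with replacement
within county, preserving every county's sample size exactly, then refit
and post-stratified.  Replicates are refit one at a time rather than
pooled into one stacked dataset — equivalent, with simpler provenance.
Both bootstraps give replicate r the deterministic sub-seed
(master, r), so results are independent of execution order and any subset
is reproducible; non-converged refits are dropped and counted, and the
run aborts if more than 2% fail.  Refits warm-start at the base fit with
7 quadrature nodes and relaxed tolerances (1e-6), since replicate noise
dwarfs parameter-tolerance error; the base fit keeps 15 nodes and 1e-8.

**Hierarchical Bayes**: priors β_p ~ N(0, 10,000) iid (variance, not SD),
re_j | σ² ~ N(0, σ²), σ² ~ InverseGamma(shape 0.01, scale 0.01).
Reference schedule 100,000 iterations after 10,000 burn-in, thinned by 5
(exactly 20,000 retained draws); the desk-scale schedule used in tests is
20,000/2,000/5.  Every retained draw is post-stratified; the credible
interval is the same equal-tailed percentile operator.

The sampler is Metropolis-within-Gibbs with four move types:

1. a random-walk Metropolis update of the full β vector, preconditioned
   by a ridge-stabilised logistic-fit covariance, global scale adapted
   during burn-in toward ~30% acceptance (adaptation stops at burn-in
   end, so the retained chain is a fixed kernel);
2. vectorised per-county 1-D updates of re_j — random-walk steps scaled
   by the current σ (adapted toward ~40%), with an independence proposal
   from the prior every 10th iteration;
3. a conjugate inverse-gamma Gibbs draw of σ² | re;
4. two exact group moves for the directions the priors barely identify:
   a *translation* move that shifts the county-level fixed effects
   (intercept, poverty) against the random intercepts — the likelihood is
   invariant along that ridge and the restricted target is Gaussian, so
   the move is an exact Gibbs draw — and a *scale* move
   (u, σ²) → (cu, c²σ²) proposed from the prior-orbit Haar conditional
   (c² ~ InvGamma(0.01, 0.01/σ²)) and accepted with the likelihood ratio.
   Without these, the intercept's effective sample size collapses to ~1
   and the σ² funnel cannot be traversed.

β components whose design column is identically zero (a factor level
absent from the survey) have conditional posterior equal to the prior and
are drawn by exact Gibbs, outside the random-walk block.  σ² is confined
below 1e280: the prior is so heavy-tailed (median ≈ 1e28) that draws
otherwise overflow float64; the ceiling cuts ~0.16% of *prior* mass and
immeasurably little posterior mass.  Diagnostics: minimum effective
sample size across all parameters (via arviz); below a configurable floor
the run warns but does not abort, matching the exploratory role of the
diagnostic.  A testing switch can turn the likelihood off (the chain then
samples the prior, verified by a Kolmogorov–Smirnov test on σ²) or pin σ²
(used for the brute-force grid-posterior comparison, where a free σ² at
J = 2 would leave the intercept with posterior SD ≈ 6 and make any tight
tolerance meaningless).

**Direct estimator**: design-weighted prevalence Σ w_i y_i / Σ w_i per
area with the weighted-ratio linearization variance
Σ w_i²(y_i − p̂)² / (Σ w_i)² and a normal 95% interval truncated to
[0, 1].  County stratification/clustering beyond the county itself is not
modelled; this is a standard stand-in for published survey tables whose
exact variance method is unknown.

## Synthetic worlds

The generator emulates a single-state BRFSS-like design: by default 67
counties with a target of 500 completed interviews each; 13 × 2 × 8
demographic cells; county adult populations log-uniform on
[20,000, 800,000]; county poverty uniform on [10, 40]%.  County cell
compositions are Dirichlet-multinomial around a common base composition
(concentration 80), so counties differ realistically and small counties
naturally lack some rare cells ("m < 208"); a flag can force all 208
cells positive.  Outcome presets (copd 7.6%, binge 17.6%, arthritis
26.0%) fix plausible coefficient profiles — age-increasing for the
chronic conditions, age-decreasing and male-skewed for binge drinking —
and solve the intercept by root finding so the post-stratified population
prevalence at re = 0 equals the preset target on the realised census;
county effects (default σ_re = 0.3, a typical county-level spread on the
logit scale) then perturb it.  Respondents are sampled from each county's
cell distribution; design weights are inverse sampling fractions
N_cell / n_cell.  One master seed drives four sub-streams (population,
random effects, sampling, outcomes) so components can be varied
independently; per-county sample sizes may be a vector.

What the generator does **not** emulate: BRFSS raking/post-survey weight
calibration (weights here are pure inverse sampling fractions),
non-response and measurement error, within-county clustering beyond the
random intercept, and any real state's actual demographic composition.
Passing coverage tests therefore demonstrate that each interval method is
calibrated *when the model is correctly specified at this design*, not
that it survives the design complexities of a real survey.

## Problem sizes used by the test and acceptance suites

Chosen to exercise the documented designs at desk scale: parameter
recovery uses 50 worlds at full scale (67 × 500); interval coverage uses
100 worlds at the reduced benchmark (20 counties × 300, R = 200, 20,000
MCMC iterations), pooled over counties and worlds with an 88–99%
acceptance band around the nominal 95%; the cross-method width
comparison runs one benchmark world with B = R = 200 and 20,000 MCMC
iterations; brute-force oracles (dense-grid likelihood, grid posterior)
run on 3-county/≈20-respondent and 2-county/30-respondent instances.
`scripts/acceptance.py` re-runs the same pipeline end to end from a
single command-line seed.

## Known limitations

* Single random intercept only — no crossed or nested effects, no
  spatial (CAR) smoothing, no survey-weighted pseudo-likelihood.
* The β–re cross-covariance is unavailable, so σ̂_ij omits it (recorded
  on the linear-predictor table); the parametric bootstrap inherits this.
* MC simulation draws β* and re* independently; at the state level this
  ignores their negative posterior coupling and widens the state interval
  somewhat relative to the Bayesian posterior, while county-level widths
  remain comparable.
* The direct estimator's variance ignores any design structure beyond
  the weights.
* Timing comparisons between methods are hardware-dependent and reported
  for orientation only.
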