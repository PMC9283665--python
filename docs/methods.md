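# Methods

## The problem

In high-mortality settings, early-life adversity (infections,
undernutrition) leaves lasting deficits in the children who survive it
(*scarring*), while simultaneously removing the most vulnerable children
from the surviving population (*selective mortality*). The two forces pull
the observable outcomes of survivors in opposite directions: scarring shifts
the whole outcome distribution down, selection makes the surviving
population look healthier precisely where adversity was worst. This package
implements an analysis pipeline that (i) constructs an ecological proxy for
adversity — the postneonatal mortality rate around a child's neighborhood
during its own infancy — from pooled birth histories, and (ii) estimates
its nonlinear effect on survivors' height-for-age and school attendance
with sibling or neighborhood fixed effects, reading off the two forces from
the shape of the fitted exposure polynomial.

## Exposure construction

For a target neighborhood *n* and birth month *b* the exposure is

    pnm(n, b) = [ Σ_p Σ_{m=b}^{b+11} deaths(p, m) ]
              / [ Σ_p Σ_{m=b}^{b+11} at_risk(p, m) ] × 1200,

pooling all neighborhoods *p* within 50 km (great-circle, haversine, Earth
radius 6371 km) in the same country, including *n*. `deaths(p, m)` counts
deaths at ages 1–12 months during calendar month *m*; `at_risk(p, m)`
counts children alive in that age band and under observation. The factor
1200 converts per-person-month rates to deaths per 100 person-years.

Ledger conventions (month-resolution data admit no fractions):

- age 12 months stays inside the "postneonatal" band because reported ages
  at death heap on 12 months; the `infant` variant adds age 0;
- the death month contributes one full at-risk person-month;
- the interview month is incomplete: months *m* with *m* ≥ survey month
  contribute neither exposure nor deaths (strict inequality);
- a rate is *valid* only where the pooled window holds at least 5 deaths
  and at least 600 person-months; children linked to invalid or absent
  windows are excluded rather than imputed;
- with distance weighting, each pooled neighborhood gets weight
  `ln(50 − d)`; weights that are not positive (d ≥ 49 km) are dropped,
  because a negative pooling weight has no interpretation as exposure;
  validity thresholds always use unweighted counts;
- the radius boundary is inclusive and distances are computed on the
  published (displaced) coordinates — the only ones an analyst has.

Construction variants exposed in `ExposureConfig`: radius (e.g. 25 km),
stricter person-month floors, the infant age band, a window offset of −9
months (exposure over the 12 months from conception), a 10-year recall
limit, and a natural-log transform of the linked rate.

`compute_rates` accepts an optional restriction of the reported window
start months; results are identical to the full grid (tested), so callers
may compute only the windows some child actually needs.

## Estimation

The outcome model is

    y_isnb = α + δ_s + β1·pnm + β2·pnm² [+ β3·pnm³] + θ′x_i + ε_isnb

with `pnm` centered at the 25th percentile of the pooled exposure
distribution *before* powers are formed — hence β1 is the marginal effect
at that percentile — and δ_s sibling (mother), neighborhood, or survey
fixed effects estimated by the within transformation (numerically identical
to group dummies; verified against a dummy regression to 1e-8).

Covariates: child age in months (and its square, formed before centering),
birth order, preceding birth interval (firstborns get the mean interval of
non-firstborns plus a firstborn indicator — dummy-variable adjustment),
female, twin; neighborhood- and survey-level models add mother's education,
mother's age at birth (and square), and sibship size, which sibling fixed
effects would absorb. All covariates are mean-centered on the analysis
sample, so the model constant α is the sample mean outcome. Interaction
models add `e×pnm` and `e×pnm²` for an any-education (or female) indicator,
plus the baseline indicator where fixed effects do not absorb it.

Sample rules: height-for-age uses survivors aged 12–59 months with
|z| ≤ 6; school attendance uses ages 7–16 years. One child per twin set
(the firstborn with valid data) enters sibling models, since exposure
cannot differ within a twin set; mothers left with fewer than two valid
children and neighborhoods with a single observation are dropped at the
respective levels. Every exclusion is counted in a ledger that reconciles
exactly with the input count. Missing covariates cause listwise deletion.

Inference is cluster-robust (Liang–Zeger) at the primary-sampling-unit
level with the CR1 factor `G/(G−1) × (N−1)/(N−K)`. When the fixed-effect
groups are nested inside clusters (siblings within a neighborhood, or the
neighborhoods themselves) the absorbed dummies are *not* counted in K: the
demeaning consumes within-cluster degrees of freedom, and counting them
would roughly double the variance for two-child sibling groups. A
simulation under the null (all structural effects zero, 200 replicates)
puts the 5%-level rejection rate of the exposure t-test at 5.0% under this
convention, against 2.5% under the dummy-counting one. Groups that span
clusters (survey fixed effects) do count their dummies. P-values use a t
reference with G−1 degrees of freedom; a binary-outcome sensitivity uses a
Mundlak logit (group means of all regressors appended) instead of per-group
dummies, avoiding the incidental-parameter problem.

Reported R² comes from the equivalent dummy regression (the within-R² is
also carried). The R² convention of published tables is ambiguous, so R² is
not used as a comparison surface.

## Marginal effects

For the quadratic, ME(x) = β1 + 2β2(x − x0); the cubic adds 3β3(x − x0)².
Delta-method variance uses the gradient (1, 2(x−x0)[, 3(x−x0)²]) over the
exposure coefficients and their cluster-robust covariance; intervals use
the normal 1.96 critical value (cluster counts in intended use make the
t/normal distinction immaterial). The percentile grid (p1–p99) is computed
once per run, by linear interpolation, on the pooled union of both outcome
samples *before* group exclusions, and shared across models, so every model
is evaluated at identical exposure levels; ME at x0 equals β1 exactly, and
its SE equals β1's SE exactly. Significance stars follow the
0.01/0.05/0.1 convention.

## The synthetic survey generator

Real birth-history microdata are access-restricted, so the package carries
a first-class generator whose statistical structure matches what the
estimator is designed to detect.

**Geometry.** Countries are disjoint ~0.8–1.2° boxes; each holds geocoded
sampling clusters ("neighborhoods"), urban with probability 0.35. Published
coordinates are displaced at uniform bearing and uniform distance up to
2 km (urban) or 5 km (rural), with a random 1% of rural clusters allowed
10 km — the anonymization scheme of real surveys. True coordinates are kept
for validation only.

**Adversity field.** The monthly postneonatal death hazard is
`mean + sd × z(nb, t)`, where z mixes unit-variance AR(1) knot series with
Gaussian-kernel spatial weights (rows normalized to unit norm), floored at
`mean × 1e-3`. Marginal variance is one everywhere; spatial correlation is
the inner product of kernel weights and decays with distance at
`spatial_scale_km`; the lag-1 autocorrelation equals the AR coefficient.
Defaults: mean 0.005/month (6.0 deaths per 100 person-years — inside the
empirically observed 0.5–34.8 range), sd 0.0015, scale 120 km, AR 0.9.

**Births and deaths.** Mothers (40 per neighborhood by default) carry a
Normal(0, 0.5²) latent frailty shared by their children — the family-level
confounder that sibling fixed effects are built to absorb. Birth events are
staggered (first uniform over the calendar span, then 9 + Gamma(2, 10)
month gaps); 1.5% of events are twin pairs. Each child dies at age 0 with
an independent neonatal hazard 0.02 (neonatal deaths mostly reflect birth
complications, not the infection environment, so they are deliberately
unrelated to the field — which is why replacing the postneonatal with the
infant rate dilutes the signal), and at each age a = 1..12 with probability

    min(1, h(nb, B+a) × exp(s · f · (h/h̄)^γ)),

with s = `selection_strength`, f the mother's frailty, and γ =
`selection_acceleration` (default 1). The γ exponent makes vulnerability
count for more where adversity is high — epidemic- and famine-type
mortality that culls the frail hardest in the worst months. This is a
deliberate design choice: with a hazard-independent multiplier (γ = 0,
recoverable by configuration) the survivor-composition bias
E[f | survive, x] is necessarily *concave* in exposure — the exponential
tilt always cuts the right frailty tail at a diminishing rate — so
selection could never dominate at high adversity, contradicting the very
mechanism the analysis probes for. Only months before the interview are
simulated; a child interviewed before completing the risk period is
right-censored by the ledger, never retroactively killed.

**Outcomes.** Survivors only (requesting outcomes for dead children is a
contract violation). Height-for-age:
`haz = (−2 + 1.5·e^{−age/12}) + scarring_slope_haz · x_true +
loading · f + Normal(0, 1)`, where `x_true` is the child's own realized
12-month hazard window mean × 1200 — the quantity the estimated exposure
approximates. School attendance is Bernoulli with a linear-probability
index, so its scarring slope is literally a probability change per unit
exposure. Negative loading means frail children fare worse — the
configuration under which selection flatters the survivors' average.

**What the generator does not emulate.** Survey weights and stratified
two-stage draw probabilities; migration (children are born where their
mother is interviewed — the same simplification the published analysis
makes); child-level frailty heterogeneity (frailty is wholly family-level);
age-at-death misreporting beyond the band convention; real spatial
population density. Passing tests therefore demonstrate internal
consistency of the estimator and its power against these specific
mechanisms, not performance under every failure mode of real survey data.

## Study conditions used by the simulation test suite

All simulation studies share an adversity field with mean 0.006/month
(7.2 per 100 person-years), sd 0.004, 60 km spatial scale, 20 knots —
chosen so the exposure distribution across linked children spans roughly
1–18 deaths per 100 person-years, matching the spread seen in pooled
multi-country data. Problem sizes per study:

- *Constant-hazard recovery*: flat hazard q = 0.005, ~100,000 children
  (6 countries × 80 neighborhoods × 100 mothers); the pooled ledger
  estimate must sit within 3 Monte-Carlo SEs of 1200q = 6.0.
- *Scarring recovery*: slope −0.02, selection off, ~50,000 children; the
  sibling-FE CI must cover −0.02. Point estimates land near −0.020 with a
  mild attenuation from the sampling noise of the estimated exposure.
- *Selection signature*: scarring −0.025 with selection (γ = 2, s = 0.4,
  frailty sd 0.6, loading −2.5) across 6 countries — many independent
  field realizations, because the squared term is identified from
  extreme-exposure windows. Criterion: β2 > 0 and ME(p90) > ME(p10) in at
  least 90% of 50 replicates, with the Fig-2-type shape (negative at p10,
  attenuating upward). Two opposing artifacts make this the hardest study:
  the measured rate is *endogenous to selection* (frailty-driven deaths
  inflate the rate exactly where survivor bias acts, re-linearizing the
  curve in measured-exposure space) and sampling noise attenuates the
  squared term quadratically.
- *Null calibration*: all structural effects zero, 200 replicates of a
  reduced design (2 × 40 × 40, 96 months); the 5%-level rejection rate of
  the exposure t-test must lie in 5% ± 2.5 pp.

Problem sizes were fixed once alongside these conditions; they are large
enough for the asymptotics the checks rely on while keeping the default
test run at desk scale.

## Numerical choices

- Validity thresholds are inclusive: ≥ 5 deaths ("more than four") and
  ≥ 600 person-months.
- Rank-deficient designs drop columns by pivoted QR with a logged warning;
  degenerate groups are re-checked after listwise deletion.
- Division by zero person-months yields an invalid (masked) rate, not an
  error.
- Percentiles use linear interpolation (`numpy.percentile` default).
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical configuration and seed reproduce
  every table byte for byte.

## Known limitations

- The generator's mother-level frailty means sibling fixed effects absorb
  the selection confounder entirely; the selection signature is therefore
  assessed with neighborhood fixed effects. Real selection likely also
  operates on child-level heterogeneity, which neither design absorbs.
- Exposure measurement error attenuates both coefficients; the package
  makes no errors-in-variables correction, mirroring the published method.
- The all-pairs distance computation is quadratic per country — fine for
  survey-scale inputs (thousands of clusters), not for millions.
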