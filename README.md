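# pnmscar

Scarring versus selective mortality in children who survive high-mortality
infancy: a pipeline for building a neighborhood-level, birth-month-indexed
**postneonatal mortality rate** from pooled geocoded birth histories, and
for estimating its nonlinear effect on survivors' height-for-age and school
attendance with **sibling or neighborhood fixed effects** and
cluster-robust inference.

It is written for demographers and epidemiologists working with DHS-style
survey microdata: birth histories with month-resolution dates, geocoded
primary sampling units with anonymization displacement, and child outcomes
measured at the interview. Because the real recode files are
access-restricted, the package ships a first-class synthetic survey
generator encoding the two mechanisms the analysis is designed to separate
— *scarring* (adversity in infancy leaves lasting deficits in survivors)
and *selection* (adversity removes the frailest children, flattering the
survivors' average) — so the whole pipeline is testable end to end.

## The model

The exposure of a child born in month *b* in neighborhood *n* is the
postneonatal mortality rate in its surroundings during its own infancy:

    pnm(n, b) = Σ_p Σ_{m=b}^{b+11} deaths(p, m)
              / Σ_p Σ_{m=b}^{b+11} at_risk(p, m) × 1200,

pooling all neighborhoods *p* within a 50 km great-circle radius in the
same country. Deaths and person-months count ages 1–12 months (age 12 kept
postneonatal because ages at death heap there); windows with fewer than 5
deaths or 600 person-months are masked as invalid. The ×1200 turns
per-person-month rates into deaths per 100 person-years.

Outcomes of surviving children are modeled as

    y_isnb = α + δ_s + β1·pnm_nb + β2·pnm²_nb + θ′x_i + ε_isnb,

with the exposure centered at its 25th percentile before powers are formed
(so β1 is the marginal effect there), δ_s sibling/neighborhood/survey fixed
effects estimated by the within transformation, and standard errors
clustered on primary sampling units. Marginal effects across the exposure
distribution are the derivative ME(x) = β1 + 2β2(x − x0), with delta-method
intervals. A negative β1 with a positive β2 — effects strong at low
adversity, fading to zero at high adversity — is the signature of scarring
increasingly masked by selection.

See `docs/methods.md` for the full conventions (censoring, twin rule,
validity thresholds, covariates, variance estimator) and the generator's
mechanics.

## Worked example

```python
from pnmscar.synthetic_data import SimConfig, AdversityFieldConfig
from pnmscar import pipeline, effects

cfg = SimConfig(seed=7, n_countries=2, n_neighborhoods_per_country=60,
                n_mothers_per_neighborhood=80, calendar_span_months=240,
                country_box_degrees=0.8,
                adversity_field=AdversityFieldConfig(
                    mean_monthly_death_hazard=0.006, hazard_sd=0.004,
                    spatial_scale_km=60.0, n_spatial_knots=20),
                scarring_slope_haz=-0.02)
res = pipeline.run(cfg, outcomes=("haz",), fe_levels=("sibling", "neighborhood"))

print("x0 (p25) =", round(res.x0, 2))
est = res.estimates["haz_sibling"]
print(est.summary_frame().loc[["pnm", "pnm_sq"]].round(4))
tab = effects.effects_table(res.estimates, res.percentiles[["p10", "p50", "p90"]],
                            res.x0)
```

which prints

```
x0 (p25) = 4.77

haz_sibling: n=2610, groups=1249, clusters=120
        estimate      se  ci_low  ci_high       p
pnm      -0.0433  0.0160 -0.0750  -0.0116  0.0079
pnm_sq    0.0035  0.0016  0.0004   0.0066  0.0258

marginal effects:
           model percentile  exposure_level  estimate     se stars
     haz_sibling        p10          3.2516   -0.0539 0.0202   ***
     haz_sibling        p50          6.7766   -0.0292 0.0111   ***
     haz_sibling        p90         13.8996    0.0209 0.0169
haz_neighborhood        p10          3.2516   -0.0278 0.0134    **
haz_neighborhood        p50          6.7766   -0.0177 0.0072    **
haz_neighborhood        p90         13.8996    0.0026 0.0120
```

Read: comparing siblings born into different adversity, an extra
postneonatal death per 100 person-years at the 10th exposure percentile
costs about 0.05 height-for-age z; by the 90th percentile the marginal
effect is indistinguishable from zero — the generator's selection mechanism
(configured here with hazard-accelerated frailty culling) progressively
cancels the scarring, and the fitted quadratic picks that up as β2 > 0.

A thin CLI wraps the same pipeline:

```
pnmscar simulate --seed 7 --out data/
pnmscar rates --data data/ --out rates.csv --radius-km 50
pnmscar fit --data data/ --out results/ --outcome haz --fe sibling
```

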