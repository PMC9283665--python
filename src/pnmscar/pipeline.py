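"""End-to-end orchestration: simulate -> rates -> samples -> fits -> effects."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from pnmscar import cohort, effects, estimation, exposure
from pnmscar.exposure import ExposureConfig
from pnmscar.estimation import FEEstimate, RegressionSpec
from pnmscar.synthetic_data import SimConfig, simulate_survey


@dataclass
class AnalysisResult:
    rates: pd.DataFrame
    linked: pd.DataFrame
    percentiles: pd.Series
    x0: float
    samples: dict[str, pd.DataFrame] = field(default_factory=dict)
    exclusions: dict[str, pd.DataFrame] = field(default_factory=dict)
    estimates: dict[str, FEEstimate] = field(default_factory=dict)


def link_children(tables: dict, exp_config: ExposureConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rates from the full pooled birth histories, linked to outcome children."""
    cells = exposure.expand_person_months(tables["births"], exp_config)
    rates = exposure.compute_rates(cells, tables["neighborhoods"], exp_config)
    children = tables["births"].merge(tables["outcomes"], on="child_id", how="inner")
    children = children.merge(
        tables["neighborhoods"][["neighborhood_id", "survey_id"]],
        on="neighborhood_id", how="left")
    linked = exposure.link_exposure(children, rates, exp_config)
    linked = cohort.add_derived_columns(linked, births=tables["births"])
    return rates, linked


def analyze(tables: dict,
            exp_config: ExposureConfig | None = None,
            outcomes: tuple[str, ...] = ("haz", "school"),
            fe_levels: tuple[str, ...] = ("sibling", "neighborhood"),
            polynomial_degree: int = 2,
            interaction: str = "none") -> AnalysisResult:
    """Run the full analysis on simulated (or equivalently shaped) tables.

    Fits one model per outcome x fixed-effects level, with the exposure
    centered at the 25th percentile of the pooled pre-exclusion sample.
    Estimate keys are ``f"{outcome}_{fe_level}"``.
    """
    exp_config = exp_config or ExposureConfig()
    rates, linked = link_children(tables, exp_config)

    filters = {"haz": cohort.filter_haz_sample, "school": cohort.filter_school_sample}
    samples, exclusions = {}, {}
    pool = []
    for out in outcomes:
        samples[out], exclusions[out] = filters[out](linked)
        pool.append(samples[out][["child_id", "exposure"]])
    pooled = pd.concat(pool).drop_duplicates("child_id")["exposure"]
    percentiles = effects.exposure_percentiles(pooled)
    x0 = float(percentiles["p25"])

    result = AnalysisResult(rates=rates, linked=linked,
                            percentiles=percentiles, x0=x0,
                            samples=samples, exclusions=exclusions)
    for out in outcomes:
        for fe in fe_levels:
            recs, excl = cohort.apply_group_rules(samples[out], fe)
            if recs.empty:
                continue
            cov = cohort.build_covariates(recs, fe)
            spec = RegressionSpec(outcome=out, fe_level=fe,
                                  polynomial_degree=polynomial_degree,
                                  interaction=interaction, centering_value=x0)
            key = f"{out}_{fe}"
            result.estimates[key] = estimation.fit_fe_ols(spec, recs, cov)
            result.exclusions[f"{key}_groups"] = excl
    return result


def run(sim_config: SimConfig | None = None,
        exp_config: ExposureConfig | None = None, **kwargs) -> AnalysisResult:
    """Simulate a survey and analyze it in one call."""
    tables = simulate_survey(sim_config or SimConfig())
    return analyze(tables, exp_config, **kwargs)
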