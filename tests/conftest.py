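import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from pnmscar.synthetic_data import AdversityFieldConfig, SimConfig, simulate_survey
from pnmscar.exposure import ExposureConfig
from pnmscar import pipeline

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def study_field(**kw) -> AdversityFieldConfig:
    """The adversity-field conditions used across simulation studies:
    mean 0.006/month (7.2 deaths per 100 person-years), sd 0.004, spatial
    texture at 60 km over 20 knots, AR(1) 0.9."""
    base = dict(mean_monthly_death_hazard=0.006, hazard_sd=0.004,
                spatial_scale_km=60.0, n_spatial_knots=20)
    base.update(kw)
    return AdversityFieldConfig(**base)


def small_config(seed=42, **kw) -> SimConfig:
    base = dict(seed=seed, n_countries=2, n_neighborhoods_per_country=40,
                n_mothers_per_neighborhood=40, calendar_span_months=240,
                country_box_degrees=0.8, adversity_field=study_field())
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_tables():
    return simulate_survey(small_config())


@pytest.fixture(scope="session")
def small_linked(small_tables):
    rates, linked = pipeline.link_children(small_tables, ExposureConfig())
    return {"rates": rates, "linked": linked}


def toy_births(rows) -> pd.DataFrame:
    """Birth records from compact tuples:
    (child, mother, nb, birth_month, death_age|None, survey_month)."""
    recs = []
    for child, mother, nb, b, a, s in rows:
        recs.append(dict(child_id=child, mother_id=mother, neighborhood_id=nb,
                         birth_month=b, death_age_months=a, survey_month=s,
                         female=False, twin=False, birth_order=1,
                         preceding_interval_months=np.nan,
                         mother_education_years=0, mother_birth_month=b - 300,
                         frailty=0.0))
    df = pd.DataFrame(recs)
    df["death_age_months"] = df["death_age_months"].astype("Int64")
    return df


def toy_neighborhoods(coords, country=None) -> pd.DataFrame:
    """Neighborhood table from (lat, lon) pairs; ids 0..n-1."""
    n = len(coords)
    country = country or [0] * n
    return pd.DataFrame({
        "neighborhood_id": range(n),
        "country_id": country,
        "survey_id": country,
        "latitude": [c[0] for c in coords],
        "longitude": [c[1] for c in coords],
        "true_latitude": [c[0] for c in coords],
        "true_longitude": [c[1] for c in coords],
        "urban": False,
    })
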