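"""Generator of DHS-like survey microdata with scarring and selection built in.

The generator emulates the statistical structure of pooled Demographic and
Health Survey birth histories:

* two-stage cluster geometry — geocoded primary sampling units ("neighborhoods")
  whose published coordinates are randomly displaced (0–2 km urban, 0–5 km
  rural, with 1% of rural units displaced up to 10 km);
* a smooth space-time *adversity field*: the monthly postneonatal death hazard
  varies over neighborhoods (Gaussian-kernel spatial mixing over knots) and
  calendar months (AR(1) innovations), so nearby places and months face
  correlated adversity;
* *selection*: each mother carries a latent frailty shared by her children;
  the monthly death hazard of a child is the local hazard times
  ``exp(selection_strength * frailty)``, so frailer children die
  disproportionately where and when adversity is high;
* *scarring*: surviving children's height-for-age (and school attendance)
  load negatively on the adversity they actually lived through in infancy.

Calendar months are integers counted from an arbitrary epoch (month 0), the
same convention as DHS century-month codes; the survey interview happens at
month ``calendar_span_months`` and all births precede it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

#: Ages (months) a death can take in the generator: 0 is neonatal, 1-12
#: is the postneonatal band used by the downstream rate estimator.
MAX_DEATH_AGE = 12


@dataclass
class AdversityFieldConfig:
    """Low-rank spatial Gaussian mixture x AR(1) hazard surface.

    ``mean_monthly_death_hazard`` is the stationary mean of the monthly
    postneonatal death probability; ``hazard_sd`` its marginal standard
    deviation. The implied long-run rate is ``mean * 1200`` deaths per 100
    person-years and must stay within the empirically plausible 0.5–34.8
    range.
    """

    n_spatial_knots: int = 12
    spatial_scale_km: float = 120.0
    temporal_ar_coefficient: float = 0.9
    mean_monthly_death_hazard: float = 0.005
    hazard_sd: float = 0.0015

    def validate(self) -> None:
        if self.n_spatial_knots < 1:
            raise ValueError("n_spatial_knots must be >= 1")
        if self.spatial_scale_km <= 0:
            raise ValueError("spatial_scale_km must be > 0")
        if not 0 <= self.temporal_ar_coefficient < 1:
            raise ValueError("temporal_ar_coefficient must be in [0, 1)")
        if self.mean_monthly_death_hazard <= 0:
            raise ValueError("mean_monthly_death_hazard must be > 0")
        if self.hazard_sd < 0:
            raise ValueError("hazard_sd must be >= 0")
        rate = self.mean_monthly_death_hazard * 1200.0
        if not 0.5 <= rate <= 34.8:
            raise ValueError(
                f"mean_monthly_death_hazard*1200 = {rate:.2f} outside the "
                "plausible 0.5-34.8 deaths per 100 person-years range"
            )


@dataclass
class DisplacementConfig:
    """Maximum GPS displacement (km) by sampling stratum."""

    urban: float = 2.0
    rural: float = 5.0
    rural_tail: float = 10.0
    rural_tail_fraction: float = 0.01

    def validate(self) -> None:
        for name in ("urban", "rural", "rural_tail"):
            if getattr(self, name) < 0:
                raise ValueError(f"displacement {name} must be >= 0")
        if not 0 <= self.rural_tail_fraction <= 1:
            raise ValueError("rural_tail_fraction must be in [0, 1]")


@dataclass
class SimConfig:
    """Everything the generator needs; one seed controls all randomness.

    Scarring slopes are per unit of exposure measured as deaths per 100
    person-years; ``selection_outcome_loading`` is negative when frailer
    children have worse outcomes (the configuration under which selective
    mortality flatters the survivors' average).
    """

    seed: int = 0
    n_countries: int = 2
    n_neighborhoods_per_country: int = 60
    n_mothers_per_neighborhood: int = 40
    calendar_span_months: int = 240
    adversity_field: AdversityFieldConfig = field(default_factory=AdversityFieldConfig)
    frailty_sd: float = 0.5
    selection_strength: float = 1.0
    # exponent linking vulnerability to the adversity level: the death
    # multiplier is exp(selection_strength * frailty * (h / mean_h)^accel),
    # so with accel > 0 frailty matters more where adversity is high —
    # selective mortality that *dominates at high adversity*. accel = 0
    # recovers a hazard-independent multiplier exp(strength * frailty).
    selection_acceleration: float = 1.0
    scarring_slope_haz: float = -0.02
    scarring_slope_school: float = -0.001
    selection_outcome_loading: float = -0.3
    school_selection_loading: float = -0.05
    urban_fraction: float = 0.35
    displacement: DisplacementConfig = field(default_factory=DisplacementConfig)
    # neonatal (age-0) deaths come from an independent hazard unrelated to
    # the adversity field: they mostly reflect birth complications, not the
    # infection/undernutrition environment the field stands for.
    neonatal_hazard: float = 0.02
    haz_noise_sd: float = 1.0
    school_base_probability: float = 0.76
    mean_children_per_mother: float = 3.0
    twin_probability: float = 0.015
    country_box_degrees: float = 1.2
    # optional in-utero channel: when True the scarring window starts at
    # conception (9 months before birth) instead of at birth.
    gestational_exposure: bool = False

    def validate(self) -> None:
        for name in ("urban_fraction", "neonatal_hazard", "twin_probability",
                     "school_base_probability"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_countries", "n_neighborhoods_per_country",
                     "n_mothers_per_neighborhood", "calendar_span_months"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.frailty_sd < 0 or self.selection_strength < 0:
            raise ValueError("frailty_sd and selection_strength must be >= 0")
        if self.haz_noise_sd < 0:
            raise ValueError("haz_noise_sd must be >= 0")
        if self.mean_children_per_mother < 1:
            raise ValueError("mean_children_per_mother must be >= 1")
        self.adversity_field.validate()
        self.displacement.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class HazardField:
    """Monthly death hazard per (neighborhood, calendar month).

    ``values[i, t]`` is the hazard of neighborhood ``neighborhood_ids[i]``
    in calendar month ``t`` (months are 0-based from the epoch).
    """

    neighborhood_ids: np.ndarray
    values: np.ndarray  # (n_neighborhoods, n_months)

    def __post_init__(self) -> None:
        self._row = {int(n): i for i, n in enumerate(self.neighborhood_ids)}

    @property
    def n_months(self) -> int:
        return self.values.shape[1]

    def row(self, neighborhood_id: int) -> np.ndarray:
        return self.values[self._row[int(neighborhood_id)]]

    def lookup(self, neighborhood_id, month) -> np.ndarray:
        """Vectorized hazard lookup for arrays of ids and months."""
        idx = np.asarray([self._row[int(n)] for n in np.atleast_1d(neighborhood_id)])
        return self.values[idx, np.atleast_1d(month)]


def _haversine_matrix(lat: np.ndarray, lon: np.ndarray,
                      lat2: np.ndarray, lon2: np.ndarray) -> np.ndarray:
    """All-pairs great-circle distances (km) between two coordinate sets."""
    la1 = np.radians(lat)[:, None]
    lo1 = np.radians(lon)[:, None]
    la2 = np.radians(lat2)[None, :]
    lo2 = np.radians(lon2)[None, :]
    a = (np.sin((la2 - la1) / 2.0) ** 2
         + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2.0) ** 2)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def make_neighborhoods(config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Scatter geocoded sampling units in one bounding box per country.

    Countries are laid out on well-separated longitudes so cross-country
    distances always exceed any plausible pooling radius. Returns true
    (pre-displacement) coordinates; :func:`displace_gps` adds the published
    ones.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    nb_id = 0
    for c in range(config.n_countries):
        lat0 = 2.0 + 3.0 * (c % 3)
        lon0 = 10.0 + 8.0 * c
        for _ in range(config.n_neighborhoods_per_country):
            rows.append({
                "neighborhood_id": nb_id,
                "country_id": c,
                "survey_id": c,
                "true_latitude": lat0 + rng.uniform(0, config.country_box_degrees),
                "true_longitude": lon0 + rng.uniform(0, config.country_box_degrees),
                "urban": bool(rng.random() < config.urban_fraction),
            })
            nb_id += 1
    return pd.DataFrame(rows)


def displace_gps(neighborhoods: pd.DataFrame, config: SimConfig,
                 seed: int | None = None) -> pd.DataFrame:
    """Anonymization displacement: uniform distance, uniform bearing.

    Urban units move at most ``displacement.urban`` km, rural units at most
    ``displacement.rural`` km except a random ``rural_tail_fraction`` of them
    which may move up to ``displacement.rural_tail`` km. True coordinates are
    retained (they exist only in synthetic data, for validation).
    """
    rng = np.random.default_rng(config.seed + 104729 if seed is None else seed)
    out = neighborhoods.copy()
    n = len(out)
    urban = out["urban"].to_numpy(bool)
    max_km = np.where(urban, config.displacement.urban, config.displacement.rural)
    tail = (~urban) & (rng.random(n) < config.displacement.rural_tail_fraction)
    max_km = np.where(tail, config.displacement.rural_tail, max_km)
    dist = rng.uniform(0.0, max_km)
    bearing = rng.uniform(0.0, 2.0 * np.pi, size=n)

    lat1 = np.radians(out["true_latitude"].to_numpy(float))
    lon1 = np.radians(out["true_longitude"].to_numpy(float))
    delta = dist / EARTH_RADIUS_KM
    lat2 = np.arcsin(np.sin(lat1) * np.cos(delta)
                     + np.cos(lat1) * np.sin(delta) * np.cos(bearing))
    lon2 = lon1 + np.arctan2(np.sin(bearing) * np.sin(delta) * np.cos(lat1),
                             np.cos(delta) - np.sin(lat1) * np.sin(lat2))
    out["latitude"] = np.degrees(lat2)
    out["longitude"] = np.degrees(lon2)
    out["displacement_km"] = dist
    return out


def generate_adversity_field(config: SimConfig, neighborhoods: pd.DataFrame,
                             seed: int | None = None,
                             n_months: int | None = None) -> HazardField:
    """Build the space-time hazard surface.

    Latent structure: unit-variance AR(1) series at ``n_spatial_knots``
    random knot locations per country, mixed into each neighborhood with
    Gaussian-kernel weights of scale ``spatial_scale_km`` (rows normalized to
    unit length so the marginal variance is one everywhere). The hazard is
    ``mean + sd * latent``, floored at ``mean * 1e-3`` to stay strictly
    positive. Spatial correlation between two neighborhoods is the inner
    product of their kernel weights, which decays with great-circle distance;
    the lag-1 temporal autocorrelation is the AR coefficient.
    """
    fc = config.adversity_field
    fc.validate()
    rng = np.random.default_rng(config.seed + 15485863 if seed is None else seed)
    if n_months is None:
        n_months = config.calendar_span_months + MAX_DEATH_AGE
    nb = neighborhoods.sort_values("neighborhood_id").reset_index(drop=True)
    values = np.empty((len(nb), n_months))
    rho = fc.temporal_ar_coefficient
    for _, grp in nb.groupby("country_id"):
        lat = grp["true_latitude"].to_numpy(float)
        lon = grp["true_longitude"].to_numpy(float)
        k = fc.n_spatial_knots
        knot_lat = rng.uniform(lat.min(), lat.max(), size=k)
        knot_lon = rng.uniform(lon.min(), lon.max(), size=k)
        d = _haversine_matrix(lat, lon, knot_lat, knot_lon)
        w = np.exp(-0.5 * (d / fc.spatial_scale_km) ** 2)
        w /= np.linalg.norm(w, axis=1, keepdims=True)
        # unit-marginal-variance AR(1) knot series
        u = np.empty((k, n_months))
        u[:, 0] = rng.standard_normal(k)
        innov = rng.standard_normal((k, n_months)) * np.sqrt(1.0 - rho ** 2)
        for t in range(1, n_months):
            u[:, t] = rho * u[:, t - 1] + innov[:, t]
        latent = w @ u
        haz = fc.mean_monthly_death_hazard + fc.hazard_sd * latent
        values[grp.index.to_numpy()] = np.maximum(
            haz, fc.mean_monthly_death_hazard * 1e-3)
    return HazardField(nb["neighborhood_id"].to_numpy(), values)


def simulate_birth_histories(config: SimConfig, neighborhoods: pd.DataFrame,
                             hazards: HazardField,
                             seed: int | None = None) -> pd.DataFrame:
    """Draw mothers, births and deaths month by month.

    Each mother gets ``1 + Poisson(mean_children_per_mother - 1)`` birth
    events, the first uniform over the calendar span and later ones separated
    by 9 + Gamma-distributed gaps (births falling past the interview are
    dropped). A birth event is a twin pair with probability
    ``twin_probability``. Death process: age 0 with the independent neonatal
    hazard; each age ``a`` in 1..12 with probability
    ``min(1, hazard(neighborhood, birth_month + a) * exp(selection_strength *
    frailty * (hazard / mean_hazard)^selection_acceleration))``, simulated
    only while the month precedes or equals the interview month (later
    months are unobservable). With ``selection_acceleration = 0`` the frailty
    multiplier is independent of the adversity level.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 32452843 if seed is None else seed)
    span = config.calendar_span_months
    survey_month = span

    nb = neighborhoods.sort_values("neighborhood_id").reset_index(drop=True)
    n_mothers = len(nb) * config.n_mothers_per_neighborhood
    mother_nb = np.repeat(nb["neighborhood_id"].to_numpy(), config.n_mothers_per_neighborhood)
    frailty = rng.normal(0.0, config.frailty_sd, size=n_mothers)
    # maternal schooling: roughly half have none, the rest average ~7 years
    any_edu = rng.random(n_mothers) < 0.48
    edu_years = np.where(any_edu, 1 + rng.poisson(5.8, size=n_mothers), 0)
    # mother aged 18-40 at first birth
    age_first_birth_months = rng.integers(18 * 12, 40 * 12, size=n_mothers)

    n_events = 1 + rng.poisson(config.mean_children_per_mother - 1.0, size=n_mothers)
    records: list[dict] = []
    child_id = 0
    for m in range(n_mothers):
        first = int(rng.integers(0, span))
        mother_birth_month = first - int(age_first_birth_months[m])
        b = first
        order = 0
        prev_b: int | None = None
        for _ in range(int(n_events[m])):
            if b >= survey_month:
                break
            k_children = 2 if rng.random() < config.twin_probability else 1
            for t in range(k_children):
                order += 1
                # the second twin's preceding interval is 0 (its co-twin);
                # only a true first birth has no preceding interval
                if t > 0:
                    interval = 0.0
                elif prev_b is None:
                    interval = np.nan
                else:
                    interval = float(b - prev_b)
                records.append({
                    "child_id": child_id,
                    "mother_id": m,
                    "neighborhood_id": int(mother_nb[m]),
                    "birth_month": b,
                    "female": bool(rng.random() < 0.49),
                    "twin": k_children > 1,
                    "birth_order": order,
                    "preceding_interval_months": interval,
                    "survey_month": survey_month,
                    "mother_education_years": int(edu_years[m]),
                    "mother_birth_month": mother_birth_month,
                    "frailty": float(frailty[m]),
                })
                child_id += 1
            prev_b = b
            b = b + 9 + int(round(rng.gamma(2.0, 10.0)))
    births = pd.DataFrame(records)

    # vectorized death process
    n = len(births)
    B = births["birth_month"].to_numpy(int)
    nb_row = np.asarray([hazards._row[i] for i in births["neighborhood_id"].to_numpy(int)])
    sf = config.selection_strength * births["frailty"].to_numpy(float)
    mean_h = config.adversity_field.mean_monthly_death_hazard
    death_age = np.full(n, -1, dtype=int)
    alive = np.ones(n, dtype=bool)
    # neonatal month (age 0): independent of the adversity field
    neo = rng.random(n) < config.neonatal_hazard
    death_age[neo] = 0
    alive &= ~neo
    for a in range(1, MAX_DEATH_AGE + 1):
        month = B + a
        observable = month <= survey_month
        h = hazards.values[nb_row, np.minimum(month, hazards.n_months - 1)]
        p = np.minimum(1.0, h * np.exp(sf * (h / mean_h) ** config.selection_acceleration))
        dies = alive & observable & (rng.random(n) < p)
        death_age[dies] = a
        alive &= ~dies
    births["death_age_months"] = pd.array(
        [a if a >= 0 else None for a in death_age], dtype="Int64")
    return births


def true_infancy_exposure(births: pd.DataFrame, hazards: HazardField,
                          config: SimConfig) -> np.ndarray:
    """Each child's own realized 12-month hazard-window mean, x1200.

    The window covers ages 1-12 (months ``birth_month+1 .. birth_month+12``),
    or the 12 months from conception when ``gestational_exposure`` is set.
    Scaled to deaths per 100 person-years, the same units as the estimated
    exposure downstream.
    """
    B = births["birth_month"].to_numpy(int)
    nb_row = np.asarray([hazards._row[i] for i in births["neighborhood_id"].to_numpy(int)])
    offset = -9 if config.gestational_exposure else 1
    months = B[:, None] + np.arange(offset, offset + 12)[None, :]
    months = np.clip(months, 0, hazards.n_months - 1)
    window = hazards.values[nb_row[:, None], months]
    return window.mean(axis=1) * 1200.0


def _baseline_age_profile(age_months: np.ndarray) -> np.ndarray:
    """Deterministic height-for-age trajectory: growth faltering that is
    steepest over the first two years, then a plateau near -2 z."""
    return -2.0 + 1.5 * np.exp(-np.asarray(age_months, float) / 12.0)


def assign_outcomes(birth_records: pd.DataFrame, hazards: HazardField,
                    config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Outcomes for surviving children.

    Raises if any record carries a recorded death: only survivors are
    measurable. Height-for-age z-scores are assigned to survivors aged 12-59
    months at the interview; school attendance to those aged 7-16 years.

    ``haz = age_profile(age) + scarring_slope_haz * exposure +
    selection_outcome_loading * frailty + Normal(0, haz_noise_sd)``;
    school attendance is a Bernoulli draw whose probability is the analogous
    linear index clipped to [0, 1], so ``scarring_slope_school`` is literally
    the probability change per unit exposure.
    """
    if birth_records["death_age_months"].notna().any():
        raise ValueError("outcomes requested for children recorded as dead")
    rng = np.random.default_rng(config.seed + 49979687 if seed is None else seed)
    rec = birth_records
    age = (rec["survey_month"] - rec["birth_month"]).to_numpy(int)
    x_true = true_infancy_exposure(rec, hazards, config)
    frailty = rec["frailty"].to_numpy(float)

    haz = (_baseline_age_profile(age)
           + config.scarring_slope_haz * x_true
           + config.selection_outcome_loading * frailty
           + rng.normal(0.0, config.haz_noise_sd, size=len(rec)))
    p_school = np.clip(config.school_base_probability
                       + config.scarring_slope_school * x_true
                       + config.school_selection_loading * frailty,
                       0.0, 1.0)
    school = rng.random(len(rec)) < p_school

    out = pd.DataFrame({
        "child_id": rec["child_id"].to_numpy(),
        "age_months": age,
        "haz": np.where((age >= 12) & (age <= 59), haz, np.nan),
        "school": pd.array(
            np.where((age >= 84) & (age <= 203), school.astype(float), np.nan)),
        "true_exposure": x_true,
    })
    out["school"] = out["school"].astype(float)
    return out


def simulate_survey(config: SimConfig) -> dict:
    """End-to-end generation; returns the three tables and the hazard field.

    Keys: ``neighborhoods`` (with both true and displaced coordinates),
    ``births`` (all children, dead or alive), ``outcomes`` (survivors only),
    ``hazards`` (the latent surface, for validation).
    """
    config.validate()
    nbs = make_neighborhoods(config)
    nbs = displace_gps(nbs, config)
    hazards = generate_adversity_field(config, nbs)
    births = simulate_birth_histories(config, nbs, hazards)
    survivors = births[births["death_age_months"].isna()]
    outcomes = assign_outcomes(survivors, hazards, config)
    return {"neighborhoods": nbs, "births": births,
            "outcomes": outcomes, "hazards": hazards}


def write_tables(tables: dict, outdir: str | Path, config: SimConfig) -> None:
    """Write neighborhoods.csv, births.csv, outcomes.csv and the sim config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("neighborhoods", "births", "outcomes"):
        tables[name].to_csv(outdir / f"{name}.csv", index=False)
    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)
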