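"""Neighborhood postneonatal mortality rate indexed to month of birth.

The exposure measure for a child born in month ``b`` in neighborhood ``n`` is

    pnm(n, b) = sum_p sum_{m=b}^{b+11} deaths[p, m]
              / sum_p sum_{m=b}^{b+11} at_risk[p, m]  * 1200

where ``p`` runs over all neighborhoods within ``radius_km`` great-circle
kilometers of ``n`` (including ``n`` itself, never crossing a country
border), ``deaths[p, m]`` counts deaths of children aged 1-12 months during
calendar month ``m`` in ``p``, and ``at_risk[p, m]`` counts person-months of
children alive in that age band and under observation. The factor 1200
converts deaths per person-month into deaths per 100 person-years.

Age 12 months is kept inside the postneonatal band because ages at death
heap on 12 months; the ``infant`` band variant adds age 0. A rate is valid
only where the pooled window has at least ``min_deaths`` deaths and
``min_person_months`` person-months.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pnmscar.synthetic_data import EARTH_RADIUS_KM

AGE_BANDS = {"postneonatal": (1, 12), "infant": (0, 12)}


@dataclass
class ExposureConfig:
    """Construction knobs for the rate; defaults are the primary analysis.

    ``window_offset`` shifts the 12-month window relative to the birth month
    at linkage time (-9 indexes the window to conception). ``weighting``
    "log_distance" weights each pooled neighborhood by ``ln(radius - d)``;
    ``max_recall_months`` drops births recalled from more than that many
    months before the interview; ``log_exposure`` links the natural log of
    the rate instead of the rate.
    """

    radius_km: float = 50.0
    min_deaths: int = 5
    min_person_months: float = 600.0
    window_length: int = 12
    window_offset: int = 0
    age_band: str = "postneonatal"
    weighting: str = "none"
    max_recall_months: int | None = None
    log_exposure: bool = False

    def validate(self) -> None:
        if self.radius_km <= 0:
            raise ValueError("radius_km must be > 0")
        if self.min_deaths < 0 or self.min_person_months < 0:
            raise ValueError("validity thresholds must be >= 0")
        if self.window_length != 12:
            raise ValueError("window_length is fixed at 12 months")
        if self.age_band not in AGE_BANDS:
            raise ValueError(f"age_band must be one of {sorted(AGE_BANDS)}")
        if self.weighting not in ("none", "log_distance"):
            raise ValueError("weighting must be 'none' or 'log_distance'")
        if self.max_recall_months is not None and self.max_recall_months <= 0:
            raise ValueError("max_recall_months must be positive when set")


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km (Earth radius 6371 km); vectorized.

    Raises on out-of-range coordinates.
    """
    lat1, lon1, lat2, lon2 = (np.asarray(v, dtype=float)
                              for v in (lat1, lon1, lat2, lon2))
    for lat in (lat1, lat2):
        if np.any(np.abs(lat) > 90.0):
            raise ValueError("latitude outside [-90, 90]")
    for lon in (lon1, lon2):
        if np.any(np.abs(lon) > 180.0):
            raise ValueError("longitude outside [-180, 180]")
    p1, l1, p2, l2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (np.sin((p2 - p1) / 2.0) ** 2
         + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2.0) ** 2)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def neighbor_sets(neighborhoods: pd.DataFrame,
                  config: ExposureConfig) -> dict[int, np.ndarray]:
    """For each neighborhood, ids within ``radius_km`` in the same country.

    Membership is symmetric, always includes the neighborhood itself, and
    never crosses country borders. Distances use the published (displaced)
    coordinates — the only coordinates a real analyst observes.
    """
    config.validate()
    result: dict[int, np.ndarray] = {}
    for _, grp in neighborhoods.groupby("country_id"):
        ids = grp["neighborhood_id"].to_numpy()
        lat = grp["latitude"].to_numpy(float)
        lon = grp["longitude"].to_numpy(float)
        d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
        within = d <= config.radius_km
        for i, n in enumerate(ids):
            result[int(n)] = np.sort(ids[within[i]])
    return result


def expand_person_months(births: pd.DataFrame,
                         config: ExposureConfig) -> pd.DataFrame:
    """Person-month ledger: deaths and at-risk counts per (neighborhood, month).

    A child with birth month B, survey month S and death age A (possibly
    missing) contributes one at-risk person-month to calendar month B+a for
    every age a in the band with B+a < S and (A missing or a <= A); the death
    month itself counts as a full at-risk month. A death is tallied at B+A
    iff A is in the band and B+A < S (the incomplete interview month
    contributes nothing). With ``max_recall_months`` set, children whose
    birth predates the interview by more than that are excluded entirely.
    """
    config.validate()
    lo, hi = AGE_BANDS[config.age_band]
    B = births["birth_month"].to_numpy(int)
    S = births["survey_month"].to_numpy(int)
    A = births["death_age_months"].to_numpy("float64", na_value=np.nan)
    if np.nanmin(A, initial=0.0) < 0:
        raise ValueError("negative death_age_months")
    nb = births["neighborhood_id"].to_numpy(int)

    keep = np.ones(len(births), dtype=bool)
    if config.max_recall_months is not None:
        keep = (S - B) <= config.max_recall_months
    nb_ids, nb_code = np.unique(nb, return_inverse=True)
    n_nb = len(nb_ids)
    max_month = int(S.max()) + 1
    at_risk = np.zeros((n_nb, max_month))
    deaths = np.zeros((n_nb, max_month))
    died = ~np.isnan(A)
    for a in range(lo, hi + 1):
        month = B + a
        risk = keep & (month < S) & (~died | (A >= a))
        np.add.at(at_risk, (nb_code[risk], month[risk]), 1.0)
        dies = keep & (month < S) & died & (A == a)
        np.add.at(deaths, (nb_code[dies], month[dies]), 1.0)

    nbi, mi = np.nonzero(at_risk + deaths)
    return pd.DataFrame({
        "neighborhood_id": nb_ids[nbi],
        "month": mi,
        "deaths": deaths[nbi, mi],
        "at_risk": at_risk[nbi, mi],
    })


def _window_sum(series: np.ndarray, window: int) -> np.ndarray:
    """Sliding sums over ``window`` consecutive months, indexed by start month."""
    c = np.concatenate([np.zeros(series.shape[:-1] + (1,)), np.cumsum(series, axis=-1)],
                       axis=-1)
    return c[..., window:] - c[..., :-window]


def compute_rates(cells: pd.DataFrame, neighborhoods: pd.DataFrame,
                  config: ExposureConfig,
                  birth_months: np.ndarray | None = None) -> pd.DataFrame:
    """Pooled windowed rates for every (neighborhood, birth month) pair.

    ``birth_months`` optionally restricts the reported window start months
    (the full grid is the default); results are identical either way for the
    months reported. Validity thresholds are always evaluated on unweighted
    death and person-month sums, even under distance weighting.
    """
    config.validate()
    w = config.window_length
    frames = []
    for _, grp in neighborhoods.groupby("country_id"):
        ids = grp["neighborhood_id"].to_numpy()
        lat = grp["latitude"].to_numpy(float)
        lon = grp["longitude"].to_numpy(float)
        d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
        adjacency = (d <= config.radius_km).astype(float)
        if config.weighting == "log_distance":
            with np.errstate(invalid="ignore", divide="ignore"):
                lw = np.log(config.radius_km - d)
            # weights that are not positive (d >= radius - 1) are dropped:
            # a negative pooling weight is not interpretable.
            weights = np.where((d <= config.radius_km) & (lw > 0), lw, 0.0)
        else:
            weights = adjacency

        sub = cells[cells["neighborhood_id"].isin(ids)]
        if sub.empty:
            continue
        pos = {int(n): i for i, n in enumerate(ids)}
        rows = sub["neighborhood_id"].map(pos).to_numpy()
        months = sub["month"].to_numpy(int)
        n_months = months.max() + 1
        D = np.zeros((len(ids), n_months))
        R = np.zeros((len(ids), n_months))
        D[rows, months] = sub["deaths"].to_numpy(float)
        R[rows, months] = sub["at_risk"].to_numpy(float)
        if n_months < w:
            pad = w - n_months
            D = np.pad(D, ((0, 0), (0, pad)))
            R = np.pad(R, ((0, 0), (0, pad)))

        deaths_u = _window_sum(adjacency @ D, w)   # unweighted, for validity
        pm_u = _window_sum(adjacency @ R, w)
        if config.weighting == "none":
            deaths_w, pm_w = deaths_u, pm_u
        else:
            deaths_w = _window_sum(weights @ D, w)
            pm_w = _window_sum(weights @ R, w)

        n_b = deaths_u.shape[1]
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(pm_w > 0, deaths_w / np.where(pm_w > 0, pm_w, 1.0) * 1200.0,
                            np.nan)
        valid = (deaths_u >= config.min_deaths) & (pm_u >= config.min_person_months)
        frames.append(pd.DataFrame({
            "neighborhood_id": np.repeat(ids, n_b),
            "birth_month": np.tile(np.arange(n_b), len(ids)),
            "rate": rate.ravel(),
            "deaths_sum": deaths_u.ravel(),
            "person_months_sum": pm_u.ravel(),
            "valid": valid.ravel(),
        }))
    if not frames:
        return pd.DataFrame(columns=["neighborhood_id", "birth_month", "rate",
                                     "deaths_sum", "person_months_sum", "valid"])
    rates = pd.concat(frames, ignore_index=True)
    if birth_months is not None:
        rates = rates[rates["birth_month"].isin(np.asarray(birth_months))]
        rates = rates.reset_index(drop=True)
    return rates


def link_exposure(children: pd.DataFrame, rates: pd.DataFrame,
                  config: ExposureConfig) -> pd.DataFrame:
    """Attach the rate at (neighborhood, birth_month + window_offset).

    Children whose window is invalid or absent from the rate table get
    ``excluded=True`` and a missing exposure. With ``log_exposure`` the
    natural log of the rate is linked (non-positive rates are excluded).
    """
    config.validate()
    out = children.copy()
    out["_link_month"] = out["birth_month"] + config.window_offset
    merged = out.merge(
        rates.rename(columns={"birth_month": "_link_month"}),
        on=["neighborhood_id", "_link_month"], how="left", validate="m:1")
    valid = merged["valid"].astype("boolean").fillna(False).to_numpy(bool)
    exposure = merged["rate"].to_numpy(float)
    if config.log_exposure:
        with np.errstate(invalid="ignore", divide="ignore"):
            exposure = np.where(exposure > 0, np.log(exposure), np.nan)
        valid &= ~np.isnan(exposure)
    merged["exposure"] = np.where(valid, exposure, np.nan)
    merged["excluded"] = ~valid
    return merged.drop(columns=["_link_month"])
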