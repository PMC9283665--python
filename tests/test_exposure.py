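"""Rate estimator: distances, neighbor pooling, person-month ledger, windows,
validity thresholds, linkage — including the hand-enumerated and brute-force
oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pnmscar.exposure import (
    AGE_BANDS, ExposureConfig, compute_rates, expand_person_months,
    haversine_km, link_exposure, neighbor_sets,
)

from conftest import small_config, toy_births, toy_neighborhoods
from pnmscar.synthetic_data import simulate_survey


class TestHaversine:
    def test_identity_is_zero(self):
        assert haversine_km(10.0, 20.0, 10.0, 20.0) == 0.0

    def test_one_degree_along_equator(self):
        # arc length of one degree on a 6371 km sphere
        assert haversine_km(0, 0, 0, 1) == pytest.approx(
            6371 * np.pi / 180, abs=1e-3)

    def test_antipodal_on_equator(self):
        assert haversine_km(0, 0, 0, 180) == pytest.approx(6371 * np.pi, rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            haversine_km(91, 0, 0, 0)
        with pytest.raises(ValueError):
            haversine_km(0, 181, 0, 0)

    @given(st.floats(-80, 80), st.floats(-179, 179),
           st.floats(-80, 80), st.floats(-179, 179))
    def test_symmetric_and_nonnegative(self, lat1, lon1, lat2, lon2):
        d12 = haversine_km(lat1, lon1, lat2, lon2)
        d21 = haversine_km(lat2, lon2, lat1, lon1)
        assert d12 >= 0
        assert d12 == pytest.approx(d21, rel=1e-9, abs=1e-9)


class TestNeighborSets:
    def test_single_neighborhood_is_own_set(self):
        nbs = toy_neighborhoods([(0.0, 0.0)])
        sets = neighbor_sets(nbs, ExposureConfig())
        assert list(sets[0]) == [0]

    def test_radius_boundary(self):
        # 0.449 deg of longitude on the equator ~ 49.93 km; 0.46 deg ~ 51.2 km
        near = toy_neighborhoods([(0.0, 0.0), (0.0, 0.449)])
        far = toy_neighborhoods([(0.0, 0.0), (0.0, 0.46)])
        cfg = ExposureConfig()
        s_near = neighbor_sets(near, cfg)
        assert set(s_near[0]) == {0, 1} and set(s_near[1]) == {0, 1}
        s_far = neighbor_sets(far, cfg)
        assert set(s_far[0]) == {0} and set(s_far[1]) == {1}

    def test_never_crosses_country_borders(self):
        nbs = toy_neighborhoods([(0.0, 0.0), (0.0, 0.01)], country=[0, 1])
        sets = neighbor_sets(nbs, ExposureConfig())
        assert set(sets[0]) == {0} and set(sets[1]) == {1}

    def test_membership_symmetric(self, small_tables):
        sets = neighbor_sets(small_tables["neighborhoods"], ExposureConfig())
        for n, members in sets.items():
            assert n in members
            for p in members:
                assert n in sets[int(p)]


class TestPersonMonthLedger:
    def survivor(self):
        return toy_births([(0, 0, 0, 100, None, 200)])

    def test_survivor_contributes_twelve_months(self):
        cells = expand_person_months(self.survivor(), ExposureConfig())
        assert cells["deaths"].sum() == 0
        assert cells["at_risk"].sum() == 12
        assert sorted(cells["month"]) == list(range(101, 113))

    def test_death_at_three_months(self):
        cells = expand_person_months(
            toy_births([(0, 0, 0, 100, 3, 200)]), ExposureConfig())
        assert sorted(cells["month"]) == [101, 102, 103]
        assert cells["at_risk"].sum() == 3
        death = cells[cells["deaths"] > 0]
        assert len(death) == 1 and death["month"].iloc[0] == 103

    def test_right_censoring_at_survey(self):
        cells = expand_person_months(
            toy_births([(0, 0, 0, 100, None, 105)]), ExposureConfig())
        assert sorted(cells["month"]) == [101, 102, 103, 104]
        assert cells["deaths"].sum() == 0

    def test_infant_band_adds_month_zero(self):
        cells = expand_person_months(self.survivor(),
                                     ExposureConfig(age_band="infant"))
        assert cells["at_risk"].sum() == 13
        assert cells["month"].min() == 100

    def test_neonatal_death_outside_postneonatal_band(self):
        cells = expand_person_months(
            toy_births([(0, 0, 0, 100, 0, 200)]), ExposureConfig())
        assert cells["deaths"].sum() == 0 and cells["at_risk"].sum() == 0
        infant = expand_person_months(
            toy_births([(0, 0, 0, 100, 0, 200)]), ExposureConfig(age_band="infant"))
        assert infant["deaths"].sum() == 1 and infant["at_risk"].sum() == 1

    def test_recall_window_drops_old_births(self):
        births = toy_births([(0, 0, 0, 100, None, 250),
                             (1, 0, 0, 160, None, 250)])
        cells = expand_person_months(births, ExposureConfig(max_recall_months=120))
        assert cells["at_risk"].sum() == 12
        assert cells["month"].min() == 161

    def test_negative_death_age_rejected(self):
        births = self.survivor()
        births["death_age_months"] = pd.array([-1], dtype="Int64")
        with pytest.raises(ValueError):
            expand_person_months(births, ExposureConfig())

    @pytest.mark.parametrize("age_band", ["postneonatal", "infant"])
    def test_ledger_equals_brute_force_enumeration(self, small_tables, age_band):
        """Cell-for-cell equality with an independent per-child loop."""
        births = small_tables["births"].head(1000)
        cfg = ExposureConfig(age_band=age_band)
        lo, hi = AGE_BANDS[age_band]
        deaths, at_risk = {}, {}
        for rec in births.itertuples():
            a_death = (None if pd.isna(rec.death_age_months)
                       else int(rec.death_age_months))
            for a in range(lo, hi + 1):
                m = rec.birth_month + a
                if m >= rec.survey_month:
                    continue
                if a_death is not None and a > a_death:
                    continue
                key = (rec.neighborhood_id, m)
                at_risk[key] = at_risk.get(key, 0) + 1
                if a_death == a:
                    deaths[key] = deaths.get(key, 0) + 1
        cells = expand_person_months(births, cfg)
        got_risk = {(r.neighborhood_id, r.month): r.at_risk
                    for r in cells.itertuples()}
        got_deaths = {(r.neighborhood_id, r.month): r.deaths
                      for r in cells.itertuples() if r.deaths > 0}
        assert got_risk == at_risk
        assert got_deaths == deaths

    def test_death_conservation(self, small_tables):
        births = small_tables["births"]
        cells = expand_person_months(births, ExposureConfig())
        a = births["death_age_months"]
        in_band = (a >= 1) & (a <= 12)
        before_survey = (births["birth_month"] + a) < births["survey_month"]
        assert cells["deaths"].sum() == (in_band & before_survey).sum()


class TestRates:
    def _one_window_cells(self, deaths, pm):
        """One isolated neighborhood with uniform cells over months 0..11."""
        per_month = pm / 12.0
        d = np.zeros(12)
        d[:deaths] = 1.0
        return pd.DataFrame({"neighborhood_id": 0, "month": range(12),
                             "deaths": d, "at_risk": per_month})

    def _rate_at(self, cells, **kw):
        nbs = toy_neighborhoods([(0.0, 0.0)])
        rates = compute_rates(cells, nbs, ExposureConfig(**kw))
        return rates[rates["birth_month"] == 0].iloc[0]

    def test_five_deaths_in_1200_person_months(self):
        row = self._rate_at(self._one_window_cells(5, 1200))
        assert row["rate"] == pytest.approx(5.0)
        assert bool(row["valid"])

    def test_four_deaths_invalid(self):
        row = self._rate_at(self._one_window_cells(4, 1200))
        assert not row["valid"]

    def test_599_person_months_invalid(self):
        row = self._rate_at(self._one_window_cells(5, 599))
        assert not row["valid"]
        assert self._rate_at(self._one_window_cells(5, 600))["valid"]

    def test_no_deaths_all_invalid_rate_zero(self):
        cells = self._one_window_cells(0, 1200)
        nbs = toy_neighborhoods([(0.0, 0.0)])
        rates = compute_rates(cells, nbs, ExposureConfig())
        assert (rates["rate"].dropna() == 0).all()
        assert not rates["valid"].any()

    def test_zero_person_months_is_invalid_not_an_error(self):
        cells = pd.DataFrame({"neighborhood_id": [0], "month": [50],
                              "deaths": [0.0], "at_risk": [1.0]})
        nbs = toy_neighborhoods([(0.0, 0.0)])
        rates = compute_rates(cells, nbs, ExposureConfig())
        empty = rates[rates["birth_month"] == 10].iloc[0]
        assert np.isnan(empty["rate"]) and not empty["valid"]

    def test_pooling_sums_neighbors_within_radius(self):
        nbs = toy_neighborhoods([(0.0, 0.0), (0.0, 0.2), (0.0, 3.0)])
        cells = pd.concat([
            self._one_window_cells(3, 600),
            self._one_window_cells(4, 600).assign(neighborhood_id=1),
            self._one_window_cells(5, 600).assign(neighborhood_id=2)])
        rates = compute_rates(cells, nbs, ExposureConfig())
        r0 = rates[(rates["neighborhood_id"] == 0) & (rates["birth_month"] == 0)]
        assert r0["deaths_sum"].iloc[0] == 7  # pools nb 1, not distant nb 2
        assert r0["person_months_sum"].iloc[0] == 1200
        assert r0["rate"].iloc[0] == pytest.approx(7.0)

    def test_log_distance_weighting_drops_nonpositive_weights(self):
        # neighbor at ~22 km: weight ln(50-22)>0; neighbor at ~49.5 km:
        # ln(50-49.5)<0 so it must be excluded from the weighted sums
        nbs = toy_neighborhoods([(0.0, 0.0), (0.0, 0.2), (0.0, 0.445)])
        d2 = haversine_km(0, 0, 0, 0.2)
        cells = pd.concat([
            self._one_window_cells(3, 600),
            self._one_window_cells(6, 1200).assign(neighborhood_id=1),
            self._one_window_cells(12, 600).assign(neighborhood_id=2)])
        rates = compute_rates(cells, nbs, ExposureConfig(weighting="log_distance"))
        r0 = rates[(rates["neighborhood_id"] == 0) & (rates["birth_month"] == 0)]
        w_self = np.log(50.0)
        w2 = np.log(50.0 - d2)
        expect = (w_self * 3 + w2 * 6) / (w_self * 600 + w2 * 1200) * 1200
        assert r0["rate"].iloc[0] == pytest.approx(expect)
        # validity still judged on unweighted counts, which include nb 2
        assert r0["deaths_sum"].iloc[0] == 21

    def test_restricted_birth_months_match_full_grid(self, small_tables):
        cells = expand_person_months(small_tables["births"], ExposureConfig())
        nbs = small_tables["neighborhoods"]
        full = compute_rates(cells, nbs, ExposureConfig())
        some = np.array([40, 41, 55])
        sub = compute_rates(cells, nbs, ExposureConfig(), birth_months=some)
        merged = full[full["birth_month"].isin(some)].reset_index(drop=True)
        pd.testing.assert_frame_equal(
            merged.sort_values(["neighborhood_id", "birth_month"]).reset_index(drop=True),
            sub.sort_values(["neighborhood_id", "birth_month"]).reset_index(drop=True))

    def test_rates_invariant_to_neighborhood_order(self, small_tables):
        cells = expand_person_months(small_tables["births"], ExposureConfig())
        nbs = small_tables["neighborhoods"]
        a = compute_rates(cells, nbs, ExposureConfig())
        b = compute_rates(cells.sample(frac=1, random_state=0),
                          nbs.sample(frac=1, random_state=1), ExposureConfig())
        key = ["neighborhood_id", "birth_month"]
        pd.testing.assert_frame_equal(
            a.sort_values(key).reset_index(drop=True),
            b.sort_values(key).reset_index(drop=True))

    def test_masking_monotonicity(self, small_tables):
        cells = expand_person_months(small_tables["births"], ExposureConfig())
        nbs = small_tables["neighborhoods"]
        base = compute_rates(cells, nbs, ExposureConfig())
        stricter = compute_rates(cells, nbs,
                                 ExposureConfig(min_deaths=10,
                                                min_person_months=1200))
        assert stricter["valid"].sum() <= base["valid"].sum()
        smaller = compute_rates(cells, nbs, ExposureConfig(radius_km=25.0))
        m = base.merge(smaller, on=["neighborhood_id", "birth_month"],
                       suffixes=("_50", "_25"))
        assert (m["person_months_sum_25"] <= m["person_months_sum_50"]).all()


class TestLinkage:
    def _rates(self):
        return pd.DataFrame({
            "neighborhood_id": [0, 0, 0],
            "birth_month": [91, 100, 101],
            "rate": [3.0, 5.25, 7.0],
            "deaths_sum": [9, 9, 9],
            "person_months_sum": [2000, 2000, 2000],
            "valid": [True, True, False],
        })

    def test_valid_rate_passes_through(self):
        children = toy_births([(0, 0, 0, 100, None, 200)])
        linked = link_exposure(children, self._rates(), ExposureConfig())
        assert linked["exposure"].iloc[0] == 5.25
        assert not linked["excluded"].iloc[0]

    def test_invalid_or_missing_rate_excludes_child(self):
        children = toy_births([(0, 0, 0, 101, None, 200),
                               (1, 0, 0, 150, None, 200),
                               (2, 0, 5, 100, None, 200)])
        linked = link_exposure(children, self._rates(), ExposureConfig())
        assert linked["excluded"].all()
        assert linked["exposure"].isna().all()

    def test_conception_offset_links_nine_months_earlier(self):
        children = toy_births([(0, 0, 0, 100, None, 200)])
        linked = link_exposure(children, self._rates(),
                               ExposureConfig(window_offset=-9))
        assert linked["exposure"].iloc[0] == 3.0

    def test_log_exposure_transform(self):
        children = toy_births([(0, 0, 0, 100, None, 200)])
        linked = link_exposure(children, self._rates(),
                               ExposureConfig(log_exposure=True))
        assert linked["exposure"].iloc[0] == pytest.approx(np.log(5.25))


def test_constant_hazard_rate_recovery_small():
    """Pooled rate estimate approaches 1200*q under a flat hazard."""
    from conftest import study_field
    cfg = small_config(
        seed=2, n_mothers_per_neighborhood=120,
        adversity_field=study_field(mean_monthly_death_hazard=0.005,
                                    hazard_sd=0.0),
        selection_strength=0.0)
    tables = simulate_survey(cfg)
    cells = expand_person_months(tables["births"], ExposureConfig())
    d, pm = cells["deaths"].sum(), cells["at_risk"].sum()
    rate = d / pm * 1200
    mc_se = 1200 * np.sqrt(d) / pm
    assert abs(rate - 6.0) < 3 * mc_se
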