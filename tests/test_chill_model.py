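import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chillday import (
    DailyTemperatureRecord,
    ModelParams,
    chill_contributions,
    daily_chill_antichill,
    predict_pbd_series,
    run_season,
)
from chillday.weather_io import SeasonExtractionError

from conftest import constant_season, oracle_chill_antichill


class TestModelParams:
    @pytest.mark.parametrize(
        "tc,rc,rh",
        [(5.0, -20.0, 0.0), (5.0, 20.0, 50.0), (5.0, -20.0, -1.0), (-1.0, -20.0, 50.0)],
    )
    def test_invalid_triples_rejected(self, tc, rc, rh):
        with pytest.raises(ValueError):
            ModelParams(tc, rc, rh)


class TestDailyContribution:
    @pytest.mark.parametrize(
        "tmax,tmin,tc,cd,ca,case",
        [
            # whole triangle above threshold
            (14.0, 6.0, 4.3, 0.0, 5.7, "1"),
            # whole triangle below threshold, base above freezing
            (4.0, 0.0, 5.3, -2.0, 0.0, "3"),
            # threshold inside the triangle
            (10.0, 0.0, 4.3, -(5.0 - 5.7**2 / 20.0), 5.7**2 / 20.0, "2"),
            # base below freezing, apex below threshold
            (4.0, -4.0, 5.0, -1.0, 0.0, "4"),
            # base below freezing, threshold inside
            (10.0, -2.0, 4.0, -(100.0 / 24.0 - 36.0 / 24.0), 36.0 / 24.0, "5"),
        ],
    )
    def test_closed_form_cases(self, tmax, tmin, tc, cd, ca, case):
        got = daily_chill_antichill(tmax, tmin, tc)
        assert got.case == case
        assert got.cd == pytest.approx(cd, abs=1e-12)
        assert got.ca == pytest.approx(ca, abs=1e-12)

    def test_isothermal_day_is_case_limit(self):
        warm = daily_chill_antichill(8.0, 8.0, 5.0)
        assert (warm.cd, warm.ca) == (0.0, 3.0)
        cold = daily_chill_antichill(3.0, 3.0, 5.0)
        assert (cold.cd, cold.ca) == (0.0, 0.0)

    def test_subzero_day_contributes_nothing(self):
        got = daily_chill_antichill(-1.0, -8.0, 5.0)
        assert (got.cd, got.ca) == (0.0, 0.0)

    def test_tmax_below_tmin_rejected(self):
        with pytest.raises(ValueError):
            daily_chill_antichill(5.0, 9.0, 4.0)

    @settings(max_examples=300, derandomize=True)
    @given(
        tmin=st.floats(-25.0, 30.0),
        span=st.floats(0.001, 25.0),
        tc=st.floats(0.0, 12.0),
    )
    def test_matches_triangle_area_oracle(self, tmin, span, tc):
        tmax = tmin + span
        got = daily_chill_antichill(tmax, tmin, tc)
        cd, ca = oracle_chill_antichill(tmax, tmin, tc)
        assert got.cd == pytest.approx(cd, abs=1e-3)
        assert got.ca == pytest.approx(ca, abs=1e-3)

    @settings(max_examples=300, derandomize=True)
    @given(
        tmin=st.floats(-25.0, 30.0),
        span=st.floats(1e-6, 25.0),
        tc=st.floats(0.0, 12.0),
    )
    def test_signs_and_single_case(self, tmin, span, tc):
        got = daily_chill_antichill(tmin + span, tmin, tc)
        assert got.cd <= 0.0
        assert got.ca >= 0.0
        assert got.case in {"1", "2", "3", "4", "5", "subzero", "isothermal"}

    @pytest.mark.parametrize(
        "tmax,tmin,tc",
        [
            (8.0, 5.0, 5.0),  # tc == tmin (case 1/2 boundary)
            (5.0, 2.0, 5.0),  # tc == tmax (case 2/3 boundary)
            (8.0, 0.0, 5.0),  # tmin == 0 (case 2/5 boundary)
            (4.0, 0.0, 5.0),  # tmin == 0 (case 3/4 boundary)
            (0.0, -5.0, 3.0),  # tmax == 0 (case 4 / subzero boundary)
            (6.0, 6.0, 4.0),  # isothermal limit
        ],
    )
    def test_continuity_across_case_boundaries(self, tmax, tmin, tc):
        eps = 1e-6
        base = daily_chill_antichill(tmax, tmin, tc)
        for dx in (-eps, 0.0, eps):
            for dn in (-eps, 0.0, eps):
                if tmax + dx < tmin + dn:
                    continue
                other = daily_chill_antichill(tmax + dx, tmin + dn, tc)
                assert abs(other.cd - base.cd) < 1e-4
                assert abs(other.ca - base.ca) < 1e-4

    def test_vectorised_agrees_with_scalar(self):
        rng = np.random.default_rng(7)
        tn = rng.uniform(-20, 25, 500)
        tx = tn + rng.uniform(0, 20, 500)
        for tc in (0.0, 4.3, 7.0):
            cd, ca = chill_contributions(tx, tn, tc)
            for i in range(0, 500, 37):
                s = daily_chill_antichill(tx[i], tn[i], tc)
                assert cd[i] == pytest.approx(s.cd, abs=1e-12)
                assert ca[i] == pytest.approx(s.ca, abs=1e-12)


class TestRunSeason:
    def test_step_season_hand_accumulation(self, step_season):
        # cold phase: Cd = -1/day so release on day 20; warm phase: Ca = 5/day
        # so 50 anti-chill days are reached 10 days later
        pred = run_season(step_season, ModelParams(5.0, -20.0, 50.0))
        assert pred.status == "bloomed"
        assert pred.release_date == dt.date(2009, 10, 20)
        assert pred.pbd == dt.date(2009, 10, 30)

    def test_no_release_when_always_warm(self):
        season = constant_season(cold_days=0, warm=(20.0, 12.0))
        pred = run_season(season, ModelParams(5.0, -20.0, 50.0))
        assert pred.status == "no-release"
        assert pred.release_date is None and pred.pbd is None

    def test_no_bloom_when_forcing_never_satisfied(self):
        # release quickly, then stay cold so anti-chill days never accrue
        season = constant_season(cold_days=273, cold=(4.0, 2.0))
        pred = run_season(season, ModelParams(5.0, -20.0, 50.0))
        assert pred.status == "no-bloom"
        assert pred.release_date is not None and pred.pbd is None

    def test_trajectories_conserve_daily_sums(self, step_season):
        params = ModelParams(5.0, -20.0, 50.0)
        pred = run_season(step_season, params)
        cd = [daily_chill_antichill(r.tmax, r.tmin, params.tc).cd for r in step_season.records]
        assert pred.chill_trajectory[-1] == pytest.approx(sum(cd))
        assert np.all(np.diff(pred.chill_trajectory) <= 1e-12)
        assert np.all(np.diff(pred.forcing_trajectory) >= -1e-12)
        # forcing restarts after release: first forcing day is the day after
        rel_idx = (pred.release_date - step_season.onset).days
        ca_after = [
            daily_chill_antichill(r.tmax, r.tmin, params.tc).ca
            for r in step_season.records[rel_idx + 1 :]
        ]
        assert pred.forcing_trajectory[0] == pytest.approx(ca_after[0])
        assert pred.forcing_trajectory[-1] == pytest.approx(sum(ca_after))

    def test_uniform_warming_never_delays_bloom(self, step_season):
        params = ModelParams(5.0, -20.0, 50.0)
        base = run_season(step_season, params)
        rel_idx = (base.release_date - step_season.onset).days
        for delta in (0.5, 1.0, 3.0):
            warmed = [
                DailyTemperatureRecord(
                    r.date,
                    r.tmax + (delta if i > rel_idx else 0.0),
                    r.tmin + (delta if i > rel_idx else 0.0),
                )
                for i, r in enumerate(step_season.records)
            ]
            season = type(step_season)(step_season.label, step_season.onset, warmed)
            pred = run_season(season, params)
            assert pred.bloomed
            assert pred.pbd <= base.pbd


class TestPredictSeries:
    def _two_season_records(self):
        recs = []
        for year in (2008, 2009):
            recs.extend(constant_season(start_year=year).records)
        return recs

    def test_independent_identical_seasons(self):
        recs = self._two_season_records()
        result = predict_pbd_series(recs, ModelParams(5.0, -20.0, 50.0), [2008, 2009])
        assert set(result.predictions) == {2008, 2009}
        p8, p9 = result.predictions[2008], result.predictions[2009]
        assert (p8.pbd.month, p8.pbd.day) == (p9.pbd.month, p9.pbd.day)

    def test_matches_single_season_run(self, step_season):
        result = predict_pbd_series(
            step_season.records, ModelParams(5.0, -20.0, 50.0), [2009]
        )
        direct = run_season(step_season, ModelParams(5.0, -20.0, 50.0))
        assert result.predictions[2009].pbd == direct.pbd

    def test_bad_season_flagged_not_silently_skipped(self):
        recs = [
            r
            for r in self._two_season_records()
            if not (dt.date(2010, 2, 1) <= r.date <= dt.date(2010, 2, 28))
        ]
        result = predict_pbd_series(recs, ModelParams(5.0, -20.0, 50.0), [2008, 2009])
        assert 2008 in result.predictions
        assert 2009 in result.failures and "gap" in result.failures[2009]

    def test_error_when_no_season_coverable(self, step_season):
        with pytest.raises(SeasonExtractionError):
            predict_pbd_series(step_season.records, ModelParams(5.0, -20.0, 50.0), [1900])
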