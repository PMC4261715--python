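"""Two-reservoir water balance: elementary fluxes, the extraction split,
the frost calendar and conservation over full runs."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vinewater.waterbalance import (
    CoverCropCalendar,
    SoilParams,
    SoilState,
    cover_crop_calendar,
    cover_crop_et,
    daily_step,
    partition_extraction,
    run_water_balance,
    soil_evaporation_step,
    stress_coefficient,
    vine_transpiration,
    vineyard_soil_evaporation,
)

EF_SOIL = SoilParams(ttsw=85.0, ttsw_1m=53.1, tew=26.9, rew=11.0, f_cc=0.84)


class TestSoilEvaporation:
    def test_depleted_layer_no_rain_no_evaporation(self):
        state = SoilState(50.0, 20.0, de=26.9, de_skin=11.0)
        e, *_ = soil_evaporation_step(state, EF_SOIL, 0.0, 3.0)
        assert e == 0.0

    def test_fresh_wet_layer_stage_one(self):
        state = SoilState(50.0, 20.0, de=0.0, de_skin=0.0)
        e, de, de_skin, k_r = soil_evaporation_step(state, EF_SOIL, 0.0, 3.0)
        assert k_r == 1.0 and e == pytest.approx(3.0)
        assert de == pytest.approx(3.0)

    def test_stage_two_reduction_coefficient(self):
        # dry skin, partially depleted layer: K_r from the Table-3 style
        # constants (26.9 - 19.0) / (26.9 - 11.0)
        state = SoilState(50.0, 20.0, de=19.0, de_skin=11.0)
        _, _, _, k_r = soil_evaporation_step(state, EF_SOIL, 0.0, 2.0)
        assert k_r == pytest.approx((26.9 - 19.0) / (26.9 - 11.0), abs=1e-12)

    def test_small_rain_restores_stage_one(self):
        state = SoilState(50.0, 20.0, de=19.0, de_skin=11.0)
        _, _, _, k_r = soil_evaporation_step(state, EF_SOIL, 3.0, 2.0)
        assert k_r == 1.0


class TestSimpleFluxes:
    @pytest.mark.parametrize("f_cc,expected", [(0.0, 2.0), (1.0, 0.0), (0.40, 1.2)])
    def test_vineyard_soil_evaporation(self, f_cc, expected):
        assert vineyard_soil_evaporation(2.0, f_cc) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "ftsw,p,expected", [(1.0, 0.4, 1.0), (0.2, 0.4, 0.5), (0.0, 0.4, 0.0), (0.4, 0.4, 1.0)]
    )
    def test_stress_coefficient(self, ftsw, p, expected):
        assert stress_coefficient(ftsw, p) == pytest.approx(expected)

    def test_stress_threshold_continuous(self):
        eps = 1e-9
        assert stress_coefficient(0.4 - eps, 0.4) == pytest.approx(1.0, abs=1e-8)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            stress_coefficient(0.5, 0.0)

    def test_vine_transpiration_values(self):
        t0, ta = vine_transpiration(0.3, 10.0, 1.0, 0.56)
        assert t0 == pytest.approx(3.0)
        assert ta == pytest.approx(1.68)
        assert vine_transpiration(0.3, 10.0, 0.0, 0.56)[1] == 0.0
        # coefficient 1 recovers the antecedent model behaviour
        assert vine_transpiration(0.3, 10.0, 1.0, 1.0)[1] == pytest.approx(3.0)

    @pytest.mark.parametrize(
        "f_g,k_s_cc,f_cc,frs_et0,e,expected",
        [
            (0.0, 1.0, 0.5, 2.0, 1.5, 0.75),  # dormant cover behaves as soil
            (1.0, 1.0, 0.75, 2.0, 0.0, 1.5),  # full cover transpires
            (1.0, 1.0, 0.0, 2.0, 1.0, 0.0),   # no cover crop, no flux
        ],
    )
    def test_cover_crop_et(self, f_g, k_s_cc, f_cc, frs_et0, e, expected):
        assert cover_crop_et(f_g, k_s_cc, frs_et0, e, f_cc) == pytest.approx(expected)


class TestExtractionPartition:
    def params(self, ttsw=100.0, ttsw_cc=40.0):
        return SoilParams(
            ttsw=ttsw, ttsw_1m=ttsw_cc / 0.5, tew=20.0, rew=8.0, f_cc=0.5
        )

    def test_stressed_case_follows_cover_crop_share(self):
        params = self.params()
        state = SoilState(tsw=30.0, tsw_cc=10.0)  # FTSW 0.3 -> k_s < 1
        k_s = stress_coefficient(0.3, 0.4)
        k_cc, k_r = partition_extraction(state, params, k_s)
        assert k_cc == pytest.approx(10.0 / (0.4 * 100.0))
        assert k_cc + k_r == pytest.approx(k_s)

    def test_both_wet_capacity_share(self):
        params = self.params()
        state = SoilState(tsw=90.0, tsw_cc=38.0)
        k_cc, k_r = partition_extraction(state, params, 1.0)
        assert k_cc == pytest.approx(40.0 / 100.0)
        assert k_r == pytest.approx(0.6)

    def test_cover_crop_dry_remaining_wet(self):
        params = self.params()
        state = SoilState(tsw=60.0, tsw_cc=8.0)  # FTSW_cc = 0.2 < 0.4
        k_cc, _ = partition_extraction(state, params, 1.0)
        assert k_cc == pytest.approx(8.0 / (0.4 * 100.0))

    def test_remaining_dry_cover_crop_wet(self):
        params = self.params()
        state = SoilState(tsw=58.0, tsw_cc=38.0)  # TSW_r 20, p*TTSW 40
        k_cc, k_r = partition_extraction(state, params, 1.0)
        assert k_cc == pytest.approx(1.0 - 20.0 / 40.0)
        assert k_r == pytest.approx(0.5)

    def test_split_always_sums_to_ks(self, rng):
        params = self.params()
        for _ in range(200):
            tsw = rng.uniform(0, 100)
            tsw_cc = rng.uniform(0, min(tsw, 40.0))
            state = SoilState(tsw=tsw, tsw_cc=tsw_cc)
            k_s = stress_coefficient(tsw / 100.0, 0.4)
            k_cc, k_r = partition_extraction(state, params, k_s)
            assert k_cc >= 0 and k_r >= 0
            assert k_cc + k_r == pytest.approx(k_s, abs=1e-12)


class TestCoverCropCalendar:
    def _tmin(self, frosts):
        dates = pd.date_range("2005-01-01", "2005-12-31", freq="D")
        tmin = np.full(len(dates), 5.0)
        for d in frosts:
            tmin[dates.get_loc(pd.Timestamp(d))] = -5.0
        return dates, tmin

    def test_season_start_from_last_spring_frost(self):
        dates, tmin = self._tmin(["2005-01-20", "2005-03-01"])
        cal = cover_crop_calendar(dates, tmin)
        assert cal.starts[2005] == date(2005, 2, 22)
        assert cal.dev_end[2005] == date(2005, 2, 22) + pd.Timedelta(days=80).to_pytimedelta()

    def test_late_spring_frost_ignored(self):
        dates, tmin = self._tmin(["2005-03-01", "2005-04-20"])
        cal = cover_crop_calendar(dates, tmin)
        assert cal.starts[2005] == date(2005, 2, 22)

    def test_frost_free_winter_defaults_and_flags(self):
        dates, tmin = self._tmin([])
        cal = cover_crop_calendar(dates, tmin)
        assert cal.starts[2005] == date(2005, 3, 1)
        assert 2005 in cal.flagged_years

    def test_autumn_frost_ends_season(self):
        dates, tmin = self._tmin(["2005-03-01", "2005-11-15"])
        cal = cover_crop_calendar(dates, tmin)
        assert cal.ends[2005] == date(2005, 11, 22)

    def test_ground_cover_stages(self):
        dates, tmin = self._tmin(["2005-03-01"])
        cal = cover_crop_calendar(dates, tmin)
        start = cal.starts[2005]
        assert cal.ground_cover(start + pd.Timedelta(days=10).to_pytimedelta()) == 0.0
        mid_dev = start + pd.Timedelta(days=30 + 25).to_pytimedelta()
        assert cal.ground_cover(mid_dev) == pytest.approx(0.5)
        assert cal.ground_cover(start + pd.Timedelta(days=100).to_pytimedelta()) == 1.0
        assert cal.ground_cover(date(2005, 12, 15)) == 0.0


class TestDailyStep:
    def test_nothing_in_nothing_out(self):
        state = SoilState(50.0, 20.0)
        flux, new = daily_step(state, EF_SOIL, 0.0, 0.0, 0.0, 0.0, 0.0)
        assert new.tsw == state.tsw and flux.et_a == 0.0

    def test_extreme_rain_clips_and_records_overflow(self):
        state = SoilState(80.0, 40.0)
        flux, new = daily_step(state, EF_SOIL, 500.0, 0.0, 0.0, 0.0, 0.0)
        assert new.tsw == pytest.approx(EF_SOIL.ttsw)
        assert flux.overflow == pytest.approx(500.0 - (EF_SOIL.ttsw - 80.0))

    def test_nan_weather_rejected(self):
        with pytest.raises(ValueError):
            daily_step(SoilState(50.0, 20.0), EF_SOIL, np.nan, 2.0, 0.3, 0.7, 0.0)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        st.floats(0, 60), st.floats(0, 8), st.floats(0, 0.6), st.floats(0, 1),
        st.floats(0, 85), st.floats(0, 44.6),
    )
    def test_daily_closure_identity(self, p, et0, f_r_v, f_g, tsw, tsw_cc):
        """TSW' - TSW = P - ET_a - overflow, exactly, from any state."""
        tsw_cc = min(tsw_cc, tsw, EF_SOIL.ttsw_cc)
        state = SoilState(tsw=tsw, tsw_cc=tsw_cc, de=5.0, de_skin=2.0)
        flux, new = daily_step(state, EF_SOIL, p, et0, f_r_v, 1 - f_r_v, f_g)
        assert new.tsw - tsw == pytest.approx(p - flux.et_a - flux.overflow, abs=1e-9)
        assert 0 <= new.tsw_cc <= new.tsw + 1e-12
        assert flux.et_a == pytest.approx(flux.t_a_v + flux.et_a_cc + flux.e_s, abs=1e-12)


class TestRunWaterBalance:
    def _run(self, soil, dates, p, et0, frv=0.3):
        n = len(dates)
        return run_water_balance(
            soil, dates, np.full(n, float(p)), np.full(n, float(et0)),
            np.full(n, frv), np.full(n, 1 - frv),
        )

    def test_gap_in_dates_rejected(self):
        dates = pd.DatetimeIndex(["2005-06-01", "2005-06-02", "2005-06-04"])
        with pytest.raises(ValueError, match="gaps"):
            self._run(EF_SOIL, dates, 1.0, 2.0)

    def test_constant_wet_keeps_reservoir_full(self):
        dates = pd.date_range("2005-05-01", periods=120, freq="D")
        daily = self._run(EF_SOIL, dates, p=8.0, et0=4.0)
        assert (daily["FTSW"] >= 0.99).all()

    def test_rainless_summer_monotone_drydown(self):
        dates = pd.date_range("2005-05-01", periods=150, freq="D")
        daily = self._run(EF_SOIL, dates, p=0.0, et0=5.0)
        assert (np.diff(daily["TSW"]) <= 1e-12).all()
        assert daily["overflow"].sum() == 0.0

    def test_degenerate_no_cover_crop_structure(self):
        """f_cc = 0 and k_c_v = 1 collapse to the vine + bare-soil model:
        no cover-crop fluxes anywhere."""
        soil = SoilParams(ttsw=85.0, ttsw_1m=53.1, tew=26.9, rew=11.0, f_cc=0.0, k_c_v=1.0)
        dates = pd.date_range("2005-05-01", periods=90, freq="D")
        daily = self._run(soil, dates, p=1.0, et0=4.0)
        assert (daily["ET_a_cc"] == 0.0).all()
        assert (daily["k_s_v_cc"] == 0.0).all()
        assert (daily["TSW_cc"] == 0.0).all()
        # with k_c_v = 1 and full water, actual equals potential transpiration
        assert daily["T_a_v"].iloc[0] == pytest.approx(daily["T_0_v"].iloc[0])

    def test_higher_kcv_never_wetter(self):
        """Raising the transpiration coefficient cannot increase soil water
        in a rain-free run, and lowers mean FTSW."""
        dates = pd.date_range("2005-05-01", periods=150, freq="D")
        runs = {}
        for kcv in (0.56, 1.0):
            soil = SoilParams(ttsw=85.0, ttsw_1m=53.1, tew=26.9, rew=11.0, f_cc=0.4, k_c_v=kcv)
            runs[kcv] = self._run(soil, dates, p=0.0, et0=5.0)
        assert (runs[1.0]["TSW"] <= runs[0.56]["TSW"] + 1e-12).all()
        assert runs[1.0]["FTSW"].mean() < runs[0.56]["FTSW"].mean()

    def test_winter_refill_reaches_capacity(self, weather_two_years):
        """Rainy winters with low demand refill the profile, matching the
        full-reservoir January initialisation."""
        w = weather_two_years
        et0 = np.where(w.index.month.isin([5, 6, 7, 8, 9]), 4.0, 0.5)
        daily = run_water_balance(
            EF_SOIL, w.index, w["precip"].to_numpy(), et0,
            np.full(len(w), 0.25), np.full(len(w), 0.75),
        )
        january_2 = daily[(daily.index.month == 2) & (daily.index.year == 2002)]
        assert january_2["FTSW"].max() > 0.95
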