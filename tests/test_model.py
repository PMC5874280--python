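"""Diurnal-curve identities: force-through, branch and midnight continuity."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from thermotime.model import (
    GENERIC_PARAMS,
    DayForcing,
    ModelParams,
    diurnal_matrix,
    hourly_temperature,
    simulate_series,
    sunset_temperature,
)
from thermotime.solar import SiteGeometry, SolarTimes


def symmetric_forcing(t_n=10.0, t_x=22.0, t_n_next=12.0, rise=6.0, sets=18.0):
    ts_prev = sunset_temperature(GENERIC_PARAMS, t_n, t_x, SolarTimes(rise, sets, 150))
    return DayForcing(
        t_n=t_n, t_x=t_x, t_n_next=t_n_next, t_s_prev=ts_prev,
        sunrise=rise, sunset=sets, sunset_prev=sets, sunrise_next=rise,
    )


params_strategy = st.builds(
    ModelParams,
    a=st.floats(-0.5, 4.0),
    b=st.floats(0.5, 6.0),
    c=st.floats(-0.5, 2.0),
)


class TestSunsetTemperature:
    def test_zero_lags_give_tn_at_sunset(self):
        p = ModelParams(a=0.0, b=3.0, c=0.0)
        assert sunset_temperature(p, 10, 20, SolarTimes(6, 18, 150)) == pytest.approx(
            10.0, abs=1e-12
        )

    def test_generic_params_match_hand_evaluation(self):
        # independent transcription of the sine expression at h = sunset
        p = GENERIC_PARAMS
        expected = 10 + (20 - 10) * math.sin(
            math.pi * (18 - 6 - p.c) / (18 - 6 + 2 * p.a - 2 * p.c)
        )
        got = sunset_temperature(p, 10, 20, SolarTimes(6, 18, 150))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_amplitude_day(self):
        assert sunset_temperature(
            GENERIC_PARAMS, 15, 15, SolarTimes(6, 18, 150)
        ) == pytest.approx(15.0, abs=1e-12)

    def test_degenerate_daylength_raises(self):
        with pytest.raises(ValueError):
            sunset_temperature(ModelParams(2, 3, 5), 10, 20, SolarTimes(10, 14, 1))


class TestForceThrough:
    @given(
        params=params_strategy,
        t_n=st.floats(-15, 15),
        amplitude=st.floats(0.1, 20),
        rise=st.floats(4.5, 8.0),
    )
    def test_curve_passes_exactly_through_tn_and_tx(self, params, t_n, amplitude, rise):
        f = symmetric_forcing(t_n=t_n, t_x=t_n + amplitude, rise=rise, sets=24 - rise)
        assert hourly_temperature(params, f, rise + params.c) == pytest.approx(
            t_n, abs=1e-9
        )
        peak_hour = (f.sunrise + f.sunset) / 2.0 + params.a
        assert hourly_temperature(params, f, peak_hour) == pytest.approx(
            t_n + amplitude, abs=1e-9
        )

    def test_branches_agree_at_boundaries(self):
        p = GENERIC_PARAMS
        f = symmetric_forcing()
        # at sunrise + c the morning night branch meets the sine at Tn
        left = hourly_temperature(p, f, f.sunrise + p.c - 1e-9)
        right = hourly_temperature(p, f, f.sunrise + p.c)
        assert left == pytest.approx(right, abs=1e-6)
        # at sunset the sine meets the evening night branch at T_S
        t_s = sunset_temperature(p, f.t_n, f.t_x, SolarTimes(f.sunrise, f.sunset, 1))
        assert hourly_temperature(p, f, f.sunset) == pytest.approx(t_s, abs=1e-12)
        assert hourly_temperature(p, f, f.sunset + 1e-9) == pytest.approx(
            t_s, abs=1e-6
        )

    def test_evening_branch_matches_independent_transcription(self):
        # closed form of the post-sunset branch written out symbol by symbol
        p = GENERIC_PARAMS
        f = symmetric_forcing(t_n=10, t_x=22, t_n_next=12)
        h = 23.0
        t_s = 10 + (22 - 10) * math.sin(
            math.pi * (18 - 6 - p.c) / (18 - 6 + 2 * p.a - 2 * p.c)
        )
        n2 = 6 - 18 + p.c + 24
        t = h - 18
        expected = 12 + (t_s - 12) * (
            math.exp(-p.b * t / n2) - (t / n2) * math.exp(-p.b)
        )
        assert hourly_temperature(p, f, h) == pytest.approx(expected, abs=1e-12)

    def test_literal_night_form_misses_tn(self):
        # the unfactored additive term does not force the curve through Tn
        p = GENERIC_PARAMS
        f = symmetric_forcing()
        h = f.sunrise + p.c - 1e-9
        forced = hourly_temperature(p, f, h, night_form="forced")
        literal = hourly_temperature(p, f, h, night_form="literal")
        assert forced == pytest.approx(f.t_n, abs=1e-6)
        assert abs(literal - f.t_n) > 0.01

    def test_monotone_response_to_tx(self):
        p = GENERIC_PARAMS
        lo = symmetric_forcing(t_x=20.0)
        hi = symmetric_forcing(t_x=25.0)
        for h in np.arange(7.5, 18.0, 0.5):
            assert hourly_temperature(p, hi, h) > hourly_temperature(p, lo, h)

    def test_rejects_out_of_range_hour(self):
        with pytest.raises(ValueError):
            hourly_temperature(GENERIC_PARAMS, symmetric_forcing(), 25.0)


class TestDiurnalMatrix:
    def test_midnight_continuity_across_days(self, rng):
        n = 30
        t_n = rng.normal(8, 4, n)
        t_x = t_n + rng.uniform(2, 12, n)
        rise = rng.uniform(4.5, 7.5, n)
        sets = 24 - rise
        end = diurnal_matrix(GENERIC_PARAMS, t_n, t_x, rise, sets, np.array([24.0]))
        start = diurnal_matrix(GENERIC_PARAMS, t_n, t_x, rise, sets, np.array([0.0]))
        assert np.abs(end[:-1, 0] - start[1:, 0]).max() < 1e-9

    def test_constant_forcing_is_periodic_after_first_day(self):
        n = 6
        t_n, t_x = np.full(n, 10.0), np.full(n, 20.0)
        rise, sets = np.full(n, 6.0), np.full(n, 18.0)
        temps = diurnal_matrix(GENERIC_PARAMS, t_n, t_x, rise, sets, np.arange(1.0, 25.0))
        # interior days are identical (first/last differ via edge surrogates)
        assert np.abs(temps[1] - temps[2]).max() < 1e-12
        assert np.abs(temps[2] - temps[3]).max() < 1e-12

    def test_dense_grid_extrema_at_forced_hours(self):
        n = 4
        t_n, t_x = np.full(n, 10.0), np.full(n, 20.0)
        rise, sets = np.full(n, 6.0), np.full(n, 18.0)
        dense = np.arange(0, 24, 1 / 60.0)
        temps = diurnal_matrix(GENERIC_PARAMS, t_n, t_x, rise, sets, dense)
        day = temps[2]
        assert day.min() == pytest.approx(10.0, abs=0.01)
        assert day.max() == pytest.approx(20.0, abs=0.01)
        assert dense[day.argmin()] == pytest.approx(6.0 + GENERIC_PARAMS.c, abs=0.02)
        assert dense[day.argmax()] == pytest.approx(12.0 + GENERIC_PARAMS.a, abs=0.02)

    def test_nan_minima_propagate_not_raise(self):
        t_n = np.array([10.0, np.nan, 9.0])
        t_x = np.array([20.0, np.nan, 19.0])
        temps = diurnal_matrix(
            GENERIC_PARAMS, t_n, t_x, np.full(3, 6.0), np.full(3, 18.0),
            np.arange(1.0, 25.0),
        )
        assert np.isnan(temps[1]).all()
        assert np.isfinite(temps[2, 12])

    def test_inverted_extremes_raise(self):
        with pytest.raises(ValueError):
            diurnal_matrix(
                GENERIC_PARAMS, np.array([20.0, 10.0]), np.array([10.0, 20.0]),
                np.full(2, 6.0), np.full(2, 18.0), np.arange(1.0, 25.0),
            )


class TestSimulateSeries:
    GEOM = SiteGeometry(latitude=47.0)

    def test_flat_input_gives_flat_output(self):
        daily = pd.DataFrame(
            {"date": pd.date_range("2001-03-01", periods=3), "tmin": 12.0, "tmax": 12.0}
        )
        out = simulate_series(GENERIC_PARAMS, daily, self.GEOM)
        assert np.allclose(out["temperature"], 12.0)

    def test_output_shape_flags_and_timestamps(self, constant_daily):
        out = simulate_series(GENERIC_PARAMS, constant_daily, self.GEOM)
        assert len(out) == 5 * 24
        assert (out.loc[:23, "flag"] == "edge").all()
        assert (out.iloc[24:-24]["flag"] == "").all()
        first = pd.to_datetime(out["datetime"].iloc[0])
        assert first == pd.Timestamp("2001-06-01 01:00:00")

    def test_hour_grid_zero_based(self, constant_daily):
        out = simulate_series(GENERIC_PARAMS, constant_daily, self.GEOM, hour_grid="0-23")
        assert pd.to_datetime(out["datetime"].iloc[0]) == pd.Timestamp("2001-06-01")

    def test_gap_in_dates_raises(self):
        daily = pd.DataFrame(
            {
                "date": ["2001-06-01", "2001-06-02", "2001-06-04"],
                "tmin": 10.0,
                "tmax": 20.0,
            }
        )
        with pytest.raises(ValueError, match="gaps"):
            simulate_series(GENERIC_PARAMS, daily, self.GEOM)

    def test_single_day_raises(self):
        daily = pd.DataFrame({"date": ["2001-06-01"], "tmin": [10.0], "tmax": [20.0]})
        with pytest.raises(ValueError):
            simulate_series(GENERIC_PARAMS, daily, self.GEOM)
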