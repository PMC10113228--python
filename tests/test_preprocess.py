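"""Preprocessing: aggregation, smoothing, response, APT, sun time, frame."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from batemerge.config import SiteConfig, TrueModel
from batemerge.errors import DataError
from batemerge.preprocess import (
    aggregate_hourly,
    assemble_model_frame,
    build_response,
    compute_apt,
    compute_sun_time,
    smooth_counts,
)
from batemerge.simulate import simulate_activity
from batemerge.weather import simulate_weather


class TestAggregateHourly:
    def test_events_in_one_hour_bin(self):
        ev = pd.DataFrame({
            "timestamp": pd.to_datetime(["2016-02-01 02:10:00",
                                         "2016-02-01 02:50:00",
                                         "2016-02-01 02:59:59"]),
            "site_id": "s", "species": "sp", "direction": "in",
        })
        out = aggregate_hourly(ev)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["hour"] == pd.Timestamp("2016-02-01 02:00:00")
        assert row["n_in"] == 3 and row["n_out"] == 0

    def test_empty_input(self):
        out = aggregate_hourly(pd.DataFrame(
            columns=["timestamp", "site_id", "species", "direction"]))
        assert len(out) == 0

    def test_zero_fill_over_span(self):
        ev = pd.DataFrame({
            "timestamp": pd.to_datetime(["2016-02-01 02:30:00",
                                         "2016-02-01 05:30:00"]),
            "site_id": "s", "species": "sp", "direction": ["in", "out"],
        })
        out = aggregate_hourly(ev)
        assert len(out) == 4  # hours 02..05 with zeros in between
        assert out["n_in"].sum() == 1 and out["n_out"].sum() == 1

    def test_invalid_direction_rejected(self):
        ev = pd.DataFrame({
            "timestamp": pd.to_datetime(["2016-02-01 02:10:00"] * 2),
            "site_id": "s", "species": "sp",
            "direction": ["in", "sideways"],
        })
        out = aggregate_hourly(ev)
        assert out["n_in"].sum() + out["n_out"].sum() == 1

    def test_conservation_on_simulated_events(self, two_sites):
        truth = TrueModel(alpha=np.log(3.0), site_effects={}, beta={})
        wx = simulate_weather(two_sites, "2016-01-01", 15, seed=8)
        ev = simulate_activity(truth, wx, two_sites, seed=8, species="sp")
        out = aggregate_hourly(ev)
        assert out["n_in"].sum() + out["n_out"].sum() == len(ev)
        per_site = out.groupby("site_id")[["n_in", "n_out"]].sum().sum(axis=1)
        for sid, n in ev.groupby("site_id").size().items():
            assert per_site[sid] == n


class TestSmoothCounts:
    def test_worked_example_with_shrunken_edges(self):
        out = smooth_counts([0, 3, 6, 3, 0])
        assert np.allclose(out, [1.5, 3.0, 4.0, 3.0, 1.5])

    def test_preserves_constants(self):
        assert np.allclose(smooth_counts(np.full(24, 7.0)), 7.0)

    def test_empty(self):
        assert len(smooth_counts([])) == 0

    def test_length_preserved(self):
        assert len(smooth_counts(np.arange(10))) == 10

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 100), min_size=3, max_size=50))
    def test_interior_matches_convolution_oracle(self, xs):
        """Interior values equal the brute-force (1/3,1/3,1/3) convolution."""
        x = np.asarray(xs)
        out = smooth_counts(x)
        oracle = np.convolve(x, np.ones(3) / 3.0, mode="valid")
        assert np.allclose(out[1:-1], oracle, rtol=1e-12, atol=1e-9)


class TestBuildResponse:
    @pytest.mark.parametrize("s_in,s_out,expected", [
        (2.3, 1.7, 1.7), (0.0, 5.0, 0.0), (4.2, 4.2, 4.2),
    ])
    def test_minimum_of_smoothed_aggregates(self, s_in, s_out, expected):
        assert build_response(s_in, s_out) == expected


class TestComputeApt:
    def test_central_difference(self):
        apt = compute_apt([1000.0, 1005.0, 1010.0])
        assert np.isnan(apt[0]) and np.isnan(apt[-1])
        assert apt[1] == 10.0

    def test_constant_pressure_zero_trend(self):
        apt = compute_apt(np.full(10, 1013.0))
        assert np.allclose(apt[1:-1], 0.0)

    def test_antisymmetry_under_reversal(self):
        ap = np.array([1000.0, 1003.0, 1001.0, 1008.0, 1002.0])
        fwd = compute_apt(ap)[1:-1]
        rev = compute_apt(ap[::-1])[1:-1]
        assert np.allclose(fwd, -rev[::-1])


class TestSunTime:
    @pytest.fixture()
    def anchors(self):
        # sunrise 06:00, sunset 18:00 on consecutive days
        days = pd.date_range("2016-03-20", periods=3)
        return pd.DataFrame({
            "sunrise": days + pd.Timedelta(hours=6),
            "sunset": days + pd.Timedelta(hours=18),
        })

    def test_sunset_is_zero(self, anchors):
        st_ = compute_sun_time(["2016-03-21 18:00"], anchors)
        assert st_[0] == pytest.approx(0.0, abs=1e-9)

    def test_midnight_is_mid_night(self, anchors):
        st_ = compute_sun_time(["2016-03-21 00:00"], anchors)
        assert st_[0] == pytest.approx(0.5, abs=1e-9)

    def test_noon_is_mid_day(self, anchors):
        st_ = compute_sun_time(["2016-03-21 12:00"], anchors)
        assert st_[0] == pytest.approx(-0.5, abs=1e-9)

    def test_sunrise_seam(self, anchors):
        before = compute_sun_time(["2016-03-21 05:59:59"], anchors)[0]
        after = compute_sun_time(["2016-03-21 06:00:01"], anchors)[0]
        assert before == pytest.approx(1.0, abs=1e-3)
        assert after == pytest.approx(-1.0, abs=1e-3)

    def test_outside_anchor_range_is_missing(self, anchors):
        st_ = compute_sun_time(["2010-01-01 12:00"], anchors)
        assert np.isnan(st_[0])


class TestAssembleModelFrame:
    @pytest.fixture(scope="class")
    def parts(self, two_sites):
        truth = TrueModel(alpha=np.log(2.0), site_effects={}, beta={})
        wx = simulate_weather(two_sites, "2016-05-10", 10, seed=2)
        # days 130..139: straddles the day-136 cutoff
        ev = simulate_activity(truth, wx, two_sites, seed=2, species="sp",
                               day_max=366)
        hourly = aggregate_hourly(ev)
        return hourly, wx

    def test_rows_beyond_day_max_excluded(self, parts, two_sites):
        hourly, wx = parts
        frame = assemble_model_frame(hourly, wx, two_sites)
        assert frame["DOY"].max() <= 136
        doy_in_events = pd.to_datetime(hourly["hour"]).dt.dayofyear - 1
        assert doy_in_events.max() > 136  # the cutoff actually bit

    def test_no_missing_values_and_st_in_range(self, parts, two_sites):
        hourly, wx = parts
        frame = assemble_model_frame(hourly, wx, two_sites)
        assert not frame.drop(columns=["species"]).isna().any().any()
        assert frame["ST"].between(-1, 1).all()

    def test_row_count_arithmetic(self, two_sites):
        """Full coverage: rows = sites x hours - APT boundary losses -
        beyond-day-max hours."""
        truth = TrueModel(alpha=np.log(2.0), site_effects={}, beta={})
        wx = simulate_weather(two_sites, "2016-01-01", 10, seed=3)
        ev = simulate_activity(truth, wx, two_sites, seed=3, species="sp")
        hourly = aggregate_hourly(
            ev, span={s.site_id: (wx.timestamp.min(), wx.timestamp.max())
                      for s in two_sites})
        frame = assemble_model_frame(hourly, wx, two_sites)
        # 2 sites x 240 h, minus first+last hour per site (APT undefined)
        assert len(frame) == 2 * 240 - 2 * 2

    def test_unknown_site_is_hard_error(self, parts, two_sites):
        hourly, wx = parts
        bad = hourly.copy()
        bad.loc[bad.index[:5], "site_id"] = "atlantis"
        with pytest.raises(DataError, match="atlantis"):
            assemble_model_frame(bad, wx, two_sites)

    def test_drop_accounting_balances(self, parts, two_sites):
        hourly, wx = parts
        frame = assemble_model_frame(hourly, wx, two_sites)
        drops = frame.attrs["drops"]
        assert drops["input_rows"] == (drops["output_rows"]
                                       + drops["doy_beyond_max"]
                                       + drops["missing_covariate"])
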