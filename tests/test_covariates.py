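"""Covariate construction: arcsinh, trailing moving averages, policy
dummies, and the weekday vs. weekend/holiday calendar split."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stayhome.covariates import (
    PolicyCalendar,
    arcsinh,
    build_dummies,
    build_epi_panel,
    split_weekday,
    trailing_ma7,
)


class TestArcsinh:
    def test_values(self):
        assert arcsinh(0.0) == 0.0
        # ln(1 + sqrt(2))
        assert arcsinh(1.0) == pytest.approx(0.881374, abs=1e-6)

    @given(st.floats(min_value=0, max_value=1e6))
    @settings(deadline=None, max_examples=50)
    def test_odd_function(self, x):
        assert arcsinh(-x) == pytest.approx(-arcsinh(x), rel=1e-12)

    @given(st.floats(min_value=0, max_value=1e6))
    @settings(deadline=None, max_examples=50)
    def test_log_envelope(self, x):
        assert arcsinh(x) <= np.log(2 * x + 1) + 1


class TestTrailingMA:
    def test_constant_series(self):
        s = pd.Series(3.0, index=pd.date_range("2020-01-01", periods=20))
        assert (trailing_ma7(s) == 3.0).all()

    def test_single_spike(self):
        s = pd.Series(
            [0, 0, 0, 0, 0, 0, 7.0], index=pd.date_range("2020-01-01", periods=7)
        )
        assert trailing_ma7(s).iloc[-1] == pytest.approx(1.0)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(7)
        s = pd.Series(
            rng.poisson(5, size=60).astype(float),
            index=pd.date_range("2020-01-01", periods=60),
        )
        got = trailing_ma7(s)
        for t in range(len(s)):
            window = s.iloc[max(0, t - 6): t + 1]
            assert got.iloc[t] == pytest.approx(window.mean(), abs=1e-12)

    def test_rejects_calendar_gaps(self):
        idx = pd.DatetimeIndex(["2020-01-01", "2020-01-02", "2020-01-04"])
        with pytest.raises(ValueError, match="gap"):
            trailing_ma7(pd.Series([1.0, 2.0, 3.0], index=idx))


class TestPolicyDummies:
    def _index(self, start="2020-04-01", end="2020-06-05"):
        dates = pd.date_range(start, end)
        return pd.DataFrame({"prefecture": "Tokyo", "date": dates})

    def test_emergency_active_day_after_declaration_through_lifting(self):
        """Declared Apr 7 and lifted May 25: the dummy is 1 on Apr 8 and
        May 25, 0 on Apr 7 and May 26."""
        cal = PolicyCalendar(school_closure={"Tokyo": []})
        cal.add_emergency("Tokyo", "2020-04-07", "2020-05-25")
        d = build_dummies(cal, self._index()).set_index("date")["emergency"]
        assert d[pd.Timestamp("2020-04-07")] == 0
        assert d[pd.Timestamp("2020-04-08")] == 1
        assert d[pd.Timestamp("2020-05-25")] == 1
        assert d[pd.Timestamp("2020-05-26")] == 0

    def test_school_closure_start_inclusive_reopening_exclusive(self):
        cal = PolicyCalendar(emergency={"Tokyo": []})
        cal.add_school_closure("Tokyo", "2020-04-02", "2020-05-11")
        d = build_dummies(cal, self._index()).set_index("date")["school_closure"]
        assert d[pd.Timestamp("2020-04-02")] == 1
        assert d[pd.Timestamp("2020-05-10")] == 1
        assert d[pd.Timestamp("2020-05-11")] == 0

    def test_no_intervals_means_all_zero(self):
        cal = PolicyCalendar(emergency={"Tokyo": []}, school_closure={"Tokyo": []})
        d = build_dummies(cal, self._index())
        assert d["emergency"].sum() == 0
        assert d["school_closure"].sum() == 0

    def test_dummy_sum_equals_interval_length_and_rebuild_idempotent(self):
        cal = PolicyCalendar(school_closure={"Tokyo": []})
        cal.add_emergency("Tokyo", "2020-04-07", "2020-05-25")
        idx = self._index()
        d1 = build_dummies(cal, idx)
        d2 = build_dummies(cal, idx)
        pd.testing.assert_frame_equal(d1, d2)
        # Apr 8 .. May 25 inclusive = 48 days
        assert d1["emergency"].sum() == 48

    def test_short_gap_reclosure_merges(self):
        """A brief reopening between two closures is not a reopening; the
        merged interval must match a brute-force day-set with the gap
        bridged."""
        cal = PolicyCalendar(emergency={"Tokyo": []})
        cal.add_school_closure("Tokyo", "2020-04-02", "2020-04-20")
        cal.add_school_closure("Tokyo", "2020-04-23", "2020-05-11")
        idx = self._index()
        merged = build_dummies(cal, idx, merge_gap=3).set_index("date")[
            "school_closure"
        ]
        days = set()
        for s, e in [("2020-04-02", "2020-04-19"), ("2020-04-23", "2020-05-10")]:
            days |= set(pd.date_range(s, e))
        days |= set(pd.date_range("2020-04-20", "2020-04-22"))  # bridged gap
        expected = idx["date"].isin(days).astype(float).to_numpy()
        assert (merged.to_numpy() == expected).all()
        unmerged = build_dummies(cal, idx, merge_gap=0).set_index("date")[
            "school_closure"
        ]
        assert unmerged[pd.Timestamp("2020-04-21")] == 0

    def test_unknown_prefecture_errors(self):
        cal = PolicyCalendar(emergency={"Tokyo": []}, school_closure={"Tokyo": []})
        idx = pd.DataFrame(
            {"prefecture": "Osaka", "date": pd.date_range("2020-04-01", periods=3)}
        )
        with pytest.raises(KeyError, match="Osaka"):
            build_dummies(cal, idx)


class TestWeekdaySplit:
    def test_saturday_and_midweek_holiday(self, holidays):
        panel = pd.DataFrame(
            {
                "date": [
                    pd.Timestamp("2020-02-15"),  # Saturday
                    pd.Timestamp("2020-11-03"),  # Culture Day, a Tuesday
                    pd.Timestamp("2020-02-17"),  # plain Monday
                ]
            }
        )
        weekday, weekend = split_weekday(panel, holidays)
        assert list(weekend["date"]) == [
            pd.Timestamp("2020-02-15"),
            pd.Timestamp("2020-11-03"),
        ]
        assert list(weekday["date"]) == [pd.Timestamp("2020-02-17")]

    def test_study_window_partitions_211_104(self, holidays):
        """Jan 6 - Nov 15 2020 splits into 211 weekdays and 104
        weekend/holiday days with the shipped national-holiday list."""
        panel = pd.DataFrame({"date": pd.date_range("2020-01-06", "2020-11-15")})
        weekday, weekend = split_weekday(panel, holidays)
        assert len(weekday) == 211
        assert len(weekend) == 104
        assert len(weekday) + len(weekend) == 315


class TestEpiPanel:
    def test_transform_invariants(self):
        rng = np.random.default_rng(3)
        dates = pd.date_range("2020-01-06", periods=40)
        epi = pd.DataFrame(
            {
                "prefecture": "P0",
                "date": dates,
                "new_infections": np.r_[np.zeros(10), rng.poisson(6, 30)].astype(int),
                "deaths": np.zeros(40, dtype=int),
            }
        )
        out = build_epi_panel(epi)
        assert ((out["m"] == 0) == (out["ma7_infections"] == 0)).all()
        assert (out["n"] == 0).all()
        # m increases with the smoothed count
        srt = out.sort_values("ma7_infections")
        assert (np.diff(srt["m"]) >= -1e-15).all()

    def test_rejects_negative_counts(self):
        epi = pd.DataFrame(
            {
                "prefecture": "P0",
                "date": pd.date_range("2020-01-06", periods=2),
                "new_infections": [1, -2],
                "deaths": [0, 0],
            }
        )
        with pytest.raises(ValueError, match="nonnegative"):
            build_epi_panel(epi)
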