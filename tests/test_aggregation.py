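"""Score aggregation, weekly rhythm, regional drop correlation, event trace."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from moodpulse import CohortConfig, GeneratorParams, aggregation, simulate_cohort


def _scores(rows):
    return pd.DataFrame(rows, columns=["user_id", "frame_start", "score"])


class TestNationwideScore:
    def test_constant_user_constant_series(self):
        frames = pd.date_range("2020-01-06", periods=16, freq="3h")
        s = _scores([(0, f, 2.0) for f in frames])
        out = aggregation.nationwide_score(s, "daily")
        assert (out["value"] == 2.0).all()
        assert (out["n_users"] == 1).all()

    def test_two_users_daily_mean(self):
        frames = pd.date_range("2020-01-06", periods=8, freq="3h")
        s = _scores([(0, f, 1.0) for f in frames] + [(1, f, 3.0) for f in frames])
        out = aggregation.nationwide_score(s, "daily")
        assert out["value"].iloc[0] == pytest.approx(2.0)
        assert out["n_users"].iloc[0] == 2

    def test_inactive_user_excluded_from_day(self):
        day1 = pd.date_range("2020-01-06", periods=8, freq="3h")
        day2 = pd.date_range("2020-01-07", periods=8, freq="3h")
        s = _scores([(0, f, 1.0) for f in list(day1) + list(day2)]
                    + [(1, f, 5.0) for f in day1])  # user 1 silent on day 2
        out = aggregation.nationwide_score(s, "daily")
        assert out["n_users"].tolist() == [2, 1]
        assert out["value"].iloc[1] == pytest.approx(1.0)

    def test_user_mean_vs_pooled_weighting(self):
        # user 1 has 4x the frames of user 0: pooled tilts toward user 1
        f = pd.date_range("2020-01-06", periods=8, freq="3h")
        s = _scores([(0, f[0], 0.0)] + [(1, fr, 4.0) for fr in f[:4]])
        um = aggregation.nationwide_score(s, "daily", method="user_mean")
        pooled = aggregation.nationwide_score(s, "daily", method="pooled")
        assert um["value"].iloc[0] == pytest.approx(2.0)
        assert pooled["value"].iloc[0] == pytest.approx(16.0 / 5)

    def test_value_within_user_mean_envelope(self):
        rng = np.random.default_rng(0)
        frames = pd.date_range("2020-01-06", periods=8, freq="3h")
        rows = [(u, f, rng.normal()) for u in range(7) for f in frames]
        s = _scores(rows)
        out = aggregation.nationwide_score(s, "daily")
        per_user = s.groupby("user_id")["score"].mean()
        assert per_user.min() <= out["value"].iloc[0] <= per_user.max()

    def test_empty_input_empty_series(self):
        out = aggregation.nationwide_score(_scores([]), "daily")
        assert len(out) == 0


class TestWeeklyRhythm:
    def test_strictly_increasing_all_up(self):
        idx = pd.date_range("2020-01-06", periods=28, freq="D")
        table = aggregation.weekly_rhythm(pd.Series(np.arange(28.0), index=idx))
        observed = table.dropna()
        assert (observed["pct_up"] == 100.0).all()

    def test_rows_sum_to_100(self):
        rng = np.random.default_rng(1)
        idx = pd.date_range("2020-01-06", periods=60, freq="D")
        table = aggregation.weekly_rhythm(pd.Series(rng.normal(size=60), index=idx))
        ok = table.dropna()
        np.testing.assert_allclose(ok["pct_up"] + ok["pct_down"], 100.0)

    def test_holiday_comparisons_excluded(self):
        idx = pd.date_range("2020-01-06", periods=14, freq="D")  # two Mon-Sun weeks
        s = pd.Series(np.arange(14.0), index=idx)
        plain = aggregation.weekly_rhythm(s)
        # first Monday has no predecessor: only the second Monday counts
        assert plain.loc["Monday", "n"] == 1
        # a holiday Sunday removes both its own and the following Monday's comparison
        table = aggregation.weekly_rhythm(s, ["2020-01-12"])
        assert table.loc["Monday", "n"] == 0
        assert table.loc["Sunday", "n"] == 1

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="2 days"):
            aggregation.weekly_rhythm(
                pd.Series([1.0], index=pd.DatetimeIndex(["2020-01-06"])))

    def test_synthetic_cohort_monday_down_weekend_up(self):
        b = simulate_cohort(CohortConfig(n_users=200, n_days=10 * 7,
                                         start_date=dt.date(2019, 7, 1), seed=2))
        daily = b.daily_population_mood()
        table = aggregation.weekly_rhythm(daily)
        assert table.loc["Monday", "pct_up"] < 10.0
        assert table.loc["Saturday", "pct_up"] > 80.0
        assert table.loc["Sunday", "pct_up"] > 80.0


class TestRegionDrop:
    def _scores(self, drops, baseline=1.0):
        target = pd.Timestamp("2020-04-12")
        base_days = pd.date_range("2020-01-01", "2020-01-03")
        rows = []
        for i, d in enumerate(drops):
            region = f"R{i:02d}"
            for day in base_days:
                rows.append({"index": day, "region": region, "value": baseline})
            rows.append({"index": target, "region": region, "value": baseline + d})
        return pd.DataFrame(rows).set_index("index")

    def _cases(self, cases):
        return pd.DataFrame({"region": [f"R{i:02d}" for i in range(len(cases))],
                             "new_cases": cases})

    def test_zero_variance_reported_undefined(self):
        scores = self._scores([0.5, 0.5, 0.5])
        res = aggregation.region_drop_correlation(
            scores, self._cases([10, 20, 30]), "2020-04-12",
            ("2020-01-01", "2020-01-03"))
        assert np.isnan(res.pearson_r)

    def test_exact_linear_gives_minus_one(self):
        cases = [0, 100, 200, 300]
        drops = [-0.001 * c for c in cases]
        res = aggregation.region_drop_correlation(
            self._scores(drops), self._cases(cases), "2020-04-12",
            ("2020-01-01", "2020-01-03"))
        assert res.pearson_r == pytest.approx(-1.0)

    def test_missing_region_excluded_with_warning(self):
        scores = self._scores([-0.1, -0.2, -0.3, -0.4])
        cases = self._cases([5, 10, 15, 20]).iloc[:3]
        with pytest.warns(UserWarning, match="missing case counts"):
            res = aggregation.region_drop_correlation(
                scores, cases, "2020-04-12", ("2020-01-01", "2020-01-03"))
        assert len(res.table) == 3

    def test_correlation_recovery_47_regions(self):
        # bivariate-normal (drop, cases) with generating correlation -0.43
        target_r = -0.43
        rs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            cov = [[1.0, target_r], [target_r, 1.0]]
            z = rng.multivariate_normal([0, 0], cov, size=47)
            drops = 0.2 * z[:, 0]
            cases = np.maximum(0, 500 + 200 * z[:, 1]).astype(int)
            scores = self._scores(drops)
            res = aggregation.region_drop_correlation(
                scores, self._cases(cases), "2020-04-12",
                ("2020-01-01", "2020-01-03"))
            rs.append(res.pearson_r)
        assert np.mean(rs) == pytest.approx(target_r, abs=0.1)


class TestEventTrace:
    def test_identity_trace_is_one(self):
        week = pd.Series(np.linspace(1, 2, 56))
        out = aggregation.event_trace(week, week, week)
        np.testing.assert_allclose(out["value"], 1.0)

    def test_shock_depresses_trace_after_onset(self):
        # three aligned synthetic weeks; shared shock only in the target week
        start = dt.date(2020, 9, 14)  # Monday; shock Sunday week 2, 08:30
        shock_time = dt.datetime(2020, 9, 27, 8, 30)
        cfg = CohortConfig(n_users=300, n_days=21, start_date=start, seed=8)
        shocked = simulate_cohort(cfg, GeneratorParams(
            ar_sd=0.05, noise_sd=0.05, baseline_sd=0.1,
            shocks=((shock_time, -2.0, 14.0),)))  # ends before midnight
        pop = shocked.population_mood() + 3.0  # keep reference mean away from 0
        w1, w2, w3 = (pop.iloc[i * 56:(i + 1) * 56].reset_index(drop=True)
                      for i in range(3))
        out = aggregation.event_trace(w2, w1, w3)
        shock_slot = 6 * 8 + 2  # Sunday, frame [06:00, 09:00)
        assert out["value"].iloc[shock_slot + 1: shock_slot + 5].max() < 0.9
        np.testing.assert_allclose(out["value"].iloc[:shock_slot], 1.0, atol=0.1)

    def test_near_zero_reference_flagged(self):
        target = pd.Series([1.0, 1.0])
        ref = pd.Series([1.0, 0.0])
        out = aggregation.event_trace(target, ref, -ref)
        assert not out["usable"].any()
        assert out["value"].isna().all()

    def test_difference_variant_shift_invariant(self):
        rng = np.random.default_rng(4)
        t, r1, r2 = (pd.Series(rng.normal(size=56)) for _ in range(3))
        base = aggregation.event_trace(t, r1, r2, mode="difference")
        shifted = aggregation.event_trace(t + 5, r1 + 5, r2 + 5, mode="difference")
        np.testing.assert_allclose(base["value"], shifted["value"], atol=1e-12)

    def test_misaligned_weeks_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            aggregation.event_trace(pd.Series([1.0]), pd.Series([1.0, 2.0]),
                                    pd.Series([1.0, 2.0]))
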