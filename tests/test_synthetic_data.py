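"""Generator correctness: sizes, determinism, couplings, and rhythm structure."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal
from scipy.signal import find_peaks
from scipy.stats import spearmanr

from moodpulse import (
    AdSpec,
    CohortConfig,
    EpidemicParams,
    GeneratorParams,
    coupled_logistic,
    simulate_ad_logs,
    simulate_cohort,
    simulate_epidemic,
)

def make_scores(n_users=20, n_days=3, seed=0, start="2020-01-06"):
    """Per-(user, frame) score table with N(0,1) scores."""
    r = np.random.default_rng(seed)
    frames = pd.date_range(start, periods=n_days * 8, freq="3h")
    return pd.DataFrame({
        "user_id": np.repeat(np.arange(n_users), len(frames)),
        "frame_start": np.tile(frames, n_users),
        "score": r.normal(size=n_users * len(frames)),
    })


class TestCohort:
    def test_size_bookkeeping(self):
        b = simulate_cohort(CohortConfig(n_users=2, n_days=1, seed=1))
        assert b.latent.shape == (2, 8)
        assert len(b.annotations) <= 12  # at most 6 prompts per user per day
        assert b.annotations["likert"].between(1, 7).all()

    def test_full_missingness_leaves_other_streams_intact(self):
        b = simulate_cohort(CohortConfig(n_users=5, n_days=3, seed=2),
                            GeneratorParams(annotation_missingness=1.0))
        assert len(b.annotations) == 0
        assert len(b.sensor_frames) == 5 * 3 * 8
        assert len(b.queries) > 0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="n_users"):
            CohortConfig(n_users=0, n_days=1)
        with pytest.raises(ValueError, match="annotation_missingness"):
            GeneratorParams(annotation_missingness=1.5)

    def test_determinism_same_seed(self):
        cfg = CohortConfig(n_users=6, n_days=4, seed=42)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        np.testing.assert_array_equal(a.latent, b.latent)
        assert_frame_equal(a.annotations, b.annotations)
        assert_frame_equal(a.sensor_frames, b.sensor_frames)
        assert_frame_equal(a.queries, b.queries)

    def test_zero_coupling_decorrelates_sensors(self):
        # ~10,000 frames; with coupling 0 every feature should be mood-blind
        b = simulate_cohort(CohortConfig(n_users=50, n_days=25, seed=7),
                            GeneratorParams(sensor_coupling=0.0))
        mood = b.latent.ravel()
        for col in ("activity_intensity", "screen_on_count", "battery_drain"):
            r = np.corrcoef(mood, b.sensor_frames[col])[0, 1]
            assert abs(r) < 0.05, col

    def test_likert_tracks_latent(self, small_bundle):
        b = small_bundle
        ann = b.annotations
        slots = ((pd.to_datetime(ann["timestamp"]) - b.slot_starts[0])
                 .dt.total_seconds() // (3 * 3600)).astype(int)
        latent = b.latent[ann["user_id"].to_numpy(), slots.to_numpy()]
        rho = spearmanr(latent, ann["likert"]).statistic
        assert rho > 0.8

    def test_population_weekly_rhythm(self):
        # Monday's population mean below Sunday's in >= 90% of weeks
        b = simulate_cohort(CohortConfig(n_users=200, n_days=12 * 7,
                                         start_date=dt.date(2019, 7, 1), seed=3))
        daily = b.daily_population_mood()
        by_day = daily.groupby(daily.index.dayofweek)
        mondays = by_day.get_group(0).to_numpy()
        sundays = by_day.get_group(6).to_numpy()
        weeks = min(len(mondays) - 1, len(sundays))
        # Monday of week w+1 vs Sunday of week w (the preceding day)
        frac = np.mean(mondays[1:weeks + 1] < sundays[:weeks])
        assert frac >= 0.9

    def test_shared_shock_lowers_latent(self):
        when = dt.datetime(2019, 7, 3, 6, 0)
        base = simulate_cohort(CohortConfig(n_users=30, n_days=7, seed=9))
        shocked = simulate_cohort(
            CohortConfig(n_users=30, n_days=7, seed=9),
            GeneratorParams(shocks=((when, -2.0, 24.0),)))
        diff = shocked.latent.mean(axis=0) - base.latent.mean(axis=0)
        hit = np.asarray((shocked.slot_starts >= when)
                         & (shocked.slot_starts < when + dt.timedelta(hours=24)))
        assert np.allclose(diff[hit], -2.0)
        assert np.allclose(diff[~hit], 0.0)


class TestEpidemic:
    def test_zero_amplitude_is_constant_baseline(self):
        epi = simulate_epidemic(
            30, EpidemicParams(baseline=10, waves=((15, 5, 0),), poisson_noise=False))
        assert (epi["new_cases"] == 10).all()

    def test_two_waves_two_peaks(self):
        epi = simulate_epidemic(
            180, EpidemicParams(baseline=2, waves=((50, 10, 500), (130, 10, 800))),
            seed=1)
        smoothed = epi["new_cases"].rolling(7).mean().dropna().to_numpy()
        peaks, _ = find_peaks(smoothed, prominence=0.2 * smoothed.max())
        assert len(peaks) == 2

    def test_negative_coupling_gives_negative_lagged_xcorr(self):
        rng = np.random.default_rng(0)
        mood = np.sin(np.arange(240) / 12.0) + 0.1 * rng.normal(size=240)
        epi = simulate_epidemic(
            240, EpidemicParams(baseline=200, waves=(), mood_coupling=-0.8,
                                mood_lag=7),
            mood=mood, seed=2)
        lagged_mood = mood[:-7]
        cases = epi["new_cases"].to_numpy()[7:]
        assert np.corrcoef(lagged_mood, cases)[0, 1] < -0.3

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            EpidemicParams(baseline=-1)
        with pytest.raises(ValueError):
            simulate_epidemic(0)


class TestAdLogs:
    def test_mood_blind_ads_show_no_score_gap(self):
        scores = make_scores(n_users=500, n_days=5, seed=1)
        ad = AdSpec("a0", delta=0.0, impressions_per_day=100_000, base_rate=0.05)
        log = simulate_ad_logs([ad], scores, seed=3)
        assert len(log) == 1_400_000
        gap = (log.loc[log.clicked, "score"].mean()
               - log.loc[~log.clicked, "score"].mean())
        assert abs(gap) < 0.01 * log["score"].std()

    def test_mood_sensitive_ad_separates_scores(self):
        scores = make_scores(n_users=200, n_days=3, seed=1)
        ad = AdSpec("a1", delta=2.0, impressions_per_day=5000, base_rate=0.01)
        log = simulate_ad_logs([ad], scores, seed=4)
        assert (log.loc[log.clicked, "score"].mean()
                > log.loc[~log.clicked, "score"].mean())

    def test_each_ad_serves_14_days(self):
        scores = make_scores(seed=2)
        log = simulate_ad_logs([AdSpec("a", impressions_per_day=50)], scores, seed=0)
        assert sorted(log["day"].unique()) == list(range(1, 15))

    def test_bad_scores_table_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            simulate_ad_logs([AdSpec("a")], pd.DataFrame({"user_id": [1]}))


class TestCoupledLogistic:
    def test_determinism_and_range(self):
        a = coupled_logistic(500, 0.1, 0.2, seed=5)
        b = coupled_logistic(500, 0.1, 0.2, seed=5)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)
        assert ((a.x > 0) & (a.x < 1)).all()
        assert ((a.y > 0) & (a.y < 1)).all()

    def test_zero_coupling_independent_maps(self):
        pair = coupled_logistic(2000, 0.0, 0.0, seed=1)
        solo = coupled_logistic(2000, 0.0, 0.9, seed=1)
        # x's dynamics do not depend on y when beta_xy = 0
        np.testing.assert_array_equal(pair.x, solo.x)

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="n must be"):
            coupled_logistic(50)
        with pytest.raises(ValueError, match="beta"):
            coupled_logistic(200, beta_xy=1.5)
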