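"""Pre-packaged study procedures over the synthetic cohorts.

Each function wires the generators to one analysis module and returns the
quantities that analysis is about: the two-step augmentation gain, the
weekly-rhythm table over a simulated year, the coupled-logistic CCM
benchmark, the regional drop correlation recovery, and the mood-blind ad
null calibration. They are the library surface behind the worked examples
and the reproduction script.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from . import ads as ads_mod
from . import aggregation, ccm, qmm
from . import synthetic_data as synth
from .pipeline import run_two_step

__all__ = [
    "two_step_gain_study",
    "augmentation_bookkeeping_study",
    "weekly_rhythm_study",
    "ccm_benchmark_study",
    "simplex_oracle_check",
    "region_drop_recovery_study",
    "ad_null_calibration_study",
]


def two_step_gain_study(seeds=range(5), n_users: int = 200, n_days: int = 21,
                        annotation_missingness: float = 0.75,
                        permuted: bool = False) -> pd.DataFrame:
    """AUC of QMM with vs without SMM augmentation, one row per seed.

    High annotation missingness is the regime where augmentation matters:
    few frames carry a self-report, while the sensor stream (and hence the
    SMM's imputed labels) covers everything. ``permuted=True`` replaces the
    SMM with a label-permuted (useless) one — the negative control under
    which the gain should vanish.
    """
    rows = []
    for seed in seeds:
        bundle = synth.simulate_cohort(
            synth.CohortConfig(n_users=n_users, n_days=n_days, seed=seed),
            synth.GeneratorParams(annotation_missingness=annotation_missingness))
        res = run_two_step(bundle, seed=seed,
                           smm_mode="permuted" if permuted else "fit")
        rows.append({"seed": seed, "auc_with": res.auc_with,
                     "auc_without": res.auc_without, "gain": res.gain,
                     "n_labels_with": res.n_labels_with,
                     "n_labels_without": res.n_labels_without})
    return pd.DataFrame(rows)


def augmentation_bookkeeping_study(n_frames: int = 2000, missingness: float = 0.5,
                                   seed: int = 0) -> dict:
    """Label-count bookkeeping under frame-level annotation missingness.

    Builds ``n_frames`` query frames, gives a (non-neutral) annotation to a
    Bernoulli(1 - missingness) subset, provides SMM predictions everywhere,
    and counts the labeled training set with and without augmentation. With
    50% missingness the augmented count is ~2x the annotation-only count.
    """
    rng = np.random.default_rng(seed)
    frames = pd.date_range("2019-07-01", periods=n_frames, freq="3h")
    import scipy.sparse as sp
    fs = qmm.QueryFrameSet(
        X=sp.csr_matrix((rng.random((n_frames, 3)) < 0.5).astype(float)),
        vocabulary=["a", "b", "c"],
        index=pd.DataFrame({"user_id": 0, "frame_start": frames}))
    annotated = rng.random(n_frames) < (1.0 - missingness)
    ann = pd.DataFrame({
        "user_id": 0,
        "timestamp": frames[annotated] + pd.Timedelta(minutes=10),
        "likert": rng.choice([1, 2, 3, 5, 6, 7], annotated.sum())})
    pred = pd.DataFrame({"user_id": 0, "frame_start": frames,
                         "predicted_class": rng.integers(0, 2, n_frames)})
    n_without = len(qmm.augment_labels(fs, ann, None).labels)
    n_with = len(qmm.augment_labels(fs, ann, pred).labels)
    return {"n_without": n_without, "n_with": n_with,
            "ratio": n_with / n_without}


def weekly_rhythm_study(n_users: int = 250, n_days: int = 364, seed: int = 0,
                        start_date: dt.date = dt.date(2019, 12, 30),
                        holidays=()) -> pd.DataFrame:
    """Weekly rhythm table from a year-long cohort's population mood.

    Uses the latent per-user mood as the per-frame score (the aggregation
    machinery is score-agnostic), so the rhythm reflects the generator's
    weekly cycle without model-estimation noise on top.
    """
    bundle = synth.simulate_cohort(
        synth.CohortConfig(n_users=n_users, n_days=n_days,
                           start_date=start_date, seed=seed),
        synth.GeneratorParams(annotation_missingness=1.0, query_rate=0.0))
    scores = bundle.latent_frame().rename(columns={"mood": "score"})
    daily = aggregation.nationwide_score(scores, granularity="daily")
    return aggregation.weekly_rhythm(daily, holidays)


def ccm_benchmark_study(n: int = 1000, beta: float = 0.32, E: int = 2,
                        n_draws: int = 30, seed: int = 0) -> dict:
    """CCM on the coupled logistic benchmark: forced vs uncoupled systems.

    With x forcing y (coupling ``beta`` in y's update), skill should converge
    in "Y xmap X" only; with zero coupling, both directions should stay flat
    near zero.
    """
    forced = synth.coupled_logistic(n, beta_xy=0.0, beta_yx=beta, seed=seed)
    res_f = ccm.ccm_both_directions(forced.x, forced.y, names=("X", "Y"),
                                    E=E, n_draws=n_draws, seed=seed)
    uncoupled = synth.coupled_logistic(n, 0.0, 0.0, seed=seed)
    res_u = ccm.ccm_both_directions(uncoupled.x, uncoupled.y, names=("X", "Y"),
                                    E=E, n_draws=n_draws, seed=seed)
    return {
        "rho_forced": res_f["Y xmap X"].rho_at_max_l,
        "rho_reverse": res_f["X xmap Y"].rho_at_max_l,
        "rho_gap": res_f["Y xmap X"].rho_at_max_l - res_f["X xmap Y"].rho_at_max_l,
        "forced_convergent": res_f["Y xmap X"].convergent,
        "reverse_convergent": res_f["X xmap Y"].convergent,
        "rho_uncoupled_max": max(abs(r.rho_at_max_l) for r in res_u.values()),
        "uncoupled_convergent": any(r.convergent for r in res_u.values()),
    }


def simplex_oracle_check(length: int = 200, seed: int = 0) -> float:
    """Max |difference| between the simplex forecaster and an exhaustive
    nearest-neighbor enumeration on a short noisy-periodic series."""
    rng = np.random.default_rng(seed)
    x = np.sin(np.arange(length) * 0.25) + 0.2 * rng.normal(size=length)
    worst = 0.0
    for E, tau in [(1, 1), (2, 1), (3, 1), (2, 2)]:
        pts = ccm.embed(x, E, tau)
        usable = len(pts) - 1
        ours = ccm._loo_simplex_forecast(pts[:usable], x[(E - 1) * tau + 1:][:usable],
                                         k=E + 1, exclusion=tau)
        oracle = _brute_force_simplex(x, E, tau, horizon=1, exclusion=tau)
        worst = max(worst, float(np.max(np.abs(ours - oracle))))
    return worst


def _brute_force_simplex(x, E, tau, horizon, exclusion):
    n_pts = len(x) - (E - 1) * tau
    points = [[x[i + (E - 1) * tau - j * tau] for j in range(E)]
              for i in range(n_pts)]
    usable = n_pts - horizon
    preds = []
    for i in range(usable):
        cand = []
        for j in range(usable):
            if abs(i - j) <= exclusion:
                continue
            d = np.sqrt(sum((points[i][c] - points[j][c]) ** 2 for c in range(E)))
            cand.append((d, j))
        cand.sort(key=lambda t: (t[0], t[1]))
        nbrs = cand[:E + 1]
        dmin = nbrs[0][0]
        ws = ([1.0] * len(nbrs) if dmin <= 1e-12
              else [np.exp(-d / dmin) for d, _ in nbrs])
        tot = sum(ws)
        preds.append(sum(w * x[j + (E - 1) * tau + horizon]
                         for w, (_, j) in zip(ws, nbrs)) / tot)
    return np.array(preds)


def region_drop_recovery_study(target_r: float = -0.43, n_regions: int = 47,
                               seeds=range(10)) -> dict:
    """Recover a known drop-vs-cases correlation across simulated regions."""
    rs = []
    base_days = pd.date_range("2020-01-01", "2020-01-03")
    target = pd.Timestamp("2020-04-12")
    for seed in seeds:
        rng = np.random.default_rng(seed)
        z = rng.multivariate_normal([0, 0], [[1, target_r], [target_r, 1]],
                                    size=n_regions)
        rows = []
        for i in range(n_regions):
            region = f"R{i:02d}"
            for day in base_days:
                rows.append({"index": day, "region": region, "value": 1.0})
            rows.append({"index": target, "region": region,
                         "value": 1.0 + 0.2 * z[i, 0]})
        scores = pd.DataFrame(rows).set_index("index")
        cases = pd.DataFrame({
            "region": [f"R{i:02d}" for i in range(n_regions)],
            "new_cases": np.maximum(0, 500 + 200 * z[:, 1]).astype(int)})
        res = aggregation.region_drop_correlation(
            scores, cases, target, (base_days[0], base_days[-1]))
        rs.append(res.pearson_r)
    return {"target_r": target_r, "mean_r": float(np.mean(rs)),
            "r_values": rs}


def ad_null_calibration_study(n_blind: int = 2000, n_sensitive: int = 10,
                              delta: float = 5.0, impressions_per_day: int = 1000,
                              base_rate: float = 0.02, seed: int = 0,
                              chunk: int = 200) -> dict:
    """Null calibration of the pairwise statistic over mood-blind ads.

    Serves ``n_blind`` mood-blind ads plus ``n_sensitive`` strongly
    mood-sensitive ones to users with N(0,1) mood scores; day winners come
    from exact pair enumeration. Under the null the fraction of ads with
    k in {0, 14} positive-win days should match 2 * 0.5^14; the sensitive
    ads should land in the extreme set.
    """
    rng = np.random.default_rng(seed)
    frames = pd.date_range("2020-01-06", periods=14 * 8, freq="3h")
    n_users = 5000
    scores = pd.DataFrame({
        "user_id": np.repeat(np.arange(n_users), 4),
        "frame_start": np.tile(frames[:4], n_users),
        "score": rng.normal(size=n_users * 4),
    })

    specs = [synth.AdSpec(f"blind{i:04d}", 0.0, impressions_per_day, base_rate)
             for i in range(n_blind)]
    specs += [synth.AdSpec(f"sens{i:02d}", delta, impressions_per_day, base_rate)
              for i in range(n_sensitive)]

    day_results = []
    child = np.random.SeedSequence(seed).generate_state(len(specs) // chunk + 1)
    for ci in range(0, len(specs), chunk):
        part = specs[ci:ci + chunk]
        events = synth.simulate_ad_logs(part, scores,
                                        seed=int(child[ci // chunk] % (2**31)))
        day_results.extend(ads_mod.pairwise_all_days(events, method="exact"))

    dist_all = ads_mod.wins_distribution(day_results)
    blind_days = [r for r in day_results if r.ad_id.startswith("blind")]
    dist_blind = ads_mod.wins_distribution(blind_days)
    null = ads_mod.binomial_null(14)
    sens = dist_all.per_ad[dist_all.per_ad["ad_id"].str.startswith("sens")]
    return {
        "n_blind_ads": dist_blind.n_ads,
        "extreme_fraction_blind": dist_blind.extreme_fraction(strict=True),
        "extreme_count_blind": int(
            dist_blind.counts[0] + dist_blind.counts[-1]),
        "null_extreme_probability": 2 * float(null.pmf_exact[14]),
        "n_sensitive_flagged": int(sens["extreme_13"].sum()),
        "n_sensitive": len(sens),
        "distribution": dist_blind,
    }
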