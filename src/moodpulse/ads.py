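"""Pairwise mood-conditioned ad-click statistic and its binomial null.

For each ad-day, pairs of impression records are drawn; whenever exactly one
record of the pair is a click, the pair is "positive" if the clicked user's
mood score is higher than the non-clicked user's, "negative" if lower, and a
tie otherwise (ties are excluded from the day's majority by default). The
majority over draws defines the day's winner; an ad's statistic is the number
of positive-win days out of its 14 serving days, compared against the exact
fair-coin binomial distribution.

Both a Monte-Carlo estimator (uniform random distinct pairs, matching the
production-scale procedure) and an exact enumeration over all
(clicked, unclicked) pairs (sorting-based, O(n log n)) are provided; the
enumeration is used automatically whenever feasible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from ._frames import frame_floor

__all__ = [
    "PairwiseDayResult",
    "WinDistribution",
    "BinomialNull",
    "join_scores",
    "pairwise_day",
    "pairwise_all_days",
    "wins_distribution",
    "binomial_null",
    "enrichment",
]


def join_scores(ad_events: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Attach each impression's mood score: the QMM score of the user's frame
    containing the impression timestamp. Impressions whose (user, frame) has
    no score are dropped with a warning."""
    ev = ad_events.copy()
    ev["frame_start"] = frame_floor(ev["timestamp"]).to_numpy()
    sc = scores[["user_id", "frame_start", "score"]].copy()
    sc["frame_start"] = pd.to_datetime(sc["frame_start"])
    merged = ev.merge(sc, on=["user_id", "frame_start"], how="left")
    missing = merged["score"].isna()
    if missing.any():
        warnings.warn(f"dropped {missing.sum()} impression(s) without a mood score",
                      stacklevel=2)
        merged = merged.loc[~missing]
    return merged.drop(columns=["frame_start"]).reset_index(drop=True)


@dataclass
class PairwiseDayResult:
    """Pairwise comparison tally for one ad-day."""

    ad_id: str
    day: int
    usable: bool
    n_draws: int  # MC draws attempted (0 in exact mode)
    n_valid_pairs: int  # pairs with exactly one click that were compared
    n_positive: int
    n_negative: int
    n_tied: int
    winner: str  # 'positive' | 'negative' | 'tie' | 'unusable'
    method: str  # 'exact' | 'mc'

    @property
    def positive_fraction(self) -> float:
        denom = self.n_positive + self.n_negative
        return self.n_positive / denom if denom else np.nan


def _winner(n_pos: int, n_neg: int) -> str:
    if n_pos > n_neg:
        return "positive"
    if n_neg > n_pos:
        return "negative"
    return "tie"


def _exact_counts(clicked_scores: np.ndarray,
                  unclicked_scores: np.ndarray) -> tuple[int, int, int]:
    """Exact (positive, negative, tied) counts over all clicked x unclicked pairs."""
    u = np.sort(unclicked_scores)
    lo = np.searchsorted(u, clicked_scores, side="left")
    hi = np.searchsorted(u, clicked_scores, side="right")
    n_pos = int(lo.sum())  # unclicked strictly below the clicked score
    n_tie = int((hi - lo).sum())
    n_neg = int((len(u) - hi).sum())
    return n_pos, n_neg, n_tie


def pairwise_day(records: pd.DataFrame, ad_id: str = "", day: int = 0,
                 n_iter: int = 100_000, seed: int = 0, method: str = "auto",
                 exact_limit: int = 100_000) -> PairwiseDayResult:
    """Pairwise positive/negative tally for one ad-day.

    ``records`` needs columns clicked (bool) and score. A day with no clicked
    or no unclicked record is flagged unusable. ``method='exact'`` enumerates
    every (clicked, unclicked) pair; ``'mc'`` draws ``n_iter`` unordered
    distinct record pairs uniformly (draws without exactly one click are
    discarded but still count toward ``n_iter``); ``'auto'`` enumerates when
    the record count is at most ``exact_limit``.
    """
    if method not in ("auto", "exact", "mc"):
        raise ValueError(f"unknown method {method!r}")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    clicked = records["clicked"].to_numpy(dtype=bool)
    score = records["score"].to_numpy(dtype=float)
    c_scores = score[clicked]
    u_scores = score[~clicked]
    if len(c_scores) == 0 or len(u_scores) == 0:
        return PairwiseDayResult(ad_id=ad_id, day=day, usable=False, n_draws=0,
                                 n_valid_pairs=0, n_positive=0, n_negative=0,
                                 n_tied=0, winner="unusable", method="none")

    if method == "auto":
        method = "exact" if len(records) <= exact_limit else "mc"

    if method == "exact":
        n_pos, n_neg, n_tie = _exact_counts(c_scores, u_scores)
        return PairwiseDayResult(
            ad_id=ad_id, day=day, usable=True, n_draws=0,
            n_valid_pairs=n_pos + n_neg + n_tie, n_positive=n_pos,
            n_negative=n_neg, n_tied=n_tie, winner=_winner(n_pos, n_neg),
            method="exact")

    rng = np.random.default_rng(seed)
    n = len(records)
    i = rng.integers(0, n, n_iter)
    j = rng.integers(0, n, n_iter)
    distinct = i != j
    one_click = clicked[i] != clicked[j]
    valid = distinct & one_click
    # orient: s_c = clicked member's score, s_u = the other's
    ci, cj = clicked[i[valid]], clicked[j[valid]]
    s_i, s_j = score[i[valid]], score[j[valid]]
    s_c = np.where(ci, s_i, s_j)
    s_u = np.where(ci, s_j, s_i)
    n_pos = int((s_c > s_u).sum())
    n_neg = int((s_c < s_u).sum())
    n_tie = int((s_c == s_u).sum())
    return PairwiseDayResult(
        ad_id=ad_id, day=day, usable=True, n_draws=n_iter,
        n_valid_pairs=int(valid.sum()), n_positive=n_pos, n_negative=n_neg,
        n_tied=n_tie, winner=_winner(n_pos, n_neg), method="mc")


def pairwise_all_days(events: pd.DataFrame, n_iter: int = 100_000, seed: int = 0,
                      method: str = "auto") -> list[PairwiseDayResult]:
    """Run :func:`pairwise_day` for every (ad, day) in a scored event log.

    ``events`` needs columns ad_id, day, clicked, score (see
    :func:`join_scores`). Seeds are derived per (ad, day) from ``seed``.
    """
    results = []
    ss = np.random.SeedSequence(seed)
    groups = sorted(events.groupby(["ad_id", "day"]).groups.keys())
    child_seeds = ss.generate_state(max(len(groups), 1))
    by = events.groupby(["ad_id", "day"])
    for (key, sub_seed) in zip(groups, child_seeds):
        ad_id, day = key
        sub = by.get_group(key)
        results.append(pairwise_day(sub, ad_id=str(ad_id), day=int(day),
                                    n_iter=n_iter, seed=int(sub_seed) % (2**31),
                                    method=method))
    return results


@dataclass
class WinDistribution:
    """Histogram of ads by number of positive-win days (out of ``n_days``)."""

    counts: np.ndarray  # ads with exactly k positive-win days, k = 0..n_days
    n_days: int
    n_ads: int  # ads with a full set of usable days
    excluded_ads: list[str]  # ads dropped for having an unusable day
    per_ad: pd.DataFrame  # ad_id, k_positive, extreme_14, extreme_13

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.n_ads if self.n_ads else self.counts * np.nan

    def extreme_fraction(self, strict: bool = True) -> float:
        """Fraction of ads in the extreme set: k in {0, n} (strict) or
        {<=1, >=n-1}."""
        k = np.arange(self.n_days + 1)
        sel = (k == 0) | (k == self.n_days) if strict else (k <= 1) | (k >= self.n_days - 1)
        return float(self.counts[sel].sum() / self.n_ads) if self.n_ads else np.nan


def wins_distribution(day_results: list[PairwiseDayResult],
                      n_days: int = 14) -> WinDistribution:
    """Aggregate day winners into the per-ad positive-win-day histogram.

    Ads must have exactly ``n_days`` usable days; others are excluded and
    reported. A day won by 'negative' or tied counts as not-positive.
    """
    by_ad: dict[str, list[PairwiseDayResult]] = {}
    for r in day_results:
        by_ad.setdefault(r.ad_id, []).append(r)

    counts = np.zeros(n_days + 1, dtype=int)
    excluded = []
    rows = []
    for ad_id, days in sorted(by_ad.items()):
        usable = [d for d in days if d.usable]
        if len(usable) != n_days:
            excluded.append(ad_id)
            continue
        k = sum(1 for d in usable if d.winner == "positive")
        counts[k] += 1
        rows.append({"ad_id": ad_id, "k_positive": k,
                     "extreme_14": k in (0, n_days),
                     "extreme_13": k <= 1 or k >= n_days - 1})
    per_ad = pd.DataFrame(rows, columns=["ad_id", "k_positive", "extreme_14",
                                         "extreme_13"])
    return WinDistribution(counts=counts, n_days=n_days, n_ads=int(counts.sum()),
                           excluded_ads=excluded, per_ad=per_ad)


@dataclass
class BinomialNull:
    """Exact fair-coin distribution of positive-win days out of ``n_days``."""

    n_days: int
    pmf_exact: list[Fraction]

    @property
    def pmf(self) -> np.ndarray:
        return np.array([float(p) for p in self.pmf_exact])

    def pmf_percent(self, k: int) -> float:
        """P(exactly k positive days) as a percentage."""
        return float(self.pmf_exact[k]) * 100.0

    def tail_percent(self, k: int) -> float:
        """P(K >= k) as a percentage."""
        return float(sum(self.pmf_exact[k:])) * 100.0


def binomial_null(n_days: int = 14) -> BinomialNull:
    """Exact Binomial(n_days, 1/2) pmf in rational arithmetic."""
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    import math
    denom = Fraction(1, 2 ** n_days)
    pmf = [math.comb(n_days, k) * denom for k in range(n_days + 1)]
    assert sum(pmf) == 1
    return BinomialNull(n_days=n_days, pmf_exact=pmf)


def enrichment(dist: WinDistribution, null: BinomialNull) -> pd.DataFrame:
    """Per-k ratio of the empirical ad fraction to the fair-coin probability.

    Zero empirical mass gives a ratio of 0 (never NaN). The returned frame
    also carries the two extreme-set ratios as attrs: ``extreme_14_ratio``
    (k in {0, n}) and ``extreme_13_ratio`` (k <= 1 or >= n-1).
    """
    if dist.n_days != null.n_days:
        raise ValueError("distribution and null have different supports")
    frac = dist.fractions
    pmf = null.pmf
    out = pd.DataFrame({"k": np.arange(dist.n_days + 1), "empirical": frac,
                        "null": pmf, "ratio": frac / pmf})
    k = out["k"].to_numpy()
    strict = (k == 0) | (k == dist.n_days)
    loose = (k <= 1) | (k >= dist.n_days - 1)
    out.attrs["extreme_14_ratio"] = float(frac[strict].sum() / pmf[strict].sum())
    out.attrs["extreme_13_ratio"] = float(frac[loose].sum() / pmf[loose].sum())
    return out
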