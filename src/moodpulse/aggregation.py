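"""Nationwide / regional mood-score aggregation and descriptive analyses.

The nationwide mood score at an index (day or 3-hour slot) is the arithmetic
mean of the mood scores of users *active* in that index — a user contributes
only where they have at least one scored frame, so the contributing
population changes from index to index and is recorded as ``n_users``.

Daily aggregation defaults to the mean of per-user daily means, so heavy
searchers do not dominate; a pooled-over-frames variant is available.

Three descriptive analyses operate on these series:

* ``weekly_rhythm`` — per weekday, the fraction of (non-holiday) days whose
  daily score is >= the previous day's.
* ``region_drop_correlation`` — per-region mood drop at a target date
  relative to a baseline window, correlated with per-region case counts.
* ``event_trace`` — a target week's slot series relative to the mean of two
  reference weeks, for tracing sharp shared events at hourly resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "nationwide_score",
    "weekly_rhythm",
    "region_drop_correlation",
    "event_trace",
    "RegionDropResult",
]

WEEKDAYS = ["Monday", "Tuesday", "Wednesday", "Thursday", "Friday",
            "Saturday", "Sunday"]


def nationwide_score(scores: pd.DataFrame, granularity: str = "daily",
                     method: str = "user_mean", by_region: bool = False,
                     region_map: pd.Series | pd.DataFrame | None = None) -> pd.DataFrame:
    """Aggregate per-(user, frame) mood scores into a population score series.

    ``scores`` needs columns user_id, frame_start, score (and region when
    ``by_region`` without a ``region_map``). Returns a frame indexed by day
    (or slot), with columns ``value`` and ``n_users`` (plus ``region``).
    Empty input yields an empty frame; an index with no active user simply
    does not appear (never a silent 0).
    """
    if granularity not in ("daily", "slot"):
        raise ValueError(f"granularity must be 'daily' or 'slot', got {granularity!r}")
    if method not in ("user_mean", "pooled"):
        raise ValueError(f"method must be 'user_mean' or 'pooled', got {method!r}")
    cols = ["value", "n_users"] + (["region"] if by_region else [])
    if len(scores) == 0:
        return pd.DataFrame(columns=cols)

    df = scores.copy()
    df["frame_start"] = pd.to_datetime(df["frame_start"])
    if by_region:
        if "region" not in df.columns:
            if region_map is None:
                raise ValueError("by_region requires a 'region' column or region_map")
            rm = region_map
            if isinstance(rm, pd.DataFrame):
                rm = rm.set_index("user_id")["region"]
            df["region"] = df["user_id"].map(rm)

    df["index"] = (df["frame_start"].dt.floor("D") if granularity == "daily"
                   else df["frame_start"])
    group_cols = (["region", "index"] if by_region else ["index"])

    if method == "user_mean":
        per_user = df.groupby(group_cols + ["user_id"])["score"].mean().reset_index()
        agg = per_user.groupby(group_cols)["score"].agg(value="mean", n_users="size")
    else:
        agg = df.groupby(group_cols).agg(
            value=("score", "mean"), n_users=("user_id", "nunique"))
    out = agg.reset_index().set_index("index").sort_index()
    if by_region:
        out = out[["region", "value", "n_users"]]
    return out


def weekly_rhythm(series: pd.DataFrame | pd.Series,
                  holidays: set | frozenset | list = ()) -> pd.DataFrame:
    """Per-weekday fraction of days whose score is >= the previous day's.

    ``series`` is a daily score series (Series, or frame with a ``value``
    column) indexed by date. A (today, yesterday) comparison counts only when
    *both* days are non-holiday; yesterday is the previous calendar day and
    must be present in the series. Returns a frame indexed by weekday with
    ``pct_up`` (today >= yesterday), ``pct_down``, and ``n`` comparisons;
    the two percentages sum to 100 exactly.
    """
    s = series["value"] if isinstance(series, pd.DataFrame) else series
    s = s.copy()
    s.index = pd.to_datetime(s.index)
    s = s.sort_index()
    if len(s) < 2:
        raise ValueError("series must span at least 2 days")
    holiday_set = {pd.Timestamp(h).normalize() for h in holidays}

    up = {w: 0 for w in range(7)}
    n = {w: 0 for w in range(7)}
    values = s.to_dict()
    for day, val in s.items():
        prev = day - pd.Timedelta(days=1)
        if prev not in values:
            continue
        if day.normalize() in holiday_set or prev.normalize() in holiday_set:
            continue
        w = day.dayofweek
        n[w] += 1
        if val >= values[prev]:
            up[w] += 1

    rows = []
    for w, name in enumerate(WEEKDAYS):
        if n[w] == 0:
            rows.append({"weekday": name, "pct_up": np.nan, "pct_down": np.nan, "n": 0})
        else:
            pct = 100.0 * up[w] / n[w]
            rows.append({"weekday": name, "pct_up": pct, "pct_down": 100.0 - pct,
                         "n": n[w]})
    return pd.DataFrame(rows).set_index("weekday")


@dataclass
class RegionDropResult:
    """Per-region mood drops with their correlation against case counts."""

    table: pd.DataFrame  # region, drop, cases
    pearson_r: float  # NaN when undefined (zero variance)
    p_value: float
    mode: str  # 'difference' | 'ratio'


def region_drop_correlation(scores: pd.DataFrame, cases: pd.DataFrame,
                            target_date, baseline_window: tuple,
                            mode: str = "difference") -> RegionDropResult:
    """Correlate each region's mood drop at ``target_date`` with its case count.

    ``scores``: daily regional series with columns region, value, indexed by
    date (as produced by ``nationwide_score(..., by_region=True)``).
    ``cases``: columns region, new_cases (counts at the target date).
    The drop is ``target - mean(baseline window)`` (difference, default) or
    ``target / mean(baseline)`` (ratio). Regions missing from either input
    are excluded with a warning. With more cases producing deeper drops, the
    expected correlation is negative.
    """
    if mode not in ("difference", "ratio"):
        raise ValueError(f"mode must be 'difference' or 'ratio', got {mode!r}")
    target = pd.Timestamp(target_date)
    b0, b1 = (pd.Timestamp(b) for b in baseline_window)

    df = scores.copy()
    df.index = pd.to_datetime(df.index)
    rows = []
    for region, sub in df.groupby("region"):
        base = sub.loc[(sub.index >= b0) & (sub.index <= b1), "value"]
        at_target = sub.loc[sub.index == target, "value"]
        if len(base) == 0 or len(at_target) == 0:
            warnings.warn(f"region {region!r} lacks baseline or target score; excluded",
                          stacklevel=2)
            continue
        baseline = float(base.mean())
        t = float(at_target.iloc[0])
        drop = t - baseline if mode == "difference" else t / baseline
        rows.append({"region": region, "drop": drop})
    table = pd.DataFrame(rows)

    case_col = cases.set_index("region")["new_cases"]
    missing = set(table["region"]) - set(case_col.index)
    if missing:
        warnings.warn(f"regions missing case counts excluded: {sorted(missing)}",
                      stacklevel=2)
        table = table.loc[~table["region"].isin(missing)]
    table["cases"] = table["region"].map(case_col)
    if len(table) < 3:
        raise ValueError("need at least 3 regions with both scores and cases")

    drop = table["drop"].to_numpy(dtype=float)
    cc = table["cases"].to_numpy(dtype=float)
    if np.ptp(drop) == 0 or np.ptp(cc) == 0:
        r, p = np.nan, np.nan  # zero variance: correlation undefined
    else:
        r, p = stats.pearsonr(drop, cc)
    return RegionDropResult(table=table.reset_index(drop=True),
                            pearson_r=float(r), p_value=float(p), mode=mode)


def event_trace(target: pd.Series, ref1: pd.Series, ref2: pd.Series,
                mode: str = "ratio", denom_tol: float = 1e-6) -> pd.DataFrame:
    """Target week's slot series relative to the mean of two reference weeks.

    The three series must be aligned slot-by-slot (same length; the index is
    taken from ``target``). Ratio mode computes target / mean(ref1, ref2) and
    flags slots where the reference mean is within ``denom_tol`` of zero as
    unusable (the ratio is unbounded there); difference mode computes
    target - mean and is invariant to adding a constant to all three weeks.
    """
    if mode not in ("ratio", "difference"):
        raise ValueError(f"mode must be 'ratio' or 'difference', got {mode!r}")
    if not (len(target) == len(ref1) == len(ref2)):
        raise ValueError("misaligned slot series: lengths differ")
    t = np.asarray(target, dtype=float)
    m = (np.asarray(ref1, dtype=float) + np.asarray(ref2, dtype=float)) / 2.0

    if mode == "difference":
        value = t - m
        usable = np.ones(len(t), dtype=bool)
    else:
        usable = np.abs(m) > denom_tol
        value = np.full(len(t), np.nan)
        value[usable] = t[usable] / m[usable]
    return pd.DataFrame({"value": value, "usable": usable},
                        index=getattr(target, "index", pd.RangeIndex(len(t))))
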