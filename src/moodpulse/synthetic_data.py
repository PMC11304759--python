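"""Synthetic data streams for the mood-analytics pipeline.

Generates, with known ground truth, every input the downstream stages
consume: a latent per-user mood process on 3-hour frames, experience-sampling
(ESM) Likert annotations, per-frame smartphone sensor features, search-query
events over a mood-stratified vocabulary, an epidemic case-count curve
(optionally coupled to population mood), ad impression/click logs
(optionally mood-dependent), and a coupled logistic-map pair used as the
standard benchmark for the causality module.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations


import datetime as dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit, logit

from ._frames import FRAME_HOURS, PROMPT_HOURS, SLOTS_PER_DAY, slot_times

__all__ = [
    "CohortConfig",
    "GeneratorParams",
    "CohortBundle",
    "EpidemicParams",
    "AdSpec",
    "CoupledMapPair",
    "simulate_cohort",
    "simulate_epidemic",
    "simulate_ad_logs",
    "coupled_logistic",
    "write_bundle",
]


# --------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class CohortConfig:
    """Cohort layout: who is observed, where, and for how long.

    ``region_assignments`` maps user index -> region label; the default
    assigns users round-robin over ``n_regions`` labels (emulating the 47
    Japanese prefectures).
    """

    n_users: int
    n_days: int
    start_date: dt.date = dt.date(2019, 7, 1)
    seed: int = 0
    n_regions: int = 47
    region_assignments: Mapping[int, str] | None = None

    def __post_init__(self) -> None:
        if self.n_users < 1:
            raise ValueError(f"n_users must be >= 1, got {self.n_users}")
        if self.n_days < 1:
            raise ValueError(f"n_days must be >= 1, got {self.n_days}")

    def region_of(self, user: int) -> str:
        if self.region_assignments is not None:
            return self.region_assignments[user]
        return f"R{user % self.n_regions + 1:02d}"


@dataclass(frozen=True)
class GeneratorParams:
    """Tunable parameters of the latent mood process and its observation models.

    The latent mood of user u in slot t is
    ``baseline_u + weekly(t) + ar(t) + shock(t) + noise`` where ``weekly`` is a
    sinusoid with 7-day period peaking at ``weekly_peak_day_frac`` (days since
    Monday 00:00; the default 6.5 = Sunday noon puts the trough midweek, so the
    population mean drops into Monday and climbs through the weekend), ``ar``
    is a per-user AR(1), and shocks are shared step events.

    Observation models:

    * annotations — six daily ESM prompts; each answered with probability
      ``1 - annotation_missingness``; the Likert response is an equal-width
      binning (width ``likert_bin_width`` on the z-scale) of the latent value
      plus response noise.
    * sensor features — linear links to latent mood scaled by
      ``sensor_coupling`` plus Gaussian noise (``sensor_noise_sd``).
    * queries — per-slot Poisson(``query_rate``) events; tokens drawn from a
      vocabulary split into positive/negative/neutral strata with stratum
      odds tilted by ``query_coupling`` × latent mood.
    """

    baseline_sd: float = 0.5
    weekly_amplitude: float = 1.0
    weekly_peak_day_frac: float = 6.5
    ar_phi: float = 0.6
    ar_sd: float = 0.3
    noise_sd: float = 0.3
    # shared shocks: (timestamp, magnitude, duration_hours)
    shocks: tuple[tuple[dt.datetime, float, float], ...] = ()

    annotation_missingness: float = 0.5
    annotation_noise_sd: float = 0.3
    likert_bin_width: float = 0.6

    sensor_coupling: float = 1.0
    sensor_noise_sd: float = 1.0
    frame_missing_rate: float = 0.0

    query_rate: float = 0.7
    query_coupling: float = 0.8
    tokens_per_query_mean: float = 2.0
    vocab_positive: int = 40
    vocab_negative: int = 40
    vocab_neutral: int = 120

    def __post_init__(self) -> None:
        for name in ("annotation_missingness", "frame_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("baseline_sd", "ar_sd", "noise_sd", "sensor_noise_sd",
                     "annotation_noise_sd", "query_rate", "weekly_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tokens_per_query_mean < 1:
            raise ValueError("tokens_per_query_mean must be >= 1")

    @property
    def vocabulary(self) -> list[str]:
        return (
            [f"pos{i:03d}" for i in range(self.vocab_positive)]
            + [f"neg{i:03d}" for i in range(self.vocab_negative)]
            + [f"neu{i:03d}" for i in range(self.vocab_neutral)]
        )


# --------------------------------------------------------------------------
# cohort bundle


@dataclass
class CohortBundle:
    """Everything one simulated cohort produced, with ground truth attached.

    ``latent`` has shape (n_users, n_slots); ``slot_starts`` gives the frame
    start time of each slot column. ``latent_mean``/``latent_sd`` are the
    population moments used for Likert discretization, so downstream code can
    recover the true mood class of any (user, slot).
    """

    config: CohortConfig
    params: GeneratorParams
    latent: np.ndarray
    slot_starts: pd.DatetimeIndex
    annotations: pd.DataFrame  # user_id, timestamp, likert
    sensor_frames: pd.DataFrame  # user_id, frame_start, <features>
    queries: pd.DataFrame  # user_id, timestamp, tokens (list of str)
    latent_mean: float
    latent_sd: float

    @property
    def n_users(self) -> int:
        return self.latent.shape[0]

    @property
    def n_slots(self) -> int:
        return self.latent.shape[1]

    def latent_z(self) -> np.ndarray:
        """Latent mood standardized by the population moments."""
        return (self.latent - self.latent_mean) / self.latent_sd

    def true_likert(self) -> np.ndarray:
        """Noise-free Likert level of every (user, slot) under the binning rule."""
        return _likert_from_z(self.latent_z(), self.params.likert_bin_width)

    def true_binary_class(self) -> np.ndarray:
        """Noise-free binary mood class per (user, slot): 1 positive, 0 negative, -1 neutral."""
        lik = self.true_likert()
        out = np.full(lik.shape, -1, dtype=int)
        out[lik >= 5] = 1
        out[lik <= 3] = 0
        return out

    def latent_frame(self) -> pd.DataFrame:
        """Long-format latent mood: user_id, frame_start, mood."""
        n_u, n_s = self.latent.shape
        return pd.DataFrame(
            {
                "user_id": np.repeat(np.arange(n_u), n_s),
                "frame_start": np.tile(self.slot_starts, n_u),
                "mood": self.latent.ravel(),
            }
        )

    def population_mood(self) -> pd.Series:
        """Across-user mean latent mood per slot."""
        return pd.Series(self.latent.mean(axis=0), index=self.slot_starts, name="mood")

    def daily_population_mood(self) -> pd.Series:
        """Across-user mean latent mood per day."""
        pop = self.population_mood()
        return pop.groupby(pop.index.floor("D")).mean()

    def regions(self) -> pd.Series:
        return pd.Series(
            [self.config.region_of(u) for u in range(self.n_users)],
            index=pd.RangeIndex(self.n_users, name="user_id"),
            name="region",
        )


def _likert_from_z(z: np.ndarray, width: float) -> np.ndarray:
    """Equal-width binning of standardized mood onto the 7-level Likert scale.

    Bin edges sit at ±width/2, ±3·width/2, ...; values exactly on an edge
    resolve by round-half-to-even, i.e. toward the neutral side for the two
    central edges.
    """
    return (np.clip(np.rint(z / width), -3, 3) + 4).astype(int)


# --------------------------------------------------------------------------
# latent process + observation streams


def _latent_mood(config: CohortConfig, params: GeneratorParams,
                 rng: np.random.Generator) -> tuple[np.ndarray, pd.DatetimeIndex]:
    n_u = config.n_users
    starts = slot_times(config.start_date, config.n_days)
    n_s = len(starts)

    baseline = rng.normal(0.0, params.baseline_sd, size=n_u)[:, None]

    # weekly sinusoid on the slot midpoints, shared phase across users
    mid = starts + pd.Timedelta(hours=FRAME_HOURS / 2)
    day_frac = mid.dayofweek.to_numpy() + (mid.hour.to_numpy() + mid.minute.to_numpy() / 60) / 24
    weekly = params.weekly_amplitude * np.cos(
        2 * np.pi * (day_frac - params.weekly_peak_day_frac) / 7.0
    )[None, :]

    innov = rng.normal(0.0, params.ar_sd, size=(n_u, n_s))
    ar = lfilter([1.0], [1.0, -params.ar_phi], innov, axis=1)

    shock = np.zeros(n_s)
    for when, magnitude, duration_h in params.shocks:
        t0 = pd.Timestamp(when)
        t1 = t0 + pd.Timedelta(hours=float(duration_h))
        mask = np.asarray((starts + pd.Timedelta(hours=FRAME_HOURS) > t0)
                          & (starts < t1))
        shock[mask] += magnitude

    noise = rng.normal(0.0, params.noise_sd, size=(n_u, n_s))
    return baseline + weekly + ar + shock[None, :] + noise, starts


def _annotations(config: CohortConfig, params: GeneratorParams, latent: np.ndarray,
                 mu: float, sd: float, rng: np.random.Generator) -> pd.DataFrame:
    n_u, _ = latent.shape
    answer_p = 1.0 - params.annotation_missingness
    shape = (n_u, config.n_days, len(PROMPT_HOURS))
    answered = rng.random(size=shape) < answer_p
    jitter_min = np.clip(rng.normal(0.0, 5.0, size=shape), -15, 15)
    resp_noise = rng.normal(0.0, params.annotation_noise_sd, size=shape)

    u_idx, d_idx, p_idx = np.nonzero(answered)
    hours = np.asarray(PROMPT_HOURS)[p_idx]
    base = pd.Timestamp(config.start_date)
    seconds = d_idx * 86400 + hours * 3600 + jitter_min[u_idx, d_idx, p_idx] * 60
    timestamps = base + pd.to_timedelta(np.round(seconds), unit="s")
    slots = d_idx * SLOTS_PER_DAY + hours // FRAME_HOURS
    z = (latent[u_idx, slots] - mu) / sd + resp_noise[u_idx, d_idx, p_idx]
    likert = _likert_from_z(z, params.likert_bin_width)
    return pd.DataFrame({"user_id": u_idx, "timestamp": timestamps, "likert": likert})


# linear links from latent mood to each named sensor feature:
# (intercept, slope multiplied by sensor_coupling, noisy?)
_SENSOR_LINKS = {
    "activity_intensity": (2.0, 1.0),
    "screen_on_count": (20.0, -3.0),
    "screen_on_duration": (45.0, -5.0),
    "location_radius": (1.5, 0.8),
    "location_entropy": (1.0, 0.4),
    "battery_drain": (8.0, -1.0),
}


def _sensor_frames(config: CohortConfig, params: GeneratorParams, latent: np.ndarray,
                   starts: pd.DatetimeIndex, rng: np.random.Generator) -> pd.DataFrame:
    n_u, n_s = latent.shape
    user_col = np.repeat(np.arange(n_u), n_s)
    frame_col = np.tile(starts, n_u)
    m = latent.ravel()
    n = m.size
    data: dict[str, np.ndarray] = {"user_id": user_col, "frame_start": frame_col}
    for name, (a, b) in _SENSOR_LINKS.items():
        data[name] = a + params.sensor_coupling * b * m + rng.normal(0, params.sensor_noise_sd, n)
    # mood-independent context features
    data["barometric_trend"] = rng.normal(0.0, 1.0, n)
    data["network_changes"] = rng.poisson(3.0, n).astype(float)
    data["weather_code"] = rng.integers(0, 5, n).astype(float)
    df = pd.DataFrame(data)
    if params.frame_missing_rate > 0:
        keep = rng.random(n) >= params.frame_missing_rate
        df = df.loc[keep].reset_index(drop=True)
    return df


def _queries(config: CohortConfig, params: GeneratorParams, latent: np.ndarray,
             starts: pd.DatetimeIndex, rng: np.random.Generator) -> pd.DataFrame:
    n_u, n_s = latent.shape
    counts = rng.poisson(params.query_rate, size=(n_u, n_s))
    total_events = int(counts.sum())
    if total_events == 0:
        return pd.DataFrame({"user_id": [], "timestamp": [], "tokens": []})

    flat = counts.ravel()
    cell = np.repeat(np.arange(n_u * n_s), flat)
    users = cell // n_s
    slots = cell % n_s
    offsets = rng.random(total_events) * FRAME_HOURS * 3600
    timestamps = starts[slots] + pd.to_timedelta(offsets, unit="s")

    mood = latent[users, slots]
    # stratum log-odds: positive / negative tilted by mood, neutral fixed
    logits = np.stack([
        params.query_coupling * mood,
        -params.query_coupling * mood,
        np.full(total_events, np.log(2.0)),
    ], axis=1)
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)

    n_tok = 1 + rng.poisson(params.tokens_per_query_mean - 1.0, total_events)
    n_pos, n_neg, n_neu = params.vocab_positive, params.vocab_negative, params.vocab_neutral
    vocab = np.asarray(params.vocabulary)

    total_tokens = int(n_tok.sum())
    event_of_token = np.repeat(np.arange(total_events), n_tok)
    u01 = rng.random(total_tokens)
    cum = np.cumsum(probs, axis=1)[event_of_token]
    strata = (u01[:, None] >= cum).sum(axis=1)  # 0 pos, 1 neg, 2 neutral
    within = rng.random(total_tokens)
    sizes = np.array([n_pos, n_neg, n_neu])
    offsets = np.array([0, n_pos, n_pos + n_neg])
    token_ids = offsets[strata] + np.minimum(
        (within * sizes[strata]).astype(int), sizes[strata] - 1)
    token_names = vocab[token_ids]
    bounds = np.cumsum(n_tok)[:-1]
    tokens_col = [list(part) for part in np.split(token_names, bounds)]

    df = pd.DataFrame({"user_id": users, "timestamp": timestamps, "tokens": tokens_col})
    return df.sort_values(["user_id", "timestamp"], kind="stable").reset_index(drop=True)


def simulate_cohort(config: CohortConfig,
                    params: GeneratorParams | None = None) -> CohortBundle:
    """Generate one cohort: latent mood plus annotation/sensor/query streams.

    Deterministic given ``(config, params)``; ``config.seed`` seeds four
    independent substreams (latent, annotations, sensors, queries) so that
    e.g. changing the annotation missingness does not perturb the sensor
    stream.
    """
    params = params or GeneratorParams()
    ss = np.random.SeedSequence(config.seed)
    r_latent, r_ann, r_sens, r_query = (np.random.default_rng(c) for c in ss.spawn(4))

    latent, starts = _latent_mood(config, params, r_latent)
    mu = float(latent.mean())
    sd = float(latent.std())
    if sd == 0:
        sd = 1.0

    annotations = _annotations(config, params, latent, mu, sd, r_ann)
    sensor_frames = _sensor_frames(config, params, latent, starts, r_sens)
    queries = _queries(config, params, latent, starts, r_query)

    return CohortBundle(
        config=config, params=params, latent=latent, slot_starts=starts,
        annotations=annotations, sensor_frames=sensor_frames, queries=queries,
        latent_mean=mu, latent_sd=sd,
    )


# --------------------------------------------------------------------------
# epidemic curve


@dataclass(frozen=True)
class EpidemicParams:
    """Multi-wave epidemic curve parameters.

    ``waves`` is a sequence of (center_day, width_days, amplitude) Gaussian
    bumps added to ``baseline``; daily counts are Poisson draws around that
    intensity. When a population mood series is supplied to
    :func:`simulate_epidemic`, the intensity at day t is multiplied by
    ``exp(mood_coupling * mood[t - mood_lag])`` — a negative coupling makes
    high mood suppress cases.
    """

    baseline: float = 5.0
    waves: tuple[tuple[float, float, float], ...] = (
        (60, 12, 300), (150, 14, 600), (240, 20, 1200), (330, 14, 2000), (420, 16, 4000),
    )
    mood_coupling: float = 0.0
    mood_lag: int = 7
    poisson_noise: bool = True

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ValueError("baseline must be >= 0")
        if self.mood_lag < 0:
            raise ValueError("mood_lag must be >= 0")
        for c, w, a in self.waves:
            if w <= 0 or a < 0:
                raise ValueError("wave widths must be > 0 and amplitudes >= 0")


def simulate_epidemic(n_days: int, params: EpidemicParams | None = None,
                      mood: np.ndarray | pd.Series | None = None,
                      start_date: dt.date = dt.date(2020, 1, 16),
                      region: str | None = None, seed: int = 0) -> pd.DataFrame:
    """Daily new-case counts, optionally modulated by lagged population mood.

    Returns columns date, region (optional), new_cases.
    """
    if n_days < 1:
        raise ValueError(f"n_days must be >= 1, got {n_days}")
    params = params or EpidemicParams()
    t = np.arange(n_days, dtype=float)
    intensity = np.full(n_days, params.baseline)
    for center, width, amp in params.waves:
        intensity = intensity + amp * np.exp(-0.5 * ((t - center) / width) ** 2)

    if mood is not None and params.mood_coupling != 0.0:
        m = np.asarray(pd.Series(mood).to_numpy(), dtype=float)
        if len(m) < n_days:
            raise ValueError("mood series shorter than n_days")
        lagged = np.empty(n_days)
        for i in range(n_days):
            lagged[i] = m[max(i - params.mood_lag, 0)]
        lagged = (lagged - lagged.mean()) / (lagged.std() or 1.0)
        intensity = intensity * np.exp(params.mood_coupling * lagged)

    rng = np.random.default_rng(seed)
    cases = rng.poisson(intensity) if params.poisson_noise else np.round(intensity).astype(int)
    out = pd.DataFrame({
        "date": pd.date_range(pd.Timestamp(start_date), periods=n_days, freq="D"),
        "new_cases": cases.astype(int),
    })
    if region is not None:
        out.insert(1, "region", region)
    return out


# --------------------------------------------------------------------------
# ad impression/click logs


@dataclass(frozen=True)
class AdSpec:
    """One campaign: 14 serving days, with a mood sensitivity ``delta``.

    ``delta`` is the log-odds shift of the click probability per unit mood
    score; ``delta = 0`` is a mood-blind ad. ``base_rate`` is the click
    probability at mood score 0.
    """

    ad_id: str
    delta: float = 0.0
    impressions_per_day: int = 1000
    base_rate: float = 1e-3
    n_days: int = 14

    def __post_init__(self) -> None:
        if not 0 < self.base_rate < 1:
            raise ValueError("base_rate must be in (0, 1)")
        if self.impressions_per_day < 0 or self.n_days < 1:
            raise ValueError("impressions_per_day must be >= 0 and n_days >= 1")


def simulate_ad_logs(ads: Sequence[AdSpec], scores: pd.DataFrame,
                     seed: int = 0) -> pd.DataFrame:
    """Impression/click event log for a set of campaigns.

    ``scores`` must have columns user_id, frame_start, score; impressions are
    sampled uniformly from its rows (so every impression has a mood score at
    view time). Click indicator is Bernoulli with
    ``logit(p) = logit(base_rate) + delta * score``.

    Returns columns ad_id, day, user_id, timestamp, clicked, score.
    """
    required = {"user_id", "frame_start", "score"}
    if not required.issubset(scores.columns):
        raise ValueError(f"scores must have columns {sorted(required)}")
    if len(scores) == 0:
        raise ValueError("scores is empty")
    rng = np.random.default_rng(seed)
    s_user = scores["user_id"].to_numpy()
    s_frame = pd.to_datetime(scores["frame_start"]).to_numpy()
    s_score = scores["score"].to_numpy(dtype=float)

    parts = []
    for ad in ads:
        n = ad.impressions_per_day * ad.n_days
        if n == 0:
            continue
        idx = rng.integers(0, len(scores), n)
        day = np.repeat(np.arange(1, ad.n_days + 1), ad.impressions_per_day)
        offs = rng.random(n) * FRAME_HOURS * 3600
        ts = s_frame[idx] + (offs * 1e9).astype("timedelta64[ns]")
        p = expit(logit(ad.base_rate) + ad.delta * s_score[idx])
        clicked = rng.random(n) < p
        parts.append(pd.DataFrame({
            "ad_id": ad.ad_id, "day": day, "user_id": s_user[idx],
            "timestamp": ts, "clicked": clicked, "score": s_score[idx],
        }))
    if not parts:
        return pd.DataFrame(
            columns=["ad_id", "day", "user_id", "timestamp", "clicked", "score"])
    return pd.concat(parts, ignore_index=True)


# --------------------------------------------------------------------------
# coupled logistic maps (benchmark for the causality module)


@dataclass(frozen=True)
class CoupledMapPair:
    """Two coupled logistic-map series.

    ``beta_xy`` is the strength of y's influence on x (it multiplies y inside
    x's update), and ``beta_yx`` the strength of x's influence on y:

        x[t+1] = x[t] * (r_x - r_x*x[t] - beta_xy*y[t])
        y[t+1] = y[t] * (r_y - r_y*y[t] - beta_yx*x[t])
    """

    x: np.ndarray
    y: np.ndarray
    beta_xy: float
    beta_yx: float
    r_x: float
    r_y: float
    seed: int


def coupled_logistic(n: int, beta_xy: float = 0.0, beta_yx: float = 0.0,
                     r_x: float = 3.8, r_y: float = 3.5, seed: int = 0,
                     burn_in: int = 300) -> CoupledMapPair:
    """Generate the classic coupled logistic benchmark pair (values in (0, 1))."""
    if n < 100:
        raise ValueError(f"n must be >= 100, got {n}")
    for name, b in (("beta_xy", beta_xy), ("beta_yx", beta_yx)):
        if not 0.0 <= b < 1.0:
            raise ValueError(f"{name} must be in [0, 1), got {b}")
    rng = np.random.default_rng(seed)
    x = np.empty(n + burn_in)
    y = np.empty(n + burn_in)
    x[0] = rng.uniform(0.2, 0.8)
    y[0] = rng.uniform(0.2, 0.8)
    for t in range(n + burn_in - 1):
        x[t + 1] = x[t] * (r_x - r_x * x[t] - beta_xy * y[t])
        y[t + 1] = y[t] * (r_y - r_y * y[t] - beta_yx * x[t])
        if not (0.0 < x[t + 1] < 1.0 and 0.0 < y[t + 1] < 1.0):
            raise ValueError(
                "coupled logistic map left (0, 1); lower the growth rates or coupling")
    return CoupledMapPair(x=x[burn_in:], y=y[burn_in:], beta_xy=beta_xy,
                          beta_yx=beta_yx, r_x=r_x, r_y=r_y, seed=seed)


# --------------------------------------------------------------------------
# plain-file writers


def write_bundle(bundle: CohortBundle, out_dir: str | Path) -> dict[str, str]:
    """Write cohort streams as plain files; returns {stream: path}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    ann = bundle.annotations.copy()
    ann["timestamp"] = pd.to_datetime(ann["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    p = out / "annotations.csv"
    ann.to_csv(p, index=False)
    paths["annotations"] = str(p)

    p = out / "sensor_frames.csv"
    bundle.sensor_frames.to_csv(p, index=False)
    paths["sensor_frames"] = str(p)

    p = out / "queries.jsonl"
    with open(p, "w") as fh:
        for row in bundle.queries.itertuples(index=False):
            fh.write(json.dumps({
                "user_id": int(row.user_id),
                "timestamp": pd.Timestamp(row.timestamp).isoformat(),
                "tokens": list(row.tokens),
            }) + "\n")
    paths["queries"] = str(p)

    p = out / "region_map.csv"
    bundle.regions().rename_axis("user_id").reset_index().to_csv(p, index=False)
    paths["region_map"] = str(p)
    return paths
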