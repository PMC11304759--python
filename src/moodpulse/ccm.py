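"""Convergent cross-mapping and empirical dynamic modelling.

Implements the causality-analysis chain for a pair of population time
series (here: nationwide mood score vs daily epidemic case counts):

1. ``smooth_standardize`` — 7-day trailing moving average, then z-scoring to
   exactly mean 0 / sd 1.
2. ``simplex_projection`` — time-delay (Takens) embedding and
   nearest-neighbor forecasting to choose the embedding dimension E by
   minimum forecast RMSE; ``smap_test`` then probes state-dependent
   (nonlinear) dynamics with locally weighted linear forecasts.
3. ``ccm_skill`` — convergent cross-mapping: the skill of predicting series
   B from the reconstructed attractor of series A, as a function of library
   size L. Convergent skill in "A xmap B" indicates that B influences A's
   dynamics (B's signature is written into A's attractor).

Nearest-neighbor searches exclude temporal neighbors within a Theiler
window (default = tau) so trivially autocorrelated points cannot serve as
dynamical neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

__all__ = [
    "StandardizedSeries",
    "SimplexResult",
    "SMapResult",
    "CCMResult",
    "smooth_standardize",
    "embed",
    "simplex_projection",
    "smap_test",
    "ccm_skill",
    "ccm_both_directions",
    "default_e_max",
]

_EPS = 1e-12


# --------------------------------------------------------------------------
# step 1: smoothing and standardization


@dataclass
class StandardizedSeries:
    """A smoothed, z-scored series plus provenance."""

    values: np.ndarray
    window: int
    raw_length: int
    name: str = ""

    def __len__(self) -> int:
        return len(self.values)


def smooth_standardize(raw, window: int = 7, center: bool = False,
                       name: str = "") -> StandardizedSeries:
    """Moving-average low-pass filter followed by exact z-scoring.

    The default trailing window matches real-time surveillance semantics
    (the smoothed value at t uses days t-window+1 .. t); ``center=True``
    gives the centered variant. Output length is ``len(raw) - window + 1``
    and has mean 0, sd 1 to machine precision (population sd, ddof=0).
    """
    x = np.asarray(pd.Series(raw).to_numpy(), dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(x) <= window:
        raise ValueError(f"series length {len(x)} must exceed window {window}")
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values")
    kernel = np.ones(window) / window
    smoothed = np.convolve(x, kernel, mode="valid")  # same for trailing/centered values
    sd = smoothed.std()
    if sd < _EPS:
        raise ValueError("series is constant after smoothing; cannot standardize")
    z = (smoothed - smoothed.mean()) / sd
    return StandardizedSeries(values=z, window=window, raw_length=len(x), name=name)


# --------------------------------------------------------------------------
# embedding


def embed(series, E: int, tau: int = 1) -> np.ndarray:
    """Time-delay embedding: point t = (x_t, x_{t-tau}, ..., x_{t-(E-1)tau}).

    Returns an array of shape (len(x) - (E-1)*tau, E); row i corresponds to
    original time index i + (E-1)*tau.
    """
    x = _values(series)
    if E < 1 or tau < 1:
        raise ValueError("E and tau must be >= 1")
    min_len = (E - 1) * tau + 1
    if len(x) < min_len:
        raise ValueError(f"series of length {len(x)} too short for E={E}, tau={tau}; "
                         f"need at least {min_len}")
    # column j holds x_{t - j*tau}; column 0 is the current value x_t
    return np.column_stack(
        [x[(E - 1 - j) * tau: len(x) - j * tau] for j in range(E)])


def _values(series) -> np.ndarray:
    if isinstance(series, StandardizedSeries):
        return series.values
    return np.asarray(pd.Series(series).to_numpy(), dtype=float)


def default_e_max(n: int) -> int:
    """Largest embedding dimension scanned by default: floor(sqrt(n))."""
    return max(1, int(np.floor(np.sqrt(n))))


# --------------------------------------------------------------------------
# simplex projection


@dataclass
class SimplexResult:
    """Leave-one-out simplex forecast error per embedding dimension."""

    table: pd.DataFrame  # columns E, rmse, rho
    best_e: int  # argmin RMSE; ties -> smallest E
    tau: int
    horizon: int


def _simplex_weights(dists: np.ndarray) -> np.ndarray:
    """Exponential simplex weights exp(-d/d_min); uniform when d_min == 0."""
    d_min = dists[..., :1]
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.exp(-dists / np.maximum(d_min, _EPS))
    zero_min = (d_min <= _EPS).ravel()
    if zero_min.any():
        w[zero_min] = 1.0
    return w / w.sum(axis=-1, keepdims=True)


def _loo_simplex_forecast(points: np.ndarray, targets: np.ndarray, k: int,
                          exclusion: int) -> np.ndarray:
    """Forecast each target from its k nearest embedded neighbors (leave-one-out).

    ``points[i]`` is the embedded state whose future value is ``targets[i]``;
    neighbors within ``exclusion`` time steps of i (including i itself) are
    excluded. Returns predictions aligned with targets.
    """
    n = len(points)
    if n <= k + 2 * exclusion:
        raise ValueError("not enough points for the requested neighbor count")
    D = cdist(points, points)
    idx = np.arange(n)
    mask = np.abs(idx[:, None] - idx[None, :]) <= exclusion
    D[mask] = np.inf

    nbr = np.argpartition(D, k - 1, axis=1)[:, :k]
    nd = np.take_along_axis(D, nbr, axis=1)
    order = np.argsort(nd, axis=1, kind="stable")
    nbr = np.take_along_axis(nbr, order, axis=1)
    nd = np.take_along_axis(nd, order, axis=1)
    w = _simplex_weights(nd)
    return (w * targets[nbr]).sum(axis=1)


def simplex_projection(series, e_values=None, tau: int = 1, horizon: int = 1,
                       exclusion: int | None = None) -> SimplexResult:
    """Choose the embedding dimension by leave-one-out simplex forecast RMSE.

    For each E, every embedded point is forecast ``horizon`` steps ahead from
    its E+1 nearest neighbors (exponential distance weights, temporal
    exclusion radius ``exclusion``, default tau). The selected E minimizes
    RMSE; ties resolve to the smallest E. ``rho`` is the Pearson correlation
    between forecasts and observations, reported for reference.
    """
    x = _values(series)
    n = len(x)
    if e_values is None:
        e_values = range(1, default_e_max(n) + 1)
    excl = tau if exclusion is None else exclusion

    rows = []
    for E in e_values:
        pts = embed(x, E, tau)
        # usable forecast origins: those with a target horizon steps ahead
        usable = len(pts) - horizon
        if usable <= (E + 1) + 2 * excl + 1:
            continue
        origins = pts[:usable]
        targets = x[(E - 1) * tau + horizon:][:usable]
        pred = _loo_simplex_forecast(origins, targets, k=E + 1, exclusion=excl)
        rmse = float(np.sqrt(np.mean((pred - targets) ** 2)))
        rho = (float(pearsonr(pred, targets)[0])
               if np.ptp(pred) > 0 and np.ptp(targets) > 0 else np.nan)
        rows.append({"E": E, "rmse": rmse, "rho": rho})
    if not rows:
        raise ValueError("series too short for any requested embedding dimension")
    table = pd.DataFrame(rows)
    best_e = int(table.loc[table["rmse"].idxmin(), "E"])
    return SimplexResult(table=table, best_e=best_e, tau=tau, horizon=horizon)


# --------------------------------------------------------------------------
# s-map nonlinearity test


@dataclass
class SMapResult:
    """Forecast skill across the state-dependence (nonlinearity) grid."""

    table: pd.DataFrame  # columns theta, rho, rmse
    nonlinear: bool
    margin: float  # documented skill-gain threshold
    best_theta: float


def smap_test(series, E: int, thetas=(0.0, 0.1, 0.3, 0.5, 0.75, 1.0, 1.5, 2.0,
                                      3.0, 4.0),
              tau: int = 1, horizon: int = 1, exclusion: int | None = None,
              margin: float = 0.02, ridge: float = 1e-8) -> SMapResult:
    """S-map nonlinearity test at fixed E.

    For each theta, every point is forecast by a locally weighted linear
    model over all other points (weights exp(-theta * d / d_mean), leave-one-
    out with temporal exclusion). Verdict "nonlinear" iff the best skill at
    theta > 0 exceeds the skill of the global linear model (theta = 0) by
    ``margin``. Singular local regressions fall back to a small ridge.
    """
    thetas = np.asarray(sorted(set(float(t) for t in thetas)))
    if not (thetas >= 0).all():
        raise ValueError("thetas must be >= 0")
    if not (thetas > 0).any():
        raise ValueError("theta grid must include at least one value > 0")
    if 0.0 not in thetas:
        raise ValueError("theta grid must include 0 (the linear reference)")

    x = _values(series)
    excl = tau if exclusion is None else exclusion
    pts = embed(x, E, tau)
    usable = len(pts) - horizon
    origins = pts[:usable]
    targets = x[(E - 1) * tau + horizon:][:usable]
    n = len(origins)
    if n < 4 * (E + 2):
        raise ValueError("series too short for s-map at this E")

    D = cdist(origins, origins)
    idx = np.arange(n)
    loo_mask = np.abs(idx[:, None] - idx[None, :]) <= excl

    A_full = np.column_stack([origins, np.ones(n)])
    rows = []
    for theta in thetas:
        preds = np.empty(n)
        for i in range(n):
            keep = ~loo_mask[i]
            d = D[i, keep]
            d_mean = d.mean()
            w = np.exp(-theta * d / max(d_mean, _EPS))
            A = A_full[keep] * w[:, None]
            b = targets[keep] * w
            # ridge-regularized normal equations; singular fits are the
            # reason for the ridge term
            G = A.T @ A + ridge * np.eye(E + 1)
            coef = np.linalg.solve(G, A.T @ b)
            preds[i] = A_full[i] @ coef
        rmse = float(np.sqrt(np.mean((preds - targets) ** 2)))
        rho = (float(pearsonr(preds, targets)[0])
               if np.ptp(preds) > 0 and np.ptp(targets) > 0 else np.nan)
        rows.append({"theta": float(theta), "rho": rho, "rmse": rmse})
    table = pd.DataFrame(rows)

    rho0 = float(table.loc[table["theta"] == 0.0, "rho"].iloc[0])
    pos = table.loc[table["theta"] > 0.0]
    best = pos.loc[pos["rho"].idxmax()]
    nonlinear = bool(best["rho"] - rho0 > margin)
    return SMapResult(table=table, nonlinear=nonlinear, margin=margin,
                      best_theta=float(best["theta"]))


# --------------------------------------------------------------------------
# convergent cross-mapping


@dataclass
class CCMResult:
    """Cross-map skill rho(L) for one direction ("A xmap B": A's attractor
    predicts B; skill indicates B influences A)."""

    direction: str
    lib_sizes: np.ndarray
    rho_mean: np.ndarray
    rho_draws: list[np.ndarray]  # per L, the rho of each library draw
    convergent: bool
    delta_rho: float  # mean rho(L_max) - mean rho(L_min)
    delta_ci: tuple[float, float]  # bootstrap 95% CI of delta_rho

    @property
    def rho_at_max_l(self) -> float:
        return float(self.rho_mean[-1])

    def to_frame(self) -> pd.DataFrame:
        lo = [np.quantile(d, 0.025) for d in self.rho_draws]
        hi = [np.quantile(d, 0.975) for d in self.rho_draws]
        return pd.DataFrame({"direction": self.direction, "L": self.lib_sizes,
                             "rho_mean": self.rho_mean, "rho_lo": lo, "rho_hi": hi})


def _cross_map_rho(points: np.ndarray, target: np.ndarray, lib_idx: np.ndarray,
                   k: int, exclusion: int) -> float:
    """Skill of predicting ``target`` at every point from neighbors in the library."""
    D = cdist(points, points[lib_idx])
    t_idx = np.arange(len(points))[:, None]
    D[np.abs(t_idx - lib_idx[None, :]) <= exclusion] = np.inf

    nbr = np.argpartition(D, k - 1, axis=1)[:, :k]
    nd = np.take_along_axis(D, nbr, axis=1)
    order = np.argsort(nd, axis=1, kind="stable")
    nbr = np.take_along_axis(nbr, order, axis=1)
    nd = np.take_along_axis(nd, order, axis=1)

    valid = np.isfinite(nd).all(axis=1)
    if valid.sum() < 3:
        return np.nan
    w = _simplex_weights(nd[valid])
    pred = (w * target[lib_idx][nbr[valid]]).sum(axis=1)
    obs = target[valid]
    if np.ptp(pred) <= 0 or np.ptp(obs) <= 0:
        return 0.0
    return float(pearsonr(obs, pred)[0])


def ccm_skill(a, b, E: int = 2, tau: int = 1, lib_sizes=None, n_draws: int = 100,
              seed: int = 0, exclusion: int | None = None,
              direction: str = "A xmap B", min_skill: float = 0.1) -> CCMResult:
    """Cross-map skill of predicting ``b`` from ``a``'s attractor vs library size.

    Libraries are contiguous random segments of the embedded series of
    ``a``; for each library size L, ``n_draws`` segments are drawn and the
    cross-map skill rho (Pearson correlation of observed vs predicted b)
    averaged. Convergence verdict: mean rho at L_max exceeds mean rho at
    L_min with the bootstrap 95% CI of the difference excluding 0, *and*
    rho at L_max reaches ``min_skill`` (a minimal-skill floor so that a
    statistically positive but negligible rise in near-zero skill is not
    called causal).
    """
    xa = _values(a)
    xb = _values(b)
    if len(xa) != len(xb):
        raise ValueError("series must have equal length")
    excl = tau if exclusion is None else exclusion
    pts = embed(xa, E, tau)
    n_pts = len(pts)
    target = xb[(E - 1) * tau:]  # aligned with embedded points

    if lib_sizes is None:
        lo = max(E + 2 + 2 * excl, 10)
        lib_sizes = np.unique(np.linspace(lo, n_pts, 8).astype(int))
    lib_sizes = np.asarray(sorted(set(int(v) for v in lib_sizes)))
    if lib_sizes[-1] > n_pts:
        raise ValueError(f"largest library size {lib_sizes[-1]} exceeds the "
                         f"{n_pts} available embedded points")
    if lib_sizes[0] < E + 2:
        raise ValueError("smallest library size too small for E+1 neighbors")

    rng = np.random.default_rng(seed)
    k = E + 1
    rho_draws: list[np.ndarray] = []
    for L in lib_sizes:
        draws = np.empty(n_draws)
        for d in range(n_draws):
            start = rng.integers(0, n_pts - L + 1)
            lib_idx = np.arange(start, start + L)
            draws[d] = _cross_map_rho(pts, target, lib_idx, k, excl)
        rho_draws.append(draws)
    rho_mean = np.array([np.nanmean(d) for d in rho_draws])

    delta_rho = float(rho_mean[-1] - rho_mean[0])
    boot = np.empty(1000)
    flat_max, flat_min = rho_draws[-1], rho_draws[0]
    for i in range(1000):
        boot[i] = (np.nanmean(rng.choice(flat_max, len(flat_max)))
                   - np.nanmean(rng.choice(flat_min, len(flat_min))))
    ci = (float(np.quantile(boot, 0.025)), float(np.quantile(boot, 0.975)))
    convergent = delta_rho > 0 and ci[0] > 0 and rho_mean[-1] >= min_skill
    return CCMResult(direction=direction, lib_sizes=lib_sizes, rho_mean=rho_mean,
                     rho_draws=rho_draws, convergent=convergent,
                     delta_rho=delta_rho, delta_ci=ci)


def ccm_both_directions(a, b, names: tuple[str, str] = ("A", "B"),
                        **kwargs) -> dict[str, CCMResult]:
    """Run CCM in both directions; keys are '<X> xmap <Y>' labels."""
    na, nb = names
    fwd = f"{na} xmap {nb}"
    rev = f"{nb} xmap {na}"
    return {
        fwd: ccm_skill(a, b, direction=fwd, **kwargs),
        rev: ccm_skill(b, a, direction=rev, **kwargs),
    }
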