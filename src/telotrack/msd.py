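"""Time-averaged MSD estimation and diffusion-model fitting.

Two MSD normalizations are provided.  "standard" divides the sum of squared
displacements at lag n by the number of observed displacement pairs.
"literal" reproduces the normalization 1/(N-1-n) over start indices
i = 0..N-2-n (one fewer than the N-n available pairs); for gap-free
trajectories this matches the printed estimator exactly, and the difference
vanishes for large N.

Fitted models (MSD in um^2, t in s):

* anomalous:  MSD(t) = 4 D_alpha t^alpha
* confined :  MSD(t) = A (1 - e^(-t/tau)) + 4 D_macro t,
  with derived D_micro = A / (4 tau) and confinement size L = sqrt(A / 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .models import UM2_PER_NM2, Trajectory

__all__ = [
    "MSDCurve",
    "AnomalousFit",
    "ConfinedFit",
    "compute_msd",
    "ensemble_msd",
    "fit_anomalous",
    "fit_confined",
    "alpha_distribution",
    "compare_groups",
]

#: default cap on the number of lags entering a fit
MIN_FIT_LAGS = 5
MAX_FIT_LAGS = 60


@dataclass
class MSDCurve:
    """Time-averaged MSD of one trajectory (or an ensemble mean).

    lags : lag times n * dt (s), strictly increasing, starting at dt.
    msd : MSD per lag, um^2.
    n_pairs : displacement pairs averaged per lag (for an ensemble curve,
        the number of contributing trajectories).
    se : per-lag standard error (ensemble curves only).
    """

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    dt: float
    traj_id: object = None
    se: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("msd must be >= 0")


@dataclass
class AnomalousFit:
    """4 D_alpha t^alpha least-squares fit."""

    D_alpha: float
    alpha: float
    rss: float
    n_points: int
    converged: bool = True

    def __post_init__(self) -> None:
        if self.D_alpha < 0:
            raise ValueError("D_alpha must be >= 0")
        if not (0 < self.alpha <= 2):
            raise ValueError("alpha must lie in (0, 2]")


@dataclass
class ConfinedFit:
    """A (1 - e^(-t/tau)) + 4 D_macro t least-squares fit with derived terms."""

    A: float
    tau: float
    D_macro: float
    rss: float
    n_points: int
    converged: bool = True
    D_micro: float = field(init=False)
    L: float = field(init=False)

    def __post_init__(self) -> None:
        if self.A < 0 or self.tau <= 0 or self.D_macro < 0:
            raise ValueError("require A >= 0, tau > 0, D_macro >= 0")
        self.D_micro = self.A / (4.0 * self.tau)
        self.L = float(np.sqrt(self.A / 2.0))


def compute_msd(trajectory: Trajectory, max_lag_frames: Optional[int] = None,
                mode: str = "standard") -> MSDCurve:
    """Time-averaged MSD over all observed frame pairs at each lag.

    Pairs are formed only between observed frames (no interpolation); lags
    with zero pairs are omitted ("literal" mode additionally omits lags whose
    printed denominator N-1-n is zero).
    """
    if mode not in ("standard", "literal"):
        raise ValueError("mode must be 'standard' or 'literal'")
    n = trajectory.n_total_frames
    if trajectory.n_present < 2:
        raise ValueError("trajectory must have at least 2 present frames")
    if max_lag_frames is None:
        max_lag_frames = n - 1
    if max_lag_frames >= n:
        raise ValueError("max_lag_frames must be < n_total_frames")
    full = np.full((n, 2), np.nan)
    full[trajectory.frames] = trajectory.positions
    lags, msds, counts = [], [], []
    for lag in range(1, max_lag_frames + 1):
        diff = full[lag:] - full[:-lag]
        if mode == "literal":
            # start indices 0..N-2-lag only, denominator N-1-lag
            denom = n - 1 - lag
            if denom <= 0:
                continue
            diff = diff[:denom]
            sq = np.einsum("ij,ij->i", diff, diff)
            valid = ~np.isnan(sq)
            if not valid.any():
                continue
            value = np.sum(sq[valid]) / denom
            count = int(valid.sum())
        else:
            sq = np.einsum("ij,ij->i", diff, diff)
            valid = ~np.isnan(sq)
            count = int(valid.sum())
            if count == 0:
                continue
            value = np.sum(sq[valid]) / count
        lags.append(lag * trajectory.dt)
        msds.append(value * UM2_PER_NM2)
        counts.append(count)
    return MSDCurve(np.asarray(lags), np.asarray(msds), np.asarray(counts),
                    trajectory.dt, traj_id=trajectory.traj_id)


def ensemble_msd(curves: Sequence[MSDCurve]) -> MSDCurve:
    """Unweighted per-lag mean over trajectories, with SE = SD / sqrt(count).

    Lags reported by fewer than 2 trajectories are omitted; all curves must
    share the same frame interval.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 curves")
    dts = {c.dt for c in curves}
    if len(dts) != 1:
        raise ValueError("curves have mixed frame intervals")
    dt = dts.pop()
    values: dict[int, list[float]] = {}
    for c in curves:
        for lag, m in zip(c.lags, c.msd):
            values.setdefault(int(round(lag / dt)), []).append(m)
    lags, mean, se, count = [], [], [], []
    for lag_frames in sorted(values):
        v = np.asarray(values[lag_frames])
        if len(v) < 2:
            continue
        lags.append(lag_frames * dt)
        mean.append(v.mean())
        se.append(v.std(ddof=1) / np.sqrt(len(v)))
        count.append(len(v))
    return MSDCurve(np.asarray(lags), np.asarray(mean), np.asarray(count), dt,
                    traj_id="ensemble", se=np.asarray(se))


def _fit_lag_count(n_lags: int, fit_fraction: float,
                   max_lags: int = MAX_FIT_LAGS) -> int:
    k = max(MIN_FIT_LAGS, min(int(round(n_lags * fit_fraction)), max_lags))
    return min(k, n_lags)


def _anomalous_model(t, d, a):
    return 4.0 * d * t ** a


def fit_anomalous(msd_curve: MSDCurve, fit_fraction: float = 0.25,
                  max_lags: int = MAX_FIT_LAGS) -> AnomalousFit:
    """Nonlinear least squares of 4 D_alpha t^alpha on linear MSD values.

    The fit uses the first ``fit_fraction`` of available lags (at least 5,
    at most ``max_lags``); starting values come from a log-log linear
    regression.  Bounds: D_alpha >= 0, alpha in (0, 2].  On non-convergence
    the log-log values are returned with ``converged=False``.
    """
    n_fit = _fit_lag_count(len(msd_curve.lags), fit_fraction, max_lags)
    if n_fit < MIN_FIT_LAGS:
        raise ValueError(f"need at least {MIN_FIT_LAGS} lags to fit")
    t = msd_curve.lags[:n_fit]
    y = msd_curve.msd[:n_fit]
    if np.all(y == 0):
        raise ValueError("MSD is identically zero; alpha is undefined")
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(np.log(t[pos]), np.log(y[pos]), 1)
        a0 = float(np.clip(slope, 0.01, 2.0))
        d0 = float(np.exp(intercept) / 4.0)
    else:
        a0, d0 = 1.0, max(y.max(), 1e-12)
    try:
        popt, _ = optimize.curve_fit(
            _anomalous_model, t, y, p0=(max(d0, 1e-12), a0),
            bounds=([0.0, 1e-6], [np.inf, 2.0]), maxfev=5000,
        )
        d_hat, a_hat = float(popt[0]), float(popt[1])
        converged = True
    except RuntimeError:
        d_hat, a_hat, converged = max(d0, 0.0), a0, False
    rss = float(np.sum((y - _anomalous_model(t, d_hat, a_hat)) ** 2))
    return AnomalousFit(d_hat, min(a_hat, 2.0), rss, n_fit, converged)


def _confined_model(t, a, tau, d):
    return a * (1.0 - np.exp(-t / tau)) + 4.0 * d * t


def fit_confined(msd_curve: MSDCurve, fit_fraction: float = 0.25,
                 max_lags: int = MAX_FIT_LAGS) -> ConfinedFit:
    """Nonlinear least squares of A (1 - e^(-t/tau)) + 4 D_macro t.

    Multi-start initialization: tau from the curve half-rise and a coarse
    grid, A from the late plateau after removing the tail slope, D_macro
    from the tail slope.  Bounds: A >= 0, tau > 0, D_macro >= 0.  Degenerate
    (purely linear) curves come back with A ~ 0 and a warning.
    """
    n_fit = _fit_lag_count(len(msd_curve.lags), fit_fraction, max_lags)
    if n_fit < 6:
        raise ValueError("need at least 6 lags to fit the confined model")
    t = msd_curve.lags[:n_fit]
    y = msd_curve.msd[:n_fit]
    n_tail = max(n_fit // 4, 2)
    slope_tail = max(
        float(np.polyfit(t[-n_tail:], y[-n_tail:], 1)[0]), 0.0)
    d0 = slope_tail / 4.0
    a0 = max(float(np.mean(y[-n_tail:]) - slope_tail * np.mean(t[-n_tail:])), 1e-12)
    half = a0 / 2.0
    above = np.flatnonzero(y - 4.0 * d0 * t >= half)
    tau_half = t[above[0]] / np.log(2.0) if len(above) else t[n_fit // 2]
    tau_grid = {max(tau_half, t[0]), t[0], t[-1] / 4.0, t[-1]}
    best = None
    for tau0 in sorted(tau_grid):
        try:
            popt, _ = optimize.curve_fit(
                _confined_model, t, y, p0=(a0, tau0, d0),
                bounds=([0.0, 1e-9, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=5000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((y - _confined_model(t, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        warnings.warn("confined fit failed to converge; returning initial guess",
                      stacklevel=2)
        return ConfinedFit(a0, max(tau_half, t[0]), d0,
                           float(np.sum((y - _confined_model(t, a0, tau_half, d0)) ** 2)),
                           n_fit, converged=False)
    (a_hat, tau_hat, d_hat), rss = best
    if a_hat < 1e-6 * max(y.max(), 1e-30):
        warnings.warn("confined fit is degenerate (A ~ 0); the curve is "
                      "essentially linear and D_macro carries the slope",
                      stacklevel=2)
    return ConfinedFit(float(a_hat), float(tau_hat), float(d_hat), rss, n_fit)


def alpha_distribution(fits: Sequence[AnomalousFit],
                       group_labels: Sequence[object]) -> dict:
    """Per-group alpha summaries: values, mean, SD, SE and fixed-bin histogram.

    Histogram bins span [0, 2] with width 0.1.  Groups with a single fit get
    ``se=None``; empty groups are omitted with a warning.
    """
    if len(fits) != len(group_labels):
        raise ValueError("fits and group_labels must have equal length")
    bins = np.round(np.arange(0.0, 2.0 + 0.1, 0.1), 10)
    groups: dict[object, list[float]] = {}
    for f, g in zip(fits, group_labels):
        groups.setdefault(g, []).append(f.alpha)
    out = {}
    for g in groups:
        v = np.asarray(groups[g])
        if len(v) == 0:
            warnings.warn(f"group {g!r} is empty; omitted", stacklevel=2)
            continue
        out[g] = {
            "alphas": v,
            "n": len(v),
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if len(v) > 1 else None,
            "se": float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else None,
            "hist": np.histogram(v, bins=bins)[0],
            "bin_edges": bins,
        }
    return out


def compare_groups(values_a: Sequence[float],
                   values_b: Sequence[float]) -> tuple[float, float, float]:
    """Two-sided Welch t-test; returns (t, df, p).

    Two zero-variance groups with equal means give t = 0, p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf,
                float(len(a) + len(b) - 2), 0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
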