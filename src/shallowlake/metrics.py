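"""Skill metrics for tipping-point prediction.

RMSE and relative RMSE of assimilated phosphorus trajectories, the
probability of eutrophication of a posterior ensemble, the point of no
return of a loading strategy, kernel-density posterior summaries,
log-likelihood surfaces over the (b, q) plane, and ensemble confidence
bands.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.stats import gaussian_kde, norm

from .lake import (
    LakeParams,
    Trajectory,
    critical_threshold,
    critical_thresholds,
    simulate_members,
    simulate_trajectory,
)
from .synthetic import Ensemble, ObservationSeries

__all__ = [
    "SkillReport",
    "DensityCurve",
    "rmse",
    "relative_rmse",
    "probability_of_eutrophication",
    "point_of_no_return",
    "posterior_density",
    "likelihood_surface",
    "top_decile_area",
    "confidence_band",
]

logger = logging.getLogger(__name__)

#: Settling horizon (years) for deciding which attractor a zero-emission
#: trajectory converges to.
SETTLE_YEARS = 1000


def _values(x) -> np.ndarray:
    return np.asarray(getattr(x, "values", x), dtype=float)


def rmse(estimate, reference) -> float:
    """Root mean squared error between two equally long series."""
    a, b = _values(estimate), _values(reference)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def relative_rmse(forecast_mean, obs: ObservationSeries, reference=None) -> float:
    """RMSE of the yearly forecast mean, scaled by the observed mean level.

    Parameters
    ----------
    forecast_mean : array-like, length T
        One-step-ahead ensemble-mean forecast of phosphorus for years 1..T.
    obs : ObservationSeries
        The assimilated observations; their mean is the denominator.
    reference : Trajectory or array-like, optional
        Error reference.  By default the observations themselves; pass
        the assumed-truth trajectory to measure error against the truth
        instead (the two conventions differ by roughly the measurement
        noise floor).
    """
    f = _values(forecast_mean)
    denom = float(np.mean(obs.values))
    if denom == 0:
        raise ValueError("observed mean is zero; relative RMSE undefined")
    if reference is None:
        ref = obs.values
    else:
        ref = _values(reference)
        if len(ref) == len(f) + 1:  # a full trajectory incl. year 0
            ref = ref[1:]
    return rmse(f, ref) / denom


def _member_thresholds(b, q, true_threshold: float | None) -> np.ndarray:
    if true_threshold is not None:
        return np.full(np.shape(b), float(true_threshold))
    thr = critical_thresholds(b, q)
    n_mono = int(np.isnan(thr).sum())
    if n_mono:
        # Monostable members inside the physical bounds have only the
        # oligotrophic attractor at zero loading: no irreversible
        # threshold exists, so they never diagnose eutrophication.
        logger.info("%d monostable members classified as non-eutrophic", n_mono)
        thr = np.where(np.isnan(thr), np.inf, thr)
    return thr


def probability_of_eutrophication(
    posterior: Ensemble,
    schedule,
    T: int | None = None,
    t_learn: int | None = None,
    true_threshold: float | None = None,
) -> float:
    """Weighted fraction of members whose projection to year T is eutrophic.

    Each member (x_t, b, q) is simulated forward from the learning time
    under the remaining schedule; it predicts eutrophication iff its
    year-T phosphorus exceeds its own critical threshold P_crit(b, q)
    (or ``true_threshold`` when provided).  Members whose parameters make
    the lake monostable have no irreversible threshold and are counted
    as non-eutrophic.
    """
    if posterior.alive_count == 0:
        raise ValueError("posterior ensemble has no alive members")
    sched = _values(schedule)
    if T is None:
        T = len(sched)
    if t_learn is None:
        t_learn = posterior.t
    if t_learn >= T + 1:
        raise ValueError("learning time must precede the horizon end")
    remaining = sched[t_learn:T]
    paths = simulate_members(posterior.x, posterior.b, posterior.q, remaining)
    x_final = paths[-1]
    thr = _member_thresholds(posterior.b, posterior.q, true_threshold)
    eutrophic = x_final > thr
    w = posterior.weights / posterior.weights.sum()
    return float(w @ eutrophic)


def point_of_no_return(x0: float, params: LakeParams, schedule, cross_check: bool = True):
    """First year from which ceasing all emissions no longer averts
    eutrophication; None if the strategy never commits the lake.

    Operationally this is the first year the trajectory exceeds P_crit;
    with ``cross_check`` the general definition — simulate from every
    yearly state with all future emissions zeroed and test which
    attractor it settles on — is evaluated too and must agree.
    """
    pcrit = critical_threshold(params)
    traj = simulate_trajectory(x0, params, schedule)
    above = np.nonzero(traj.values > pcrit)[0]
    shortcut = int(above[0]) if len(above) else None

    if cross_check:
        zero = np.zeros(SETTLE_YEARS)
        settled = simulate_members(traj.values, params.b, params.q, zero)[-1]
        committed = np.nonzero(settled > pcrit)[0]
        general = int(committed[0]) if len(committed) else None
        if general != shortcut:
            raise AssertionError(
                f"point-of-no-return definitions disagree: crossing={shortcut}, "
                f"zero-emission simulation={general}"
            )
    return shortcut


class DensityCurve(NamedTuple):
    """A kernel density estimate evaluated on an explicit grid."""

    grid: np.ndarray
    density: np.ndarray

    @property
    def mode(self) -> float:
        return float(self.grid[np.argmax(self.density)])

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def posterior_density(samples, weights=None, grid_size: int = 512) -> DensityCurve:
    """Gaussian-kernel density estimate of a one-dimensional sample set.

    Bandwidth by Scott's rule; the grid spans the samples plus three
    bandwidths on each side.  Degenerate (zero-variance) samples yield a
    narrow spike and a warning.
    """
    s = np.asarray(samples, dtype=float)
    if s.ndim != 1 or len(s) < 10:
        raise ValueError("need a one-dimensional sample set of at least 10 points")
    if np.all(s == s[0]):
        warnings.warn("degenerate (zero-variance) samples; returning a spike")
        h = max(abs(s[0]) * 1e-6, 1e-12)
        grid = np.linspace(s[0] - 6 * h, s[0] + 6 * h, grid_size)
        return DensityCurve(grid, norm.pdf(grid, loc=s[0], scale=h))
    kde = gaussian_kde(s, bw_method="scott", weights=weights)
    h = float(np.sqrt(kde.covariance[0, 0]))  # Scott bandwidth on the data scale
    grid = np.linspace(s.min() - 3 * h, s.max() + 3 * h, grid_size)
    return DensityCurve(grid, kde(grid))


def likelihood_surface(b_grid, q_grid, obs: ObservationSeries, schedule, x0: float) -> np.ndarray:
    """Log-likelihood of the observations over a (b, q) grid at fixed X_0.

    Each grid point is simulated deterministically from ``x0`` and scored
    by the summed Gaussian measurement log-density over all observations.
    Returns an array of shape ``(len(b_grid), len(q_grid))``.
    """
    b_grid = np.asarray(b_grid, dtype=float)
    q_grid = np.asarray(q_grid, dtype=float)
    B, Q = np.meshgrid(b_grid, q_grid, indexing="ij")
    sched = _values(schedule)[: obs.horizon]
    paths = simulate_members(x0, B.ravel(), Q.ravel(), sched)  # (T+1, nb*nq)
    resid = paths[1:] - obs.values[:, None]
    ll = norm.logpdf(resid, scale=np.sqrt(obs.noise_variance)).sum(axis=0)
    return ll.reshape(B.shape)


def top_decile_area(surface: np.ndarray) -> float:
    """Fraction of grid cells whose likelihood is within the top decile of
    the peak, i.e. at least one tenth of the maximum likelihood.

    Operates on log-likelihood surfaces (threshold ``max + ln 0.1``).  A
    sharply peaked surface concentrates this region on a small area; a
    flat ridge spreads it out.  Used to contrast parameter
    identifiability between emission strategies.
    """
    s = np.asarray(surface, dtype=float)
    return float(np.mean(s >= s.max() + np.log(0.1)))


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, qs) -> np.ndarray:
    """Weighted quantiles reducing to numpy's linear interpolation when
    weights are uniform."""
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    total = cw[-1]
    # plotting positions generalising (i-1)/(n-1)
    denom = total - w[-1]
    if denom <= 0:
        return np.full(len(np.atleast_1d(qs)), v[0])
    pos = (cw - w) / denom
    return np.interp(np.atleast_1d(qs), pos, v)


def confidence_band(member_series: np.ndarray, weights=None, level: float = 0.9):
    """Pointwise weighted quantile band of member trajectories.

    Parameters
    ----------
    member_series : array, shape (n_times, n_members)
        One phosphorus (or parameter) path per member.
    weights : array, optional
        Member weights; uniform if omitted.
    level : float
        Band coverage; 0.9 gives the 5th and 95th percentiles.

    Returns
    -------
    (lower, upper) arrays of length n_times.
    """
    m = np.atleast_2d(np.asarray(member_series, dtype=float))
    n = m.shape[1]
    if n < 20:
        warnings.warn(f"confidence band from only {n} members is unreliable")
    if weights is None:
        lo_hi = np.percentile(m, [50 * (1 - level), 50 * (1 + level)], axis=1)
        return lo_hi[0], lo_hi[1]
    w = np.asarray(weights, dtype=float)
    qs = np.array([(1 - level) / 2, (1 + level) / 2])
    out = np.array([_weighted_quantile(row, w, qs) for row in m])
    return out[:, 0], out[:, 1]


@dataclass
class SkillReport:
    """Bundle of skill metrics for one assimilation run."""

    method: str
    rmse: float | None = None
    relative_rmse: float | None = None
    prob_eutrophication: dict[int, float] = field(default_factory=dict)
    point_of_no_return: int | None = None
    densities: dict[str, DensityCurve] = field(default_factory=dict)
    bands: dict[str, tuple] = field(default_factory=dict)
    nfe: int | None = None

    def to_json(self, path=None) -> str:
        payload = {
            "method": self.method,
            "rmse": self.rmse,
            "relative_rmse": self.relative_rmse,
            "prob_eutrophication": {str(k): v for k, v in self.prob_eutrophication.items()},
            "point_of_no_return": self.point_of_no_return,
            "nfe": self.nfe,
            "densities": {
                k: {"grid": list(map(float, d.grid)), "density": list(map(float, d.density))}
                for k, d in self.densities.items()
            },
            "bands": {
                k: {"lower": list(map(float, lo)), "upper": list(map(float, hi))}
                for k, (lo, hi) in self.bands.items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text
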