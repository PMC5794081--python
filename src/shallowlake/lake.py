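"""Deterministic phosphorus dynamics of a bistable shallow lake.

The lake is modelled as a discrete yearly map for the total phosphorus
concentration ``X_t`` (dimensionless)::

    X_{t+1} = X_t - b*X_t + X_t^q / (1 + X_t^q) + a_t

where ``b`` is the loss parameter (sedimentation/outflow), ``q`` the
recycle exponent governing phosphorus release from the sediment, and
``a_t`` the anthropogenic loading in year ``t``.  For suitable ``(b, q)``
the zero-loading map is bistable: a low (oligotrophic) and a high
(eutrophic) stable equilibrium separated by an unstable equilibrium.
That unstable equilibrium is the critical phosphorus threshold
``P_crit`` — once crossed, the lake converges to the eutrophic state
even if all emissions stop (the lake is irreversible).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "LakeParams",
    "Trajectory",
    "Equilibrium",
    "EquilibriumSet",
    "step_phosphorus",
    "simulate_trajectory",
    "simulate_members",
    "find_equilibria",
    "critical_threshold",
    "critical_thresholds",
    "critical_constant_loading",
]

logger = logging.getLogger(__name__)

#: Upper end of the root-search bracket for equilibria.  The eutrophic
#: equilibrium satisfies b*x = x^q/(1+x^q) < 1/b, so for b > 0.1 it lies
#: well below this bound.
ROOT_BRACKET_HIGH = 10.0

B_RANGE = (0.0, 1.0)  # loss parameter, open interval
Q_RANGE = (2.0, 8.0)  # recycle exponent, closed interval


@dataclass(frozen=True)
class LakeParams:
    """Loss and recycle parameters of the lake map.

    Parameters
    ----------
    b : float
        Loss parameter, physically plausible in (0, 1).
    q : float
        Recycle exponent, physically plausible in [2, 8].
    """

    b: float
    q: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.b) or not np.isfinite(self.q):
            raise ValueError("lake parameters must be finite")
        if not (B_RANGE[0] < self.b < B_RANGE[1]):
            raise ValueError(f"loss parameter b={self.b} outside (0, 1)")
        if not (Q_RANGE[0] <= self.q <= Q_RANGE[1]):
            raise ValueError(f"recycle exponent q={self.q} outside [2, 8]")


@dataclass(frozen=True)
class Trajectory:
    """Phosphorus concentrations, one per year t = 0..T."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValueError("trajectory values must be one-dimensional")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("trajectory values must be finite and non-negative")

    @property
    def horizon(self) -> int:
        """Simulation horizon T (number of yearly steps)."""
        return len(self.values) - 1

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, idx):
        return self.values[idx]


@dataclass(frozen=True)
class Equilibrium:
    level: float
    stability: str  # "stable" | "unstable"


@dataclass(frozen=True)
class EquilibriumSet:
    """Roots of the zero-loading fixed-point equation, with stability flags."""

    roots: tuple[Equilibrium, ...] = field(default_factory=tuple)

    @property
    def unstable(self) -> float | None:
        for r in self.roots:
            if r.stability == "unstable":
                return r.level
        return None

    @property
    def stable(self) -> tuple[float, ...]:
        return tuple(r.level for r in self.roots if r.stability == "stable")

    @property
    def is_bistable(self) -> bool:
        return len(self.stable) == 2 and self.unstable is not None


def _recycle(x: np.ndarray, q: np.ndarray) -> np.ndarray:
    xq = np.power(x, q)
    return xq / (1.0 + xq)


def _step_raw(x, b, q, a):
    """One map step, fully vectorised, no validation or clipping."""
    return x - b * x + _recycle(x, q) + a


def step_phosphorus(x: float, params: LakeParams, a: float = 0.0) -> float:
    """Advance the phosphorus level by one year.

    Returns ``x - b*x + x^q/(1+x^q) + a``, clipped at zero (with a log
    message) should rounding ever produce a negative level.
    """
    x = float(x)
    a = float(a)
    if not np.isfinite(x) or not np.isfinite(a):
        raise ValueError("phosphorus level and loading must be finite")
    if x < 0 or a < 0:
        raise ValueError("phosphorus level and loading must be non-negative")
    out = _step_raw(x, params.b, params.q, a)
    if out < 0:
        logger.warning("map produced negative phosphorus %g; clipping to 0", out)
        out = 0.0
    return float(out)


def simulate_trajectory(x0: float, params: LakeParams, schedule) -> Trajectory:
    """Iterate the lake map over an emission schedule.

    Parameters
    ----------
    x0 : float
        Initial phosphorus concentration X_0.
    params : LakeParams
    schedule : array-like or EmissionSchedule
        Yearly loadings a_0..a_{T-1}.

    Returns
    -------
    Trajectory of length T+1 with values[0] = x0.
    """
    a = np.asarray(getattr(schedule, "values", schedule), dtype=float)
    if a.ndim != 1:
        raise ValueError("schedule must be one-dimensional")
    out = np.empty(len(a) + 1)
    out[0] = float(x0)
    x = float(x0)
    for t, at in enumerate(a):
        x = step_phosphorus(x, params, at)
        out[t + 1] = x
    return Trajectory(out)


def simulate_members(x0, b, q, schedule) -> np.ndarray:
    """Vectorised forward simulation of many (x0, b, q) members.

    All of ``x0``, ``b``, ``q`` broadcast to a common shape; returns an
    array of shape ``(T+1,) + shape`` with the phosphorus path of each
    member.  No per-step validation — used internally by the filters and
    metrics where members are already bound-checked.
    """
    a = np.asarray(getattr(schedule, "values", schedule), dtype=float)
    x0, b, q = np.broadcast_arrays(np.asarray(x0, float), np.asarray(b, float), np.asarray(q, float))
    out = np.empty((len(a) + 1,) + x0.shape)
    out[0] = x0
    x = x0.copy()
    for t, at in enumerate(a):
        x = np.maximum(_step_raw(x, b, q, at), 0.0)
        out[t + 1] = x
    return out


def _net_loss(x, b, q):
    """phi(x) = b*x - x^q/(1+x^q); its roots are the zero-loading equilibria."""
    return b * x - _recycle(x, q)


def _map_derivative(x, b, q):
    """d X_{t+1} / d X_t at zero loading."""
    xq = np.power(x, q)
    drecycle = q * np.power(x, q - 1.0) / (1.0 + xq) ** 2
    return 1.0 - b + drecycle


def find_equilibria(params: LakeParams, n_grid: int = 4000) -> EquilibriumSet:
    """All zero-loading equilibria of the map on [0, 10], with stability.

    Roots of ``b*x = x^q/(1+x^q)`` are located by sign changes of
    ``phi(x) = b*x - x^q/(1+x^q)`` on a dense grid followed by Brent's
    method.  A root r is stable iff the magnitude of the map derivative
    ``|1 - b + d/dx x^q/(1+x^q)|`` at r is below 1 (discrete-map
    criterion).
    """
    b, q = params.b, params.q
    roots = [0.0]  # x=0 always solves the fixed-point equation
    xs = np.linspace(1e-9, ROOT_BRACKET_HIGH, n_grid)
    phi = _net_loss(xs, b, q)
    sign = np.sign(phi)
    for i in np.nonzero(np.diff(sign) != 0)[0]:
        lo, hi = xs[i], xs[i + 1]
        try:
            r = brentq(_net_loss, lo, hi, args=(b, q), xtol=1e-14, rtol=1e-15)
        except Exception as exc:  # pragma: no cover - brentq on a sign change
            raise RuntimeError(f"root finding failed on bracket [{lo}, {hi}]") from exc
        roots.append(float(r))
    # drop duplicates from tangencies
    uniq: list[float] = []
    for r in sorted(roots):
        if not uniq or abs(r - uniq[-1]) > 1e-9:
            uniq.append(r)
    eqs = []
    for r in uniq:
        lam = abs(_map_derivative(r, b, q)) if r > 0 else abs(1.0 - b)
        eqs.append(Equilibrium(level=r, stability="stable" if lam < 1.0 else "unstable"))
    return EquilibriumSet(roots=tuple(eqs))


def critical_threshold(params: LakeParams) -> float:
    """Critical phosphorus threshold P_crit: the unstable zero-loading equilibrium.

    Raises
    ------
    ValueError
        If the lake is monostable (no unstable equilibrium, hence no
        irreversible threshold).
    """
    eq = find_equilibria(params)
    if eq.unstable is None:
        raise ValueError(
            f"no critical threshold: lake with b={params.b}, q={params.q} is monostable"
        )
    return eq.unstable


def critical_thresholds(b, q, tol: float = 1e-12) -> np.ndarray:
    """Vectorised P_crit for arrays of (b, q); NaN where the lake is monostable.

    The unstable root of ``b = x^(q-1)/(1+x^q)`` lies on the rising branch
    of the right-hand side, i.e. in ``(0, (q-1)^(1/q))``; a bistable lake
    requires ``b`` below the branch maximum ``(q-1)^((q-1)/q)/q``.  Solved
    by vectorised bisection.
    """
    b = np.asarray(b, dtype=float)
    q = np.asarray(q, dtype=float)
    b, q = np.broadcast_arrays(b, q)
    x_peak = np.power(q - 1.0, 1.0 / q)
    b_max = np.power(q - 1.0, (q - 1.0) / q) / q
    bistable = b < b_max
    lo = np.full(b.shape, 1e-12)
    hi = np.where(bistable, x_peak, 1.0)

    def h(x):
        return np.power(x, q - 1.0) / (1.0 + np.power(x, q))

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        below = h(mid) < b  # root is above mid
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
        if np.all(hi - lo < tol):
            break
    out = 0.5 * (lo + hi)
    return np.where(bistable, out, np.nan)


def critical_constant_loading(params: LakeParams) -> float:
    """Fold-bifurcation loading a*: the largest constant loading with an
    oligotrophic equilibrium.

    Equal to the local maximum of ``phi(x) = b*x - x^q/(1+x^q)`` between
    zero and the unstable equilibrium; for constant ``a < a*`` a low
    stable equilibrium persists, for ``a > a*`` every trajectory is
    attracted to the eutrophic state.
    """
    pcrit = critical_threshold(params)  # raises for monostable lakes
    res = minimize_scalar(
        lambda x: -_net_loss(x, params.b, params.q),
        bounds=(1e-12, pcrit),
        method="bounded",
        options={"xatol": 1e-12},
    )
    if not res.success:  # pragma: no cover
        raise RuntimeError(f"maximisation of the net loss curve failed: {res.message}")
    return float(-res.fun)
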