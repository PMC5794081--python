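"""Anthropogenic phosphorus emission strategies.

Four loading schedules drive the study:

* ``low_constant`` — a constant loading just below the fold bifurcation,
  the highest level that keeps the lake oligotrophic indefinitely;
* ``high_stepwise`` — starts at zero and steps up every 20 years, with a
  single scale factor calibrated so the lake first crosses its critical
  threshold in a prescribed year (default 45);
* ``linear_ramp`` / ``abrupt_step`` — two alternative eutrophying
  strategies: a linear increase over the whole horizon, and a low
  constant loading that jumps to a high level at year 40.

The stepwise/ramp/step magnitudes are not free parameters: each schedule
shape carries one scale factor found by bisection against the crossing
year of the deterministic truth trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lake import LakeParams, critical_constant_loading, critical_threshold, simulate_trajectory

__all__ = [
    "EmissionSchedule",
    "first_crossing_year",
    "make_low_emissions",
    "make_high_emissions_stepwise",
    "make_alternative_strategies",
]

#: Loading scale unit: the calibrated scale factor s in [0, 1] multiplies
#: this maximum yearly loading.  Chosen so a mid-horizon threshold
#: crossing is reachable for the default lake parameters.
MAX_LOADING = 0.3

#: Default margin below the fold loading a* for the low-emissions strategy.
LOW_EMISSIONS_MARGIN = 0.98

#: Default truth initial condition used when calibrating crossing years.
DEFAULT_X0 = 0.05


@dataclass(frozen=True)
class EmissionSchedule:
    """Yearly anthropogenic loadings a_0..a_{T-1}."""

    values: np.ndarray
    label: str = "custom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValueError("schedule values must be one-dimensional")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("loadings must be finite and non-negative")

    @property
    def horizon(self) -> int:
        return len(self.values)

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, idx):
        return self.values[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": np.arange(len(self.values)), "a_t": self.values})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str = "custom") -> "EmissionSchedule":
        df = pd.read_csv(path)
        return cls(values=df["a_t"].to_numpy(), label=label)


def first_crossing_year(x0: float, params: LakeParams, schedule) -> int | None:
    """First year t with X_t above the lake's critical threshold, or None."""
    pcrit = critical_threshold(params)
    traj = simulate_trajectory(x0, params, schedule)
    above = np.nonzero(traj.values > pcrit)[0]
    return int(above[0]) if len(above) else None


def make_low_emissions(
    params: LakeParams,
    T: int = 100,
    margin: float = LOW_EMISSIONS_MARGIN,
) -> EmissionSchedule:
    """Constant loading at ``margin * a*``, just below the fold bifurcation.

    With the default margin the truth trajectory from X_0 = 0.05 stays
    strictly oligotrophic for every horizon.
    """
    if not (0.0 <= margin <= 1.0):
        raise ValueError("margin must lie in [0, 1]")
    a_star = critical_constant_loading(params)
    return EmissionSchedule(np.full(T, margin * a_star), label="low_constant")


def _calibrate_scale(profile: np.ndarray, x0: float, params: LakeParams, target: int) -> float:
    """Find the scale s in [0, 1] so that loading ``s * MAX_LOADING * profile``
    makes the truth first cross P_crit exactly in year ``target``.

    The crossing year is a non-increasing step function of s; bisection
    locates both edges of the s-interval achieving the target year and the
    midpoint is returned (robust, and idempotent across runs).
    """

    def crossing(s: float) -> float:
        c = first_crossing_year(x0, params, s * MAX_LOADING * profile)
        return np.inf if c is None else c

    return _calibrate_scale_fn(crossing, target)


def make_high_emissions_stepwise(
    params: LakeParams,
    T: int = 100,
    step_interval: int = 20,
    target_crossing_year: int = 45,
    x0: float = DEFAULT_X0,
) -> EmissionSchedule:
    """Stepwise-increasing schedule calibrated to eutrophy the lake mid-horizon.

    Starts at zero loading and increases by equal increments at every
    multiple of ``step_interval`` years; a single scale factor applied to
    this profile is calibrated by bisection so the deterministic truth
    first exceeds P_crit exactly in ``target_crossing_year``.
    """
    if T % step_interval != 0:
        raise ValueError("step_interval must divide T")
    if not (step_interval < target_crossing_year < T):
        raise ValueError("target crossing year must lie within (step_interval, T)")
    n_steps = T // step_interval
    t = np.arange(T)
    profile = (t // step_interval) / (n_steps - 1)  # 0, 1/(n-1), ..., 1
    s = _calibrate_scale(profile, x0, params, target_crossing_year)
    return EmissionSchedule(s * MAX_LOADING * profile, label="high_stepwise")


def make_alternative_strategies(
    params: LakeParams,
    T: int = 100,
    target_crossing_year: int = 50,
    switch_year: int = 40,
    x0: float = DEFAULT_X0,
    margin: float = LOW_EMISSIONS_MARGIN,
) -> tuple[EmissionSchedule, EmissionSchedule]:
    """Two alternative eutrophying strategies.

    Returns
    -------
    (ramp, abrupt)
        ``ramp``: loading increasing linearly from zero over the horizon;
        ``abrupt``: low constant loading switching to a high constant at
        ``switch_year``.  Each carries one scale factor calibrated so the
        truth first crosses P_crit in ``target_crossing_year``.
    """
    t = np.arange(T)
    ramp_profile = t / (T - 1)
    s_ramp = _calibrate_scale(ramp_profile, x0, params, target_crossing_year)
    ramp = EmissionSchedule(s_ramp * MAX_LOADING * ramp_profile, label="linear_ramp")

    a_low = margin * critical_constant_loading(params)
    base = np.full(T, a_low)

    def abrupt_profile_scaled(s: float) -> np.ndarray:
        a = base.copy()
        a[switch_year:] = s * MAX_LOADING
        return a

    # reuse the bisection through a profile trick: calibrate on the
    # incremental (above-low) part of the post-switch loading
    step_profile = np.zeros(T)
    step_profile[switch_year:] = 1.0

    def crossing(s: float) -> float:
        c = first_crossing_year(x0, params, base + s * MAX_LOADING * step_profile)
        return np.inf if c is None else c

    s_shift = _calibrate_scale_fn(crossing, target_crossing_year)
    abrupt = EmissionSchedule(base + s_shift * MAX_LOADING * step_profile, label="abrupt_step")
    return ramp, abrupt


def _calibrate_scale_fn(crossing, target: int) -> float:
    """Bisection on an arbitrary crossing-year function of the scale."""
    if crossing(1.0) > target:
        raise ValueError("calibration failed: crossing too late at maximum loading")
    if crossing(0.0) <= target:
        raise ValueError("calibration failed: crossing too early at zero extra loading")

    def edge(pred) -> float:
        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if pred(mid):
                hi = mid
            else:
                lo = mid
        return hi

    s_enter = edge(lambda s: crossing(s) <= target)
    s_exit = edge(lambda s: crossing(s) < target)
    s = 0.5 * (s_enter + s_exit)
    if crossing(s) != target:
        raise ValueError(f"calibration failed: crossing year jumps over {target}")
    return s
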