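"""Synthetic truth, observations and prior ensembles (the study's data supply).

This is a twin experiment: the "assumed truth" is the deterministic lake
trajectory generated from known parameters (b = 0.42, q = 2.00,
X_0 = 0.05), observations are the truth plus i.i.d. Gaussian measurement
noise with variance 0.01, and every estimator starts from the same
deliberately biased lognormal prior over (X_0, b, q) — prior means
(0.20, 0.62, 4.00) imply a lake with a greater capacity to absorb
pollution than it truly has.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lake import B_RANGE, Q_RANGE, LakeParams, Trajectory, simulate_trajectory

__all__ = [
    "TRUTH_PARAMS",
    "TRUTH_X0",
    "MEASUREMENT_VARIANCE",
    "ObservationSeries",
    "LognormalMarginal",
    "PriorSpec",
    "Ensemble",
    "lognormal_underlying_moments",
    "generate_truth",
    "generate_observations",
    "generate_realization_set",
    "sample_prior",
]

#: Assumed-truth lake parameters of the twin experiment.
TRUTH_PARAMS = LakeParams(b=0.42, q=2.00)
#: Assumed-truth initial phosphorus level.
TRUTH_X0 = 0.05
#: Measurement noise variance nu.
MEASUREMENT_VARIANCE = 0.01


@dataclass(frozen=True)
class ObservationSeries:
    """Noisy yearly phosphorus measurements y_1..y_T."""

    values: np.ndarray
    noise_variance: float
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValueError("observations must be one-dimensional")
        if self.noise_variance <= 0:
            raise ValueError("measurement variance must be positive")

    @property
    def horizon(self) -> int:
        return len(self.values)

    def __len__(self) -> int:
        return len(self.values)


def lognormal_underlying_moments(mean: float, var: float) -> tuple[float, float]:
    """(mu, sigma) of the underlying normal for a lognormal with the given
    arithmetic mean and variance: sigma^2 = ln(1 + v/m^2), mu = ln m - sigma^2/2."""
    if mean <= 0 or var <= 0:
        raise ValueError("lognormal mean and variance must be positive")
    sigma2 = np.log1p(var / mean**2)
    mu = np.log(mean) - 0.5 * sigma2
    return float(mu), float(np.sqrt(sigma2))


@dataclass(frozen=True)
class LognormalMarginal:
    """One lognormal prior marginal, moment-matched on the natural scale."""

    mean: float
    var: float
    bounds: tuple[float, float]
    #: if True, (mean, var) are instead the moments of the underlying
    #: normal (sensitivity-check interpretation)
    underlying: bool = False

    def moments(self) -> tuple[float, float]:
        """(mu, sigma) of the underlying normal."""
        if self.underlying:
            if self.var <= 0:
                raise ValueError("variance must be positive")
            return np.log(self.mean), float(np.sqrt(self.var))
        return lognormal_underlying_moments(self.mean, self.var)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """n in-bounds draws via rejection sampling."""
        mu, sigma = self.moments()
        lo, hi = self.bounds
        out = np.empty(0)
        while len(out) < n:
            draw = rng.lognormal(mu, sigma, size=max(n, 2 * (n - len(out))))
            out = np.concatenate([out, draw[(draw > lo) & (draw <= hi)]])
        return out[:n]

    def log_density(self, x) -> np.ndarray:
        """Log density of the (bound-truncated, unnormalised) marginal."""
        mu, sigma = self.moments()
        x = np.asarray(x, dtype=float)
        lo, hi = self.bounds
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (np.log(x) - mu) / sigma
            ld = -np.log(x * sigma * np.sqrt(2 * np.pi)) - 0.5 * z**2
        return np.where((x > lo) & (x <= hi), ld, -np.inf)


@dataclass(frozen=True)
class PriorSpec:
    """Independent lognormal prior marginals for (X_0, b, q)."""

    x0: LognormalMarginal
    b: LognormalMarginal
    q: LognormalMarginal

    @classmethod
    def default(cls, underlying: bool = False) -> "PriorSpec":
        """The study's biased prior: means (0.20, 0.62, 4.00), variances
        (0.20, 0.20, 1.00), truncated to the physical bounds."""
        return cls(
            x0=LognormalMarginal(0.20, 0.20, bounds=(0.0, np.inf), underlying=underlying),
            b=LognormalMarginal(0.62, 0.20, bounds=B_RANGE, underlying=underlying),
            q=LognormalMarginal(4.00, 1.00, bounds=Q_RANGE, underlying=underlying),
        )

    @property
    def marginals(self) -> tuple[LognormalMarginal, LognormalMarginal, LognormalMarginal]:
        return (self.x0, self.b, self.q)

    def log_density(self, x0, b, q) -> np.ndarray:
        return self.x0.log_density(x0) + self.b.log_density(b) + self.q.log_density(q)


@dataclass
class Ensemble:
    """Weighted set of augmented members J = (x, b, q) at a time step."""

    members: np.ndarray  # shape (n, 3): columns x, b, q
    weights: np.ndarray  # shape (n,), non-negative, summing to 1
    t: int = 0
    initial_size: int | None = None

    def __post_init__(self) -> None:
        self.members = np.atleast_2d(np.asarray(self.members, dtype=float))
        if self.members.shape[1] != 3:
            raise ValueError("members must have columns (x, b, q)")
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.members):
            raise ValueError("one weight per member required")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        total = self.weights.sum()
        if len(self.members) and total > 0:
            self.weights = self.weights / total
        if self.initial_size is None:
            self.initial_size = len(self.members)

    @property
    def alive_count(self) -> int:
        return len(self.members)

    @property
    def x(self) -> np.ndarray:
        return self.members[:, 0]

    @property
    def b(self) -> np.ndarray:
        return self.members[:, 1]

    @property
    def q(self) -> np.ndarray:
        return self.members[:, 2]

    def mean(self) -> np.ndarray:
        """Weighted mean of (x, b, q)."""
        return self.weights @ self.members

    def copy(self) -> "Ensemble":
        return Ensemble(
            members=self.members.copy(),
            weights=self.weights.copy(),
            t=self.t,
            initial_size=self.initial_size,
        )


def generate_truth(
    schedule,
    params: LakeParams = TRUTH_PARAMS,
    x0: float = TRUTH_X0,
) -> Trajectory:
    """Deterministic assumed-truth trajectory (process noise is zero)."""
    return simulate_trajectory(x0, params, schedule)


def generate_observations(
    truth: Trajectory,
    noise_variance: float = MEASUREMENT_VARIANCE,
    seed: int = 0,
) -> ObservationSeries:
    """Observations y_t = X_t + eps_t, eps_t ~ N(0, nu) i.i.d., for t = 1..T.

    Noise is not truncated, so observations can occasionally dip below
    zero when the lake is near the origin.
    """
    if noise_variance <= 0:
        raise ValueError("measurement variance must be positive")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, np.sqrt(noise_variance), size=truth.horizon)
    return ObservationSeries(values=truth.values[1:] + eps, noise_variance=noise_variance, seed=seed)


def generate_realization_set(
    truth: Trajectory,
    noise_variance: float = MEASUREMENT_VARIANCE,
    n: int = 10,
    base_seed: int = 0,
) -> list[ObservationSeries]:
    """n independent observation realizations with seeds base_seed..base_seed+n-1."""
    if n < 1:
        raise ValueError("need at least one realization")
    return [generate_observations(truth, noise_variance, base_seed + i) for i in range(n)]


def sample_prior(spec: PriorSpec, n: int, seed: int | np.random.Generator = 0) -> Ensemble:
    """Draw an n-member prior ensemble of (X_0, b, q) with uniform weights.

    Each marginal is sampled independently and rejection-sampled into its
    physical bounds, so the initial ensemble is fully alive; sample
    depletion during filtering is then attributable to the filters alone.
    """
    if n < 2:
        raise ValueError("a prior ensemble needs at least two members")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols = [m.sample(rng, n) for m in spec.marginals]
    members = np.column_stack(cols)
    return Ensemble(members=members, weights=np.full(n, 1.0 / n), t=0)
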