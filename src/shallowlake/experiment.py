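"""End-to-end twin-experiment orchestration.

One :class:`ExperimentConfig` drives the four studies:

* learning trajectories — posterior-mean paths of (x, b, q) per method
  and emission case, with 90% ensemble bands;
* ensemble-size sweep — relative RMSE (mean and range over observation
  realizations) per method and ensemble size, with NFE accounting;
* eutrophication-probability study — probability of eutrophication as a
  function of learning time in the high-emissions case;
* point-of-no-return snapshot — posterior densities of b, q, P_crit and
  the projected year-100 phosphorus from the year-45 posterior.

Defaults are deliberately scaled down so the full suite runs on one CPU
in minutes; the larger configurations are reachable through the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assimilation import LakeAssimilation, LakeAssimilationResults
from .lake import LakeParams, critical_threshold
from .metrics import (
    confidence_band,
    point_of_no_return,
    posterior_density,
    probability_of_eutrophication,
)
from .strategies import (
    EmissionSchedule,
    make_alternative_strategies,
    make_high_emissions_stepwise,
    make_low_emissions,
)
from .synthetic import PriorSpec, generate_realization_set, generate_truth

__all__ = [
    "ExperimentConfig",
    "run_learning_trajectories",
    "run_ensemble_size_sweep",
    "run_eutrophication_probability_study",
    "run_point_of_no_return_snapshot",
]

logger = logging.getLogger(__name__)

METHODS = ("enkf", "pf", "pc", "mcmc")


@dataclass
class ExperimentConfig:
    """Study configuration; the defaults reproduce the twin-experiment
    setup (truth parameters, biased lognormal prior, measurement
    variance, 100-year horizon, 10 observation realizations)."""

    truth_b: float = 0.42
    truth_q: float = 2.00
    truth_x0: float = 0.05
    noise_variance: float = 0.01
    T: int = 100
    low_margin: float = 0.98
    step_interval: int = 20
    target_crossing_year: int = 45
    realizations: int = 10
    base_seed: int = 0
    prior_underlying: bool = False
    #: per-method ensemble sizes for single runs (scaled-down defaults)
    sizes: dict = field(
        default_factory=lambda: {"enkf": 1000, "pf": 2000, "pc": 5000, "mcmc": 500}
    )
    #: assimilation times for MCMC (every 5 years keeps cost moderate)
    mcmc_stride: int = 5
    output_dir: str | None = None

    # -- construction / serialization -----------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # -- derived objects -------------------------------------------------------

    @property
    def truth_params(self) -> LakeParams:
        return LakeParams(self.truth_b, self.truth_q)

    def prior_spec(self) -> PriorSpec:
        return PriorSpec.default(underlying=self.prior_underlying)

    def schedules(self) -> dict[str, EmissionSchedule]:
        p = self.truth_params
        return {
            "low": make_low_emissions(p, self.T, self.low_margin),
            "high": make_high_emissions_stepwise(
                p, self.T, self.step_interval, self.target_crossing_year, self.truth_x0
            ),
        }

    def alternative_schedules(self) -> dict[str, EmissionSchedule]:
        ramp, abrupt = make_alternative_strategies(self.truth_params, self.T, x0=self.truth_x0)
        return {"linear_ramp": ramp, "abrupt_step": abrupt}

    def mcmc_times(self) -> list[int]:
        return list(range(self.mcmc_stride, self.T + 1, self.mcmc_stride))


def _fit(config: ExperimentConfig, schedule, truth, method: str, size: int, seed: int,
         **options) -> LakeAssimilationResults:
    from .synthetic import generate_observations

    obs = generate_observations(truth, config.noise_variance, seed)
    model = LakeAssimilation(obs, schedule, prior=config.prior_spec(), truth=truth)
    if method == "mcmc":
        options.setdefault("assimilation_times", config.mcmc_times())
    if method == "pc":
        options.pop("assimilation_times", None)
    return model.fit(method, size=size, seed=seed, **options)


def _write(report: dict, outdir: str | None, name: str, config: ExperimentConfig) -> None:
    if outdir is None:
        return
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for key, val in report.items():
        if isinstance(val, pd.DataFrame):
            val.to_csv(out / f"{name}_{key}.csv", index=False)
    meta = {
        "study": name,
        "config_hash": config.config_hash(),
        "base_seed": config.base_seed,
        "failures": report.get("failures", {}),
        "nfe": report.get("nfe", {}),
        "alive_min": report.get("alive_min", {}),
    }
    with open(out / f"{name}_manifest.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)


def _band_frame(res: LakeAssimilationResults, level: float = 0.9) -> pd.DataFrame:
    """90% ensemble bands of (x, b, q) at each stored assimilation time."""
    rows = []
    for ens in res.raw.posteriors:
        for i, name in enumerate(("x", "b", "q")):
            vals = ens.members[:, i]
            lo, hi = confidence_band(vals[None, :], weights=ens.weights, level=level)
            rows.append({"year": ens.t, "quantity": name, "lower": lo[0], "upper": hi[0]})
    return pd.DataFrame(rows)


def run_learning_trajectories(config: ExperimentConfig, methods=METHODS) -> dict:
    """Posterior-mean learning trajectories of (x, b, q) per method and case.

    Means are averaged across the observation realizations; 90% ensemble
    bands come from the first realization.  Method failures are recorded
    and do not abort the remaining methods.
    """
    import warnings as _warnings

    report: dict = {"failures": {}, "nfe": {}, "alive_min": {}}
    frames, band_frames = [], []
    for case, schedule in config.schedules().items():
        truth = generate_truth(schedule, config.truth_params, config.truth_x0)
        for method in methods:
            try:
                per_real = []
                bands = None
                for r in range(config.realizations):
                    with _warnings.catch_warnings():
                        _warnings.simplefilter("ignore")
                        res = _fit(config, schedule, truth, method,
                                   config.sizes[method], config.base_seed + r)
                    mt = res.mean_trajectory.copy()
                    mt["realization"] = r
                    per_real.append(mt)
                    if r == 0:
                        with _warnings.catch_warnings():
                            _warnings.simplefilter("ignore")
                            bands = _band_frame(res)
                        report["nfe"][f"{case}/{method}"] = res.nfe
                        report["alive_min"][f"{case}/{method}"] = int(
                            res.raw.alive_counts.min()
                        )
                allr = pd.concat(per_real)
                mean = allr.groupby("year")[["x", "b", "q"]].mean().reset_index()
                mean["method"] = method
                mean["case"] = case
                frames.append(mean)
                bands["method"] = method
                bands["case"] = case
                band_frames.append(bands)
            except Exception as exc:
                logger.exception("method %s failed on case %s", method, case)
                report["failures"][f"{case}/{method}"] = repr(exc)
    report["means"] = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    report["bands"] = pd.concat(band_frames, ignore_index=True) if band_frames else pd.DataFrame()
    _write(report, config.output_dir, "learning", config)
    return report


def run_ensemble_size_sweep(config: ExperimentConfig, sizes: dict | None = None,
                            methods=METHODS) -> dict:
    """Relative RMSE (mean and min-max range across realizations) per
    method and ensemble size, for both emission cases.

    The range is reported as (min, max) over the realization set, not a
    confidence interval.  Each cell also records its NFE cost.
    """
    import warnings as _warnings

    if sizes is None:
        sizes = {
            "enkf": [75, 250, 1000, 2500],
            "pf": [75, 250, 1000, 2500],
            "pc": [250, 1000, 5000],
            "mcmc": [500],
        }
    report: dict = {"failures": {}}
    rows = []
    for case, schedule in config.schedules().items():
        truth = generate_truth(schedule, config.truth_params, config.truth_x0)
        for method in methods:
            for size in sizes.get(method, []):
                try:
                    vals, nfe = [], None
                    for r in range(config.realizations):
                        with _warnings.catch_warnings():
                            _warnings.simplefilter("ignore")
                            res = _fit(config, schedule, truth, method, size,
                                       config.base_seed + r)
                            if method == "mcmc":
                                vals.append(_mcmc_relative_rmse(res, truth))
                            else:
                                vals.append(res.relative_rmse())
                        nfe = res.nfe
                    rows.append(
                        {
                            "case": case,
                            "method": method,
                            "size": size,
                            "rel_rmse_mean": float(np.mean(vals)),
                            "rel_rmse_min": float(np.min(vals)),
                            "rel_rmse_max": float(np.max(vals)),
                            "nfe": nfe,
                        }
                    )
                except Exception as exc:
                    logger.exception("sweep cell failed: %s/%s/%d", case, method, size)
                    report["failures"][f"{case}/{method}/{size}"] = repr(exc)
    report["rmse"] = pd.DataFrame(rows)
    _write(report, config.output_dir, "sweep", config)
    return report


def _mcmc_relative_rmse(res: LakeAssimilationResults, truth) -> float:
    """Relative RMSE of the posterior-mean phosphorus path simulated from
    the final MCMC chain's (X_0, b, q) samples."""
    from .lake import simulate_members
    from .metrics import rmse as _rmse

    theta = res.raw.diagnostics["theta_samples"]
    t_last = max(theta)
    samples = theta[t_last]
    sched = res.model.schedule.values
    paths = simulate_members(samples[:, 0], samples[:, 1], samples[:, 2], sched)
    mean_path = paths.mean(axis=1)
    return _rmse(mean_path[1:], truth.values[1:]) / float(
        np.mean(res.model.observations.values)
    )


def run_eutrophication_probability_study(config: ExperimentConfig, methods=METHODS) -> dict:
    """Probability of eutrophication vs learning time, high-emissions case.

    Yearly learning times for EnKF and PF, every 5th year for PC (cost
    control), the MCMC stride for MCMC; mean and (min, max) range across
    the observation realizations; the point of no return of the truth is
    included for reference.
    """
    import warnings as _warnings

    schedule = config.schedules()["high"]
    truth = generate_truth(schedule, config.truth_params, config.truth_x0)
    ponr = point_of_no_return(config.truth_x0, config.truth_params, schedule)
    report: dict = {"failures": {}, "point_of_no_return": ponr}
    rows = []
    for method in methods:
        try:
            if method in ("enkf", "pf"):
                t_grid = list(range(1, config.T + 1))
            elif method == "pc":
                t_grid = list(range(5, config.T + 1, 5))
            else:
                t_grid = config.mcmc_times()
            probs = np.full((config.realizations, len(t_grid)), np.nan)
            for r in range(config.realizations):
                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore")
                    if method == "pc":
                        for j, t in enumerate(t_grid):
                            res = _fit(config, schedule, truth, "pc",
                                       config.sizes["pc"], config.base_seed + r,
                                       t_learn=t)
                            probs[r, j] = res.probability_of_eutrophication()
                    else:
                        res = _fit(config, schedule, truth, method,
                                   config.sizes[method], config.base_seed + r)
                        for j, t in enumerate(t_grid):
                            probs[r, j] = probability_of_eutrophication(
                                res.raw.posterior_at(t), schedule, T=config.T
                            )
            for j, t in enumerate(t_grid):
                col = probs[:, j]
                rows.append(
                    {
                        "method": method,
                        "year": t,
                        "prob_mean": float(np.nanmean(col)),
                        "prob_min": float(np.nanmin(col)),
                        "prob_max": float(np.nanmax(col)),
                    }
                )
        except Exception as exc:
            logger.exception("probability study failed for %s", method)
            report["failures"][method] = repr(exc)
    report["probability"] = pd.DataFrame(rows)
    _write(report, config.output_dir, "probability", config)
    return report


def run_point_of_no_return_snapshot(config: ExperimentConfig, methods=METHODS) -> dict:
    """Posterior densities of b, q, P_crit and projected year-T phosphorus
    from each method's posterior at the point of no return (year 45)."""
    import warnings as _warnings

    schedule = config.schedules()["high"]
    truth = generate_truth(schedule, config.truth_params, config.truth_x0)
    t_star = config.target_crossing_year
    report: dict = {"failures": {}, "t_star": t_star}
    rows = []
    for method in methods:
        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                options = {}
                if method == "pc":
                    options["t_learn"] = t_star
                if method == "mcmc":
                    options["assimilation_times"] = [t_star]
                res = _fit(config, schedule, truth, method, config.sizes[method],
                           config.base_seed, **options)
                for param in ("b", "q", "pcrit", "x_T"):
                    curve = res.posterior_density(param, t=t_star)
                    rows.append(
                        pd.DataFrame(
                            {
                                "method": method,
                                "quantity": param,
                                "grid": curve.grid,
                                "density": curve.density,
                            }
                        )
                    )
        except Exception as exc:
            logger.exception("snapshot failed for %s", method)
            report["failures"][method] = repr(exc)
    report["densities"] = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    report["true_values"] = pd.DataFrame(
        {
            "quantity": ["b", "q", "pcrit", "x_T"],
            "value": [
                config.truth_b,
                config.truth_q,
                critical_threshold(config.truth_params),
                float(truth.values[-1]),
            ],
        }
    )
    _write(report, config.output_dir, "snapshot", config)
    return report
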