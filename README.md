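# shallowlake

Bayesian data assimilation test-bed for predicting an approaching
tipping point in the classic **shallow lake problem**.

A shallow lake accumulates phosphorus according to the yearly map

```
X_{t+1} = X_t − b·X_t + X_t^q / (1 + X_t^q) + a_t
```

where `X_t` is the (dimensionless) phosphorus concentration, `b` the
loss parameter, `q` the recycle exponent and `a_t` the anthropogenic
loading. For suitable `(b, q)` the lake is **bistable**: a desirable
oligotrophic state and an undesirable eutrophic state, separated by an
unstable equilibrium — the critical threshold `P_crit`. Once the lake
crosses `P_crit` it converges to the eutrophic state even if all
emissions stop (the transition is irreversible).

The package stages a twin experiment around this model. A known "truth"
(`b = 0.42`, `q = 2.00`, `X_0 = 0.05`, so `P_crit ≈ 0.54`) is driven by
either a safe constant loading or a stepwise-increasing loading that
tips the lake in year 45; noisy yearly observations
(`y_t = X_t + ε_t`, `ε_t ~ N(0, 0.01)`) feed four joint
state–parameter estimators that all start from the same deliberately
optimistic lognormal prior over `(X_0, b, q)`:

* **EnKF** — stochastic (perturbed-observation) ensemble Kalman filter,
* **PF** — particle filter (sequential importance resampling),
* **PC** — pre-calibration: accept/reject screening by the normalized
  mean squared error criterion `M ≤ 1`,
* **MCMC** — sequential Metropolis–Hastings on `p(X_0, b, q | y_1..t)`.

Skill is scored by relative RMSE of the estimated phosphorus path, the
**probability of eutrophication** (fraction of posterior members whose
projection to year 100 exceeds their own `P_crit`), the **point of no
return**, and KDE posterior densities of `b`, `q`, `P_crit` and the
projected end-of-horizon phosphorus.

It is aimed at researchers in ecological modelling and data
assimilation who want a small, fully reproducible benchmark for
early-warning skill near a fold bifurcation.

## Worked example

```python
from shallowlake import LakeAssimilation, TRUTH_PARAMS
from shallowlake.strategies import make_high_emissions_stepwise

schedule = make_high_emissions_stepwise(TRUTH_PARAMS)  # tips the lake in year 45
model = LakeAssimilation.from_truth(schedule, seed=0)  # truth + noisy observations
res = model.fit("enkf", size=2500, seed=1)
print(res.summary())
```

```
Shallow-lake joint state-parameter assimilation
=======================================================
Method:               EnKF
Horizon (years):      100
NFE:                  250000
Alive members (last): 6 / 2500
-------------------------------------------------------
quantity      post. mean   post. std     truth
x                 2.5449      0.0309    2.5542
b                 0.4350      0.0056    0.4200
q                 2.3574      0.0882    2.0000
-------------------------------------------------------
Relative RMSE (vs truth):           4.9%
Relative RMSE (vs observations):    7.7%
Probability of eutrophication:    1.000
```

Reading the output: a 2500-member filter spends 250,000 lake-model
evaluations (NFE = members × years). By year 100 it has pulled the
biased prior (`b: 0.62, q: 4.0`) close to the truth, tracks the
eutrophic phosphorus level to within ~5% of the observed mean, and
assigns probability 1 to the eutrophication that did in fact occur.
"Alive members" records sample depletion: members that leave the
physically plausible region (`b` in (0,1), `q` in [2,8], `x ≥ 0`) are
removed over time — severe here precisely because the true `q` sits on
its physical bound. The probability of eutrophication as a function of
learning time (`res.probability_of_eutrophication(t_learn=...)`) is the
early-warning signal the package is built to study.

The four paper-style studies (learning trajectories, RMSE vs ensemble
size, probability vs learning time, posterior snapshot at the point of
no return) run from one config:

```sh
shallowlake all --seed 1 --out results/
shallowlake assimilate --method pf --case high --size 5000
```

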