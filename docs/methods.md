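# Methods

## The lake model

The lake is a one-dimensional discrete map for total phosphorus,

    X_{t+1} = X_t − b·X_t + X_t^q/(1 + X_t^q) + a_t ,

with loss parameter `b ∈ (0, 1)`, recycle exponent `q ∈ [2, 8]` and
yearly anthropogenic loading `a_t ≥ 0`. All quantities are
dimensionless; the time step is one year. Process noise is zero
throughout: the truth is deterministic and all stochasticity enters
through measurement noise and the prior.

At zero loading the equilibria solve `b·x = x^q/(1+x^q)`. The origin is
always stable; on the bistable range (`b < (q−1)^((q−1)/q)/q`) two
positive roots appear, the lower unstable and the upper stable. The
unstable root is the critical threshold `P_crit`; for the truth
(`b=0.42, q=2`) the quadratic closed form gives `P_crit = 0.5445…`,
printed as 0.54. Stability is classified by the discrete-map criterion
(|map derivative| vs 1), since the model is a map, not a flow. Roots
are bracketed on `[0, 10]` — an implementation constant; the eutrophic
equilibrium is ≈`(1+a)/b` and stays far below 10 for admissible
parameters.

`critical_constant_loading` returns the fold loading `a*`: the local
maximum of `φ(x) = b·x − x^q/(1+x^q)` between 0 and `P_crit`. For
constant `a < a*` an oligotrophic equilibrium survives; above it every
trajectory tips. For the truth, `a* ≈ 0.0464`.

## Emission strategies

* **low_constant** — constant loading at `0.98·a*`. The margin keeps
  the truth strictly oligotrophic under discrete steps; loading exactly
  at `a*` would be marginal and non-robust. Exposed in the config.
* **high_stepwise** — zero loading stepping up by equal increments
  every 20 years. The step profile is a shape choice; the binding
  constraint is the calibration: one scale factor, found by bisection,
  makes the deterministic truth first exceed `P_crit` exactly in year
  45. The bisection locates both edges of the scale interval achieving
  the target year and returns the midpoint, so calibration is exact,
  robust and idempotent. The scale is expressed in units of a maximum
  loading of 0.3 per year — the smallest round value for which a
  mid-horizon crossing is reachable with this profile.
* **linear_ramp / abrupt_step** — alternative eutrophying strategies: a
  ramp from zero over the horizon, and the low constant loading jumping
  to a high constant at year 40; each calibrated the same way to a
  year-50 crossing (within the 40–60 window the design calls for).

## Synthetic data

Observations are `y_t = X_t + ε_t`, `ε_t ~ N(0, ν)` i.i.d. with
`ν = 0.01`, for `t = 1..T`, `T = 100`; ten independent realizations
(consecutive seeds) form the evaluation set. Noise is not truncated:
near-zero phosphorus an observation can dip below zero, which the
filters handle through the likelihood rather than by clipping.

The prior over `(X_0, b, q)` is a product of independent lognormals
with natural-scale means (0.20, 0.62, 4.00) and variances
(0.20, 0.20, 1.00), moment-matched to the underlying normal via
`σ² = ln(1 + v/m²)`, `μ = ln m − σ²/2`. The "variance" is read on the
natural scale (the same scale as the means); a config flag switches to
the underlying-normal interpretation for sensitivity checks. Draws are
rejection-sampled into the physical bounds so the initial ensemble is
fully alive — depletion during filtering is then attributable to the
filters, not the initialization. Two consequences worth noting:

* truncating `b` at 1 removes ≈14% of upper-tail mass, so the realized
  prior mean of `b` is ≈0.48, below the nominal 0.62 (still biased
  high relative to the truth 0.42);
* the `q` marginal is left-truncated at its physical bound 2, which is
  also the true value — the prior (and any posterior) can only
  approach `q = 2` from above.

## The estimators

All four schemes target the joint posterior of the augmented vector
`J = (x, b, q)` given observations up to a time. The measurement map is
the identity on the phosphorus component, and the likelihood is
Gaussian with variance `ν`.

**EnKF.** Stochastic, perturbed-observation flavour. Each year the
members are propagated one step, the Kalman gain is the sample
cross-covariance between `(x, b, q)` and the forecast observation over
(forecast variance + ν), and each member is nudged toward an
independently perturbed observation. After the analysis, `b` and `q`
receive Gaussian kernel jitter with standard deviation
`0.1 × (current ensemble std)`. The jitter is not optional polish: the
true `q` sits exactly on its physical bound, so a converged ensemble
straddles the bound and loses members at every update. Without jitter
the ensemble collapses to a frozen singleton (observed: 1 of 2500
alive), the gain degenerates to zero and assimilation silently stops
with a persistent bias. The jitter scale shrinks with the ensemble
spread, so it does not prevent convergence; setting it to 0 restores
the strictly static-parameter filter.

**PF.** Sequential importance resampling with weights accumulated in
log space; systematic resampling (the lowest-variance standard scheme)
when the effective sample size `1/Σw²` drops below half the alive
count. Parameters are static by default; an optional post-resampling
kernel jitter (off by default) counters particle impoverishment.
Without jitter the PF never violates the bounds, so it does not
deplete. Before any resampling the filter is algebraically identical to
discrete Bayes enumeration over the particles, which the tests exploit
as an exact oracle.

**PC.** Every prior draw is simulated through the learning window and
accepted iff `M = (1/T)Σ_t (y_t − x_t)²/ν ≤ 1`; accepted draws carry
uniform weights. The boundary `M = 1` is accepted (the two printed
conventions disagree on a measure-zero set). Zero acceptances are a
hard error carrying the acceptance-rate log.

**MCMC.** One independent Metropolis–Hastings chain per assimilation
time `t`, targeting `prior(X_0, b, q) · Π_{s≤t} N(y_s; x_s, ν)` with
`x_s` from deterministic simulation. The chain walks in
`z = log(X_0, b, q)`, where the lognormal prior marginals become
(truncated) Gaussians and the random-walk proposal is symmetric.
Proposal scales adapt toward ~0.3 acceptance during the first 10% of
the chain only, preserving detailed balance afterwards; bounds are
enforced through the prior support. NFE accounting charges each
proposal `t` model-years. Default assimilation times are every 5 years
(cost control; each chain re-simulates from scratch).

Members of the ensemble methods that leave the physical region
(`b ∉ (0,1)`, `q ∉ [2,8]`, `x < 0`) are removed and the weights
renormalized over survivors; complete depletion raises a hard error
naming the method and year.

## Skill metrics

**Relative RMSE.** The headline convention is the RMSE of the scheme's
posterior-mean phosphorus path against the *assumed truth*, divided by
the mean of the assimilated observations. The observation-referenced
variant is also available but is floored at the noise ratio
`√ν / mean(y)` (≈45–60% in the low-emissions case), which makes it
unable to discriminate between good estimators; the truth-referenced
variant is the informative one in a twin experiment. A one-step-ahead
(pre-update) forecast variant is provided as well; it carries an extra
transition-lag error during the fast eutrophication years.

**Probability of eutrophication.** Each posterior member `(x_t, b, q)`
is projected to year 100 under the remaining schedule and counted
(weighted) as eutrophic iff its final phosphorus exceeds its *own*
`P_crit(b, q)` — a decision maker cannot know the true threshold. A
switch allows classification against the true threshold. Members whose
parameters make the lake monostable have only the oligotrophic
attractor at zero loading, hence no irreversible threshold; they are
counted as non-eutrophic and logged.

**Point of no return.** The first year from which zeroing all future
emissions no longer averts eutrophication. Operationally this is the
first crossing of `P_crit`; the implementation cross-checks the general
definition (simulate from every yearly state with zero emissions for
1000 years and test which attractor it settles on) against the
shortcut and fails loudly on disagreement. For the calibrated
high-emissions schedule it is year 45; for the low schedule it does not
exist.

**Posterior densities.** Gaussian KDE with Scott's-rule bandwidth on a
512-point grid spanning the samples ±3 bandwidths; degenerate samples
yield a warned-about spike. `P_crit` densities map each member to its
own unstable root (vectorised bisection on
`b = x^(q−1)/(1+x^q)`), dropping monostable members.

**Likelihood surface and identifiability.** The log-likelihood of all
100 observations over a `(b, q)` grid at fixed `X_0` is sharply peaked
near the truth for the eutrophying strategy and an elongated flat ridge
for the safe strategy. The contrast statistic is the fraction of grid
cells whose likelihood is within a factor 10 of the peak ("top decile
of the peak"); a range-based version is useless here because the
surface's dynamic range is dominated by astronomically bad corners.
The low/high area ratio exceeds 5 by a wide margin (typically 30–50).

**Confidence bands.** Pointwise weighted 5th/95th percentiles of member
trajectories, with a linear-interpolation convention that reduces to
numpy's default for uniform weights; bands from fewer than 20 members
are flagged unreliable.

## Problem sizes

The studies default to scaled-down ensembles — EnKF/PF in the
hundreds-to-thousands, PC in the thousands, MCMC chains of a few
hundred retained samples per time — chosen so every study and the full
test suite complete on a single CPU in minutes while preserving the
qualitative and quantitative behaviour of interest (skill ranges,
convergence around the year-45 transition, depletion, the
probability-of-eutrophication trends). Larger configurations are
reachable through the config without code changes.

## What the synthetic generator does and does not emulate

It emulates: deterministic bistable dynamics, additive Gaussian
measurement noise of known variance, a biased and overdispersed
lognormal prior, and multiple observation realizations. It does not
emulate process noise, structural model error, non-Gaussian or
time-varying measurement error, or stochastic emissions. Passing tests
therefore demonstrate estimator behaviour under a clean,
correctly-specified twin experiment — a lower bound on the difficulty
of real early-warning problems, not evidence of field performance.

## Known limitations

* The stepwise schedule's step magnitudes are a reconstruction: only
  the shape (steps every 20 years from zero) and the year-45 crossing
  are constrained; absolute loadings depend on the chosen maximum
  loading unit (0.3).
* The EnKF requires the kernel jitter for a usable posterior in this
  problem; results with jitter 0 document the collapse rather than the
  filter's skill.
* MCMC chains are independent across assimilation times and
  single-chain; no convergence diagnostics beyond the acceptance-rate
  window are computed.
* The PC posterior is a screened prior: with an informative observation
  window and a finite prior sample its acceptance rate can reach zero,
  which is surfaced as a hard error rather than smoothed over.
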