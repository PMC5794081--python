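"""Filters and samplers: likelihood, bounds, EnKF, PF, PC, MCMC, NFE.

The PF and MCMC engines are checked against independent brute-force
Bayes oracles (weight enumeration / grid quadrature) on tiny instances.
"""

import numpy as np
import pytest
from scipy.stats import norm

from shallowlake.assimilation import (
    EnsembleDepletedError,
    count_nfe,
    enforce_physical_bounds,
    gaussian_loglik,
    precalibration_metric,
    run_enkf,
    run_mcmc_sequential,
    run_pf,
    run_precalibration,
)
from shallowlake.lake import LakeParams, simulate_trajectory
from shallowlake.synthetic import Ensemble, ObservationSeries, PriorSpec, sample_prior


def make_ensemble(members, weights=None, t=0):
    members = np.asarray(members, dtype=float)
    if weights is None:
        weights = np.full(len(members), 1.0 / len(members))
    return Ensemble(members=members, weights=np.asarray(weights, float), t=t)


class TestGaussianLoglik:
    def test_maximum_at_zero_residual(self):
        # -0.5 * ln(2*pi*0.01) evaluated independently via scipy
        assert gaussian_loglik(0.3, 0.3, 0.01) == pytest.approx(
            float(norm.logpdf(0.0, scale=0.1)), abs=1e-12
        )
        assert gaussian_loglik(0.3, 0.3, 0.01) == pytest.approx(1.383647, abs=1e-6)

    def test_residual_penalty(self):
        # residual 0.1 at nu=0.01 costs 0.1^2 / (2 * 0.01) = 0.5
        peak = gaussian_loglik(0.5, 0.5, 0.01)
        assert gaussian_loglik(0.5, 0.6, 0.01) == pytest.approx(peak - 0.5, abs=1e-12)

    def test_symmetric_in_residual_sign(self):
        assert gaussian_loglik(0.5, 0.62, 0.01) == gaussian_loglik(0.5, 0.38, 0.01)

    def test_invalid_variance(self):
        with pytest.raises(ValueError):
            gaussian_loglik(0.5, 0.5, 0.0)


class TestPhysicalBounds:
    @pytest.mark.parametrize(
        "member, kept",
        [
            ((0.3, 0.5, 3.0), True),
            ((-0.01, 0.5, 3.0), False),  # negative phosphorus
            ((0.3, 1.2, 3.0), False),  # b outside (0, 1)
            ((0.3, 0.5, 1.9), False),  # q below 2
            ((0.3, 0.5, 8.1), False),  # q above 8
            ((0.0, 0.999, 8.0), True),  # boundary x and q are admissible
        ],
    )
    def test_membership(self, member, kept):
        ens = make_ensemble([member, (0.3, 0.5, 3.0)])
        out, removed = enforce_physical_bounds(ens)
        assert removed == (0 if kept else 1)
        assert out.alive_count == (2 if kept else 1)

    def test_weights_renormalized(self):
        ens = make_ensemble([(0.3, 0.5, 3.0), (-1.0, 0.5, 3.0)], weights=[0.5, 0.5])
        out, _ = enforce_physical_bounds(ens)
        assert out.weights.sum() == pytest.approx(1.0)

    def test_total_depletion_raises(self):
        ens = make_ensemble([(-1.0, 0.5, 3.0), (-2.0, 0.5, 3.0)], t=7)
        with pytest.raises(EnsembleDepletedError, match="t=7"):
            enforce_physical_bounds(ens)


class TestEnKF:
    def test_huge_noise_leaves_forecast_unchanged(self):
        # Kalman gain -> 0 as nu -> infinity
        prior = sample_prior(PriorSpec.default(), 200, seed=1)
        obs = ObservationSeries(values=np.array([0.5]), noise_variance=1e9, seed=0)
        res = run_enkf(prior, obs, np.zeros(1), seed=2, param_jitter=0.0)
        post = res.posteriors[-1]
        assert post.alive_count == 200
        # every member's parameters essentially untouched by the update
        assert np.allclose(post.members[:, 1:], prior.members[:, 1:], atol=1e-3)

    def test_scalar_kalman_gain_closed_form(self):
        # one step, fixed parameters: the analysis mean must equal
        # xf_mean + K (y - xf_mean) with K = var(xf) / (var(xf) + nu),
        # up to the Monte-Carlo error of the observation perturbations
        rng = np.random.default_rng(5)
        n = 50_000
        x0 = np.abs(rng.normal(0.3, 0.1, n))
        members = np.column_stack([x0, np.full(n, 0.42), np.full(n, 2.0)])
        prior = make_ensemble(members)
        nu = 0.01
        y = 0.6
        obs = ObservationSeries(values=np.array([y]), noise_variance=nu, seed=0)
        res = run_enkf(prior, obs, np.zeros(1), seed=7, param_jitter=0.0)

        p = LakeParams(0.42, 2.0)
        xf = np.array([simulate_trajectory(v, p, [0.0]).values[1] for v in x0[:0]])
        xf = x0 - 0.42 * x0 + x0**2 / (1 + x0**2)  # independent hand evaluation
        var_f = np.var(xf, ddof=1)
        gain = var_f / (var_f + nu)
        expected = xf.mean() + gain * (y - xf.mean())
        got = res.posteriors[-1].x.mean()
        assert got == pytest.approx(expected, abs=4 * np.sqrt(nu / n) * gain + 1e-4)

    def test_alive_counts_non_increasing(self, high_obs, high_schedule):
        prior = sample_prior(PriorSpec.default(), 300, seed=3)
        res = run_enkf(prior, high_obs, high_schedule, seed=4)
        assert np.all(np.diff(res.alive_counts) <= 0)
        assert res.nfe == count_nfe(300, 100)

    def test_reproducible(self, low_obs, low_schedule):
        a = run_enkf(sample_prior(PriorSpec.default(), 100, seed=1), low_obs, low_schedule, seed=2)
        b = run_enkf(sample_prior(PriorSpec.default(), 100, seed=1), low_obs, low_schedule, seed=2)
        assert np.array_equal(a.posteriors[-1].members, b.posteriors[-1].members)


class TestParticleFilter:
    def test_equidistant_particles_share_weight(self):
        b, q = 0.42, 2.0
        x0 = np.array([0.2, 0.4])
        xf = x0 - b * x0 + x0**2 / (1 + x0**2)
        y = float(xf.mean())  # equidistant from both propagated particles
        prior = make_ensemble(np.column_stack([x0, [b, b], [q, q]]))
        obs = ObservationSeries(values=np.array([y]), noise_variance=0.01, seed=0)
        res = run_pf(prior, obs, np.zeros(1), seed=1)
        assert np.allclose(res.posteriors[-1].weights, [0.5, 0.5], atol=1e-12)

    def test_two_particle_weight_ratio(self):
        # particles whose propagated states sit 0 and 0.2 away from the
        # observation carry weights exp(0) : exp(-2) -> (0.8808, 0.1192)
        b, q = 0.42, 2.0
        x0 = np.array([0.3, 0.55])
        xf = x0 - b * x0 + x0**q / (1 + x0**q)
        # shift the second particle's start so its propagated state lands
        # exactly 0.2 above the first particle's
        from scipy.optimize import brentq

        step = lambda v: v - b * v + v**q / (1 + v**q)
        x0[1] = brentq(lambda v: step(v) - (xf[0] + 0.2), 0.3, 2.0, xtol=1e-15)
        prior = make_ensemble(np.column_stack([x0, [b, b], [q, q]]))
        obs = ObservationSeries(values=np.array([xf[0]]), noise_variance=0.01, seed=0)
        res = run_pf(prior, obs, np.zeros(1), seed=1, resample_fraction=0.0)
        expected = np.array([1.0, np.exp(-2.0)])
        expected /= expected.sum()
        assert np.allclose(res.posteriors[-1].weights, expected, atol=1e-9)
        assert expected[0] == pytest.approx(0.8808, abs=1e-4)

    def test_matches_enumeration_oracle(self):
        # 3 particles, 2 steps, no resampling: the posterior must equal the
        # brute-force discrete Bayes enumeration exactly
        members = np.array([[0.10, 0.30, 2.0], [0.30, 0.42, 2.5], [0.50, 0.55, 3.0]])
        sched = np.array([0.02, 0.03])
        nu = 0.01
        obs_vals = np.array([0.25, 0.30])
        prior = make_ensemble(members)
        obs = ObservationSeries(values=obs_vals, noise_variance=nu, seed=0)
        res = run_pf(prior, obs, sched, seed=1, resample_fraction=0.0)

        # oracle: enumerate each particle's deterministic path and weight
        w = np.ones(3)
        paths = []
        for x0, b, q in members:
            path = simulate_trajectory(x0, LakeParams(b, q), sched).values
            paths.append(path)
        paths = np.array(paths)
        for t in (1, 2):
            w *= norm.pdf(obs_vals[t - 1], loc=paths[:, t], scale=np.sqrt(nu))
        w /= w.sum()
        oracle_mean = w @ paths[:, 2]
        got = res.posteriors[-1].mean()[0]
        assert got == pytest.approx(oracle_mean, abs=1e-12)
        assert np.allclose(res.posteriors[-1].weights, w, atol=1e-12)

    def test_weights_sum_to_one_every_step(self, low_obs, low_schedule):
        prior = sample_prior(PriorSpec.default(), 300, seed=5)
        res = run_pf(prior, low_obs, low_schedule, seed=6)
        for ens in res.posteriors:
            assert ens.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_alive_counts_non_increasing(self, low_obs, low_schedule):
        prior = sample_prior(PriorSpec.default(), 300, seed=5)
        res = run_pf(prior, low_obs, low_schedule, seed=6)
        assert np.all(np.diff(res.alive_counts) <= 0)


class TestPrecalibration:
    def test_metric_arithmetic(self):
        # residuals of constant size r give M = r^2 / nu
        traj = np.full((2, 3), 0.5)
        obs = np.array([0.55, 0.55])
        M = precalibration_metric(traj + np.array([[0.0], [0.0]]), obs, nu=0.01)
        assert np.allclose(M, 0.25)
        obs = np.array([0.60, 0.60])
        assert np.allclose(precalibration_metric(traj, obs, nu=0.01), 1.0)
        obs = np.array([0.70, 0.70])
        assert np.allclose(precalibration_metric(traj, obs, nu=0.01), 4.0)

    def test_boundary_m_equal_one_accepted(self):
        # observations exactly 0.1 above one member's path: M = 1, accepted
        good = (0.10, 0.42, 2.0)
        bad = (0.90, 0.80, 7.0)
        sched = np.full(4, 0.02)
        path = simulate_trajectory(good[0], LakeParams(good[1], good[2]), sched).values
        obs = ObservationSeries(values=path[1:] + 0.1, noise_variance=0.01, seed=0)
        prior = make_ensemble([good, bad])
        res = run_precalibration(prior, obs, sched)
        assert res.posteriors[-1].alive_count == 1
        assert res.posteriors[-1].members[0, 1:] == pytest.approx([0.42, 2.0])

    def test_residual_two_sigma_rejected(self):
        member = (0.10, 0.42, 2.0)
        sched = np.full(4, 0.02)
        path = simulate_trajectory(member[0], LakeParams(*member[1:]), sched).values
        obs = ObservationSeries(values=path[1:] + 0.2, noise_variance=0.01, seed=0)
        prior = make_ensemble([member, member])
        with pytest.raises(EnsembleDepletedError, match="acceptance rate 0"):
            run_precalibration(prior, obs, sched)

    def test_learning_window_restricts_metric(self):
        # a member that fits early but diverges later must still be accepted
        # when only the early window is scored
        member = (0.10, 0.42, 2.0)
        sched = np.full(6, 0.02)
        path = simulate_trajectory(member[0], LakeParams(*member[1:]), sched).values
        obs_vals = path[1:].copy()
        obs_vals[3:] += 1.0  # gross late mismatch
        obs = ObservationSeries(values=obs_vals, noise_variance=0.01, seed=0)
        prior = make_ensemble([member, member])
        res = run_precalibration(prior, obs, sched, t_learn=3)
        assert res.posteriors[-1].alive_count == 2
        with pytest.raises(EnsembleDepletedError):
            run_precalibration(prior, obs, sched, t_learn=6)


class TestMCMC:
    def test_prior_recovery_without_observations(self, prior_spec):
        obs = ObservationSeries(values=np.zeros(5), noise_variance=0.01, seed=0)
        res = run_mcmc_sequential(
            prior_spec, obs, np.zeros(5), assimilation_times=[0], n_keep=4000, seed=3
        )
        ens = res.posteriors[-1]
        reference = sample_prior(prior_spec, 100_000, seed=8)
        # chain samples (X_0, b, q) from the truncated prior
        assert ens.b.mean() == pytest.approx(reference.b.mean(), abs=0.03)
        assert ens.q.mean() == pytest.approx(reference.q.mean(), abs=0.25)
        assert ens.x.mean() == pytest.approx(reference.x.mean(), abs=0.05)

    def test_matches_grid_quadrature_oracle(self, prior_spec):
        # two observations, 20^3 quadrature over (X_0, b, q)
        p = LakeParams(0.42, 2.0)
        sched = np.array([0.02, 0.02])
        path = simulate_trajectory(0.15, p, sched).values
        obs_vals = path[1:] + np.array([0.05, -0.03])
        nu = 0.01
        obs = ObservationSeries(values=obs_vals, noise_variance=nu, seed=0)

        x0g = np.linspace(0.01, 1.0, 20)
        bg = np.linspace(0.05, 0.98, 20)
        qg = np.linspace(2.01, 7.9, 20)
        X0, B, Q = np.meshgrid(x0g, bg, qg, indexing="ij")
        flat = [a.ravel() for a in (X0, B, Q)]
        from shallowlake.lake import simulate_members

        paths = simulate_members(flat[0], flat[1], flat[2], sched)
        log_post = prior_spec.log_density(*flat)
        for t in (1, 2):
            log_post += norm.logpdf(obs_vals[t - 1], loc=paths[t], scale=np.sqrt(nu))
        w = np.exp(log_post - log_post.max())
        w /= w.sum()
        oracle_b = float(w @ flat[1])

        res = run_mcmc_sequential(
            prior_spec, obs, sched, assimilation_times=[2], n_keep=8000, seed=4
        )
        chain_b = res.posteriors[-1].b
        # ~3 Monte-Carlo standard errors with a generous autocorrelation factor
        mcse = 3 * chain_b.std() / np.sqrt(len(chain_b) / 20)
        assert chain_b.mean() == pytest.approx(oracle_b, abs=max(mcse, 0.02))

    def test_nfe_counts_proposals_times_years(self, prior_spec):
        obs = ObservationSeries(values=np.full(10, 0.2), noise_variance=0.01, seed=0)
        res = run_mcmc_sequential(
            prior_spec, obs, np.zeros(10), assimilation_times=[5, 10], n_keep=900, seed=1
        )
        n_chain = res.diagnostics["chain_length"]
        assert res.nfe == n_chain * 5 + n_chain * 10

    def test_chain_too_short_rejected(self, prior_spec):
        obs = ObservationSeries(values=np.full(3, 0.2), noise_variance=0.01, seed=0)
        with pytest.raises(ValueError, match="100"):
            run_mcmc_sequential(prior_spec, obs, np.zeros(3), [1], n_keep=50)


class TestNFE:
    @pytest.mark.parametrize(
        "n, T, expected", [(1000, 100, 100_000), (1, 1, 1), (75, 100, 7500)]
    )
    def test_product(self, n, T, expected):
        assert count_nfe(n, T) == expected

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            count_nfe(0, 100)
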