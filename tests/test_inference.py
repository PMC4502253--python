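import numpy as np
import pytest

from spatemort import (
    ModelSpec,
    PosteriorSamples,
    SimulationConfig,
    default_populations,
    fit,
    log_likelihood,
    log_prior,
    make_grid_adjacency,
    posterior_quantiles,
    potential_scale_reduction,
    simulate_dataset,
    simulate_true_parameters,
)
from spatemort.inference import DegenerateChainError, cell_log_rate_draws, load_samples, save_samples
from spatemort._hmc import hmc_sample
from spatemort._reparam import ModelTransform
from spatemort.models import linear_predictor_array


class TestPotentialScaleReduction:
    def test_same_distribution_chains_near_one(self):
        rng = np.random.default_rng(1)
        chains = rng.standard_normal((2, 10_000))
        assert abs(potential_scale_reduction(chains) - 1.0) < 0.01

    def test_shifted_chains_flagged(self):
        rng = np.random.default_rng(2)
        chains = rng.standard_normal((2, 2_000))
        chains[1] += 10.0
        assert potential_scale_reduction(chains) > 2.0

    def test_constant_chains_raise(self):
        with pytest.raises(DegenerateChainError):
            potential_scale_reduction(np.ones((2, 100)))

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            potential_scale_reduction(np.zeros((1, 100)))


def _samples_from_scalar_draws(values, default_scheme):
    """Minimal PosteriorSamples carrying alpha0 draws only."""
    spec = ModelSpec(1, default_scheme, np.arange(2000, 2005), 1)
    arr = np.asarray(values, float)[None, :]
    blocks = {"alpha0": arr}
    return PosteriorSamples(spec, blocks, {}, seed=0)


class TestPosteriorQuantiles:
    def test_median_of_small_set(self, default_scheme):
        s = _samples_from_scalar_draws([1, 2, 3, 4, 5], default_scheme)
        q = posterior_quantiles(s, lambda p: p.alpha0, [0.5])
        assert q[0] == pytest.approx(3.0)

    def test_constant_draws(self, default_scheme):
        s = _samples_from_scalar_draws([2.5] * 10, default_scheme)
        q = posterior_quantiles(s, lambda p: p.alpha0, [0.025, 0.5, 0.975])
        assert np.allclose(q, 2.5)

    def test_normal_draws_tail_quantiles(self, default_scheme):
        rng = np.random.default_rng(3)
        s = _samples_from_scalar_draws(rng.standard_normal(10_000), default_scheme)
        q = posterior_quantiles(s, lambda p: p.alpha0, [0.025, 0.975])
        assert abs(q[0] + 1.96) < 0.05 and abs(q[1] - 1.96) < 0.05

    def test_invalid_probs_rejected(self, default_scheme):
        s = _samples_from_scalar_draws([1.0, 2.0], default_scheme)
        with pytest.raises(ValueError):
            posterior_quantiles(s, lambda p: p.alpha0, [0.0, 0.5])


class TestSamplerCorrectness:
    def test_single_cell_posterior_matches_dense_grid(self):
        """HMC on a 1-D Poisson-count model agrees with numeric integration.

        Total variation between the binned draw histogram and the exact
        posterior stays under 0.02.
        """
        deaths, exposure = 7.0, 120.0
        prior_sd = 10.0

        def logp_grad(x):
            lam = np.exp(x[0])
            lp = deaths * x[0] - exposure * lam - 0.5 * (x[0] / prior_sd) ** 2
            g = deaths - exposure * lam - x[0] / prior_sd**2
            return lp, np.array([g])

        rng = np.random.default_rng(11)
        draws, _ = hmc_sample(
            logp_grad, np.array([np.log(deaths / exposure)]), 500, 50_000, rng,
            max_leapfrog=8, init_step=0.2,
        )
        xs = draws[:, 0]
        grid = np.linspace(xs.min() - 0.5, xs.max() + 0.5, 4001)
        lp = deaths * grid - exposure * np.exp(grid) - 0.5 * (grid / prior_sd) ** 2
        dens = np.exp(lp - lp.max())
        dens /= np.trapezoid(dens, grid)
        edges = np.quantile(xs, np.linspace(0, 1, 21))
        edges[0], edges[-1] = grid[0], grid[-1]
        hist, _ = np.histogram(xs, bins=edges)
        p_hat = hist / hist.sum()
        cdf = np.concatenate(([0.0], np.cumsum(dens) * (grid[1] - grid[0])))
        p_exact = np.diff(np.interp(edges, grid, cdf[:-1] / cdf[-2]))
        tv = 0.5 * np.abs(p_hat - p_exact).sum()
        assert tv < 0.02

    def test_sampled_density_equals_likelihood_plus_prior(self, default_scheme):
        """The HMC target is exactly the model density (single-district case).

        Differences of the sampler's log posterior across points equal the
        differences of log_likelihood + log_prior plus the log-scale sampling
        Jacobians, for every model.
        """
        cfg = SimulationConfig(n_rows=1, n_cols=1, seed=4)
        graph = make_grid_adjacency(1, 1)
        params = simulate_true_parameters(cfg, graph, default_scheme)
        pops = default_populations(1, default_scheme, cfg.n_years)
        data = simulate_dataset(params, pops, 3, seed=9, years=cfg.years)
        for mid in (1, 2, 3, 4, 5):
            spec = ModelSpec(mid, default_scheme, cfg.years, 1)
            tr = ModelTransform(spec, data, graph)
            rng = np.random.default_rng(mid)
            psi1 = tr.initial_point() + 0.05 * rng.standard_normal(tr.dim)
            psi2 = tr.initial_point() + 0.05 * rng.standard_normal(tr.dim)

            def natural_logpost(psi):
                p = tr.natural(psi)
                lp = log_likelihood(p, spec, data) + log_prior(p, spec, graph)
                lp += sum(
                    np.log(v) for k, v in p.sigmas.items()
                    if k not in ("spatial_u", "spatial_v")
                )
                return lp

            d_psi = tr.logp_grad(psi1)[0] - tr.logp_grad(psi2)[0]
            d_nat = natural_logpost(psi1) - natural_logpost(psi2)
            assert d_psi == pytest.approx(d_nat, abs=1e-6), f"model {mid}"

    def test_analytic_gradients_match_finite_differences(self, study):
        data, _, graph = study
        for mid in (1, 2, 3, 4, 5):
            spec = ModelSpec(mid, data.age_scheme, data.years, data.n_districts)
            tr = ModelTransform(spec, data, graph)
            rng = np.random.default_rng(mid)
            psi = tr.initial_point() + 0.02 * rng.standard_normal(tr.dim)
            _, grad = tr.logp_grad(psi)
            for i in rng.choice(tr.dim, size=12, replace=False):
                hi, lo = psi.copy(), psi.copy()
                hi[i] += 1e-6
                lo[i] -= 1e-6
                fd = (tr.logp_grad(hi)[0] - tr.logp_grad(lo)[0]) / 2e-6
                assert grad[i] == pytest.approx(fd, rel=5e-3, abs=1e-4)


class TestFit:
    def test_determinism(self, study):
        data, _, graph = study
        spec = ModelSpec(1, data.age_scheme, data.years, data.n_districts)
        s1 = fit(spec, data, graph, chains=2, draws=40, warmup=80, seed=5)
        s2 = fit(spec, data, graph, chains=2, draws=40, warmup=80, seed=5)
        for name in s1.blocks:
            assert np.array_equal(s1.blocks[name], s2.blocks[name])

    def test_invalid_config_rejected(self, study):
        data, _, graph = study
        spec = ModelSpec(1, data.age_scheme, data.years, data.n_districts)
        with pytest.raises(ValueError):
            fit(spec, data, graph, draws=0)

    def test_likelihood_dominated_limit(self, default_scheme):
        """With 1e6 person-years per cell the posterior sits on the data."""
        graph = make_grid_adjacency(2, 2)
        cfg = SimulationConfig(n_rows=2, n_cols=2, n_years=10, seed=13)
        params = simulate_true_parameters(cfg, graph, default_scheme)
        pops = np.full((4, 19, 10), 1e6)
        data = simulate_dataset(params, pops, 1, seed=14, years=cfg.years)
        spec = ModelSpec(1, default_scheme, cfg.years, 4)
        s = fit(spec, data, graph, chains=2, draws=300, warmup=300, seed=15)
        lr = cell_log_rate_draws(s)
        post_mean = lr.mean(axis=0)
        emp = np.log(np.maximum(data.deaths, 0.5) / pops)
        emp_se = 1.0 / np.sqrt(np.maximum(data.deaths, 1.0))
        frac_close = np.mean(np.abs(post_mean - emp) < 3 * emp_se)
        assert frac_close > 0.98

    def test_convergence_gate_on_fixture(self, fitted_m3):
        """Model 3 on the default fixture: all PSRFs below the 1.1 gate."""
        _, samples, _ = fitted_m3
        assert samples.max_psrf() < 1.1

    def test_posterior_covers_generating_log_rates(self, fitted_m3):
        spec, samples, truth = fitted_m3
        lr = cell_log_rate_draws(samples)
        eta = linear_predictor_array(truth, spec)
        lo, hi = np.quantile(lr, [0.05, 0.95], axis=0)
        cov = ((eta >= lo) & (eta <= hi)).mean()
        assert 0.8 < cov <= 1.0

    def test_draws_satisfy_constraints(self, fitted_m3):
        _, samples, _ = fitted_m3
        for name in ("alpha_age", "beta_age", "gamma_period", "phi_cohort"):
            assert np.abs(samples.stacked(name).sum(axis=-1)).max() < 1e-8
        w = samples.stacked("u_spatial") + samples.stacked("v_spatial")
        assert np.abs(w.sum(axis=-1)).max() < 1e-8


def test_save_load_round_trip(tmp_path, fitted_m3):
    _, samples, _ = fitted_m3
    save_samples(samples, tmp_path / "post")
    back = load_samples(tmp_path / "post")
    assert back.n_chains == samples.n_chains
    assert back.n_draws == samples.n_draws
    for name in samples.blocks:
        assert np.allclose(back.blocks[name], samples.blocks[name])
    assert back.spec.model_id == 3
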