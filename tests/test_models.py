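from itertools import permutations

import numpy as np
import pytest
from scipy.stats import poisson

from spatemort import (
    AgeScheme,
    MortalityDataset,
    SimulationConfig,
    linear_predictor,
    log_likelihood,
    log_prior,
    make_grid_adjacency,
    simulate_true_parameters,
)
from spatemort.models import (
    ConstraintError,
    ModelParameters,
    ModelSpec,
    _rw_logpdf,
    icar_logpdf,
    linear_predictor_array,
)


def _spec(model_id, scheme, years, n_districts, **kw):
    return ModelSpec(model_id, scheme, np.asarray(years), n_districts, **kw)


@pytest.fixture()
def random_params(default_scheme, grid12):
    cfg = SimulationConfig(seed=31)
    return simulate_true_parameters(cfg, grid12, default_scheme)


class TestLinearPredictor:
    def test_model1_arithmetic_by_hand(self, default_scheme):
        # years 1991..2011 centre at 2001; the last year has t~ = 10
        spec = _spec(1, default_scheme, np.arange(1991, 2012), 1)
        p = ModelParameters.zeros(spec)
        p.alpha0, p.beta0 = -4.0, -0.02
        assert linear_predictor(p, spec, 0, 0, 20) == pytest.approx(-4.2)

    def test_out_of_range_indices(self, default_scheme):
        spec = _spec(1, default_scheme, np.arange(2000, 2010), 2)
        p = ModelParameters.zeros(spec)
        for bad in [(2, 0, 0), (0, 19, 0), (0, 0, 10), (-1, 0, 0)]:
            with pytest.raises(ValueError):
                linear_predictor(p, spec, *bad)

    def test_model2_reduces_to_model1_at_theta_one(self, default_scheme, grid12, random_params):
        years = np.arange(1993, 2013)
        s1 = _spec(1, default_scheme, years, 12)
        s2 = _spec(2, default_scheme, years, 12)
        p = random_params
        p.theta = 1.0
        assert np.allclose(
            linear_predictor_array(p, s2), linear_predictor_array(p, s1)
        )

    def test_model3_and_4_nesting(self, default_scheme, random_params):
        years = np.arange(1993, 2013)
        p = random_params
        s1 = _spec(1, default_scheme, years, 12)
        s3 = _spec(3, default_scheme, years, 12)
        s4 = _spec(4, default_scheme, years, 12)
        phi_saved = p.phi_cohort.copy()
        p.phi_cohort = np.zeros_like(phi_saved)
        assert np.allclose(linear_predictor_array(p, s3), linear_predictor_array(p, s1))
        p.phi_cohort = phi_saved
        p.w_age = np.ones_like(p.w_age)
        assert np.allclose(linear_predictor_array(p, s4), linear_predictor_array(p, s3))


class TestLogLikelihood:
    def _toy(self, tiny_scheme):
        rng = np.random.default_rng(0)
        years = np.arange(2000, 2002)
        spec = _spec(1, tiny_scheme, years, 2)
        deaths = rng.integers(0, 20, size=(2, 2, 2))
        pop = rng.uniform(50, 500, size=(2, 2, 2))
        data = MortalityDataset(deaths, pop, tiny_scheme, years)
        p = ModelParameters.zeros(spec)
        p.alpha0 = -3.0
        p.alpha_age = np.array([0.5, -0.5])
        p.u_spatial = np.array([0.2, -0.2])
        return spec, data, p

    def test_matches_brute_force_cell_sum(self, tiny_scheme):
        spec, data, p = self._toy(tiny_scheme)
        expected = 0.0
        for s in range(2):
            for a in range(2):
                for t in range(2):
                    mu = data.population[s, a, t] * np.exp(linear_predictor(p, spec, s, a, t))
                    expected += poisson.logpmf(data.deaths[s, a, t], mu)
        assert log_likelihood(p, spec, data) == pytest.approx(expected, rel=1e-12)

    def test_zero_deaths_contribution_is_minus_mu(self, tiny_scheme):
        spec, data, p = self._toy(tiny_scheme)
        data.deaths[:] = 0
        mu = data.population * np.exp(linear_predictor_array(p, spec))
        assert log_likelihood(p, spec, data) == pytest.approx(-mu.sum(), rel=1e-12)

    def test_maximised_at_empirical_rate(self):
        """One cell with 5 deaths over 100 person-years peaks at rate 0.05."""
        scheme = AgeScheme(np.array([85.0]), np.array([np.inf]))
        years = np.array([2000])
        spec = _spec(1, scheme, years, 1)
        data = MortalityDataset(
            np.array([[[5]]]), np.array([[[100.0]]]), scheme, years
        )

        def ll(rate):
            p = ModelParameters.zeros(spec)
            p.alpha0 = np.log(rate)
            return log_likelihood(p, spec, data)

        assert ll(0.05) > ll(0.05 * 1.05)
        assert ll(0.05) > ll(0.05 * 0.95)

    def test_invalid_data_rejected(self, tiny_scheme):
        spec, data, p = self._toy(tiny_scheme)
        bad = data.deaths.astype(float).copy()
        bad[0, 0, 0] = -1
        with pytest.raises(ValueError):
            log_likelihood(p, spec, type("D", (), {"deaths": bad, "population": data.population})())


class TestLogPrior:
    def test_rw1_density_is_increment_normal(self):
        """A length-3 RW1 block contributes N(0,1) log-densities of its steps."""
        from scipy.stats import norm

        x = np.array([0.3, -0.1, 0.4])
        expected = norm.logpdf(x[1] - x[0]) + norm.logpdf(x[2] - x[1])
        assert _rw_logpdf(x, 1.0, 1) == pytest.approx(expected, rel=1e-12)

    def test_smooth_profile_beats_rough_permutations(self):
        """RW1 density ranks length-4 blocks by their squared-increment sum."""
        base = np.array([0.0, 0.1, 0.25, 0.5])
        ss_base = np.sum(np.diff(base) ** 2)
        lp_base = _rw_logpdf(base, 1.0, 1)
        for perm in set(permutations(base)):
            ss = np.sum(np.diff(perm) ** 2)
            if ss > ss_base + 1e-12:
                assert _rw_logpdf(np.array(perm), 1.0, 1) < lp_base

    def test_icar_constant_block_is_maximal(self, grid12):
        rng = np.random.default_rng(5)
        u = rng.normal(size=12)
        u -= u.mean()
        assert icar_logpdf(np.zeros(12), 1.0, grid12) > icar_logpdf(u, 1.0, grid12)

    def test_icar_translation_invariance(self, grid12):
        rng = np.random.default_rng(6)
        u = rng.normal(size=12)
        assert icar_logpdf(u, 0.7, grid12) == pytest.approx(
            icar_logpdf(u + 3.3, 0.7, grid12), rel=1e-12
        )

    def test_finite_for_valid_parameters(self, default_scheme, grid12, random_params):
        spec = _spec(3, default_scheme, np.arange(1993, 2013), 12)
        lp = log_prior(random_params, spec, grid12)
        assert np.isfinite(lp)

    def test_sum_to_zero_violation_raises(self, default_scheme, grid12, random_params):
        spec = _spec(3, default_scheme, np.arange(1993, 2013), 12)
        p = random_params
        p.u_spatial = p.u_spatial + 0.5
        with pytest.raises(ConstraintError):
            log_prior(p, spec, grid12)

    def test_cohort_drift_violation_raises(self, default_scheme, grid12, random_params):
        spec = _spec(3, default_scheme, np.arange(1993, 2013), 12)
        p = random_params
        ramp = np.arange(p.phi_cohort.size) - (p.phi_cohort.size - 1) / 2
        p.phi_cohort = p.phi_cohort + 0.05 * ramp
        with pytest.raises(ConstraintError):
            log_prior(p, spec, grid12)


def test_model_registry_components():
    from spatemort.models import MODEL_COMPONENTS

    assert set(MODEL_COMPONENTS) == {1, 2, 3, 4, 5}
    assert "power_trend" in MODEL_COMPONENTS[2]
    assert "cohort_rw" in MODEL_COMPONENTS[3]
    assert "weighted_cohort_rw" in MODEL_COMPONENTS[4]
    assert "lee_carter" in MODEL_COMPONENTS[5]
    assert all("bym" in c for c in MODEL_COMPONENTS.values())
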