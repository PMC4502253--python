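import numpy as np
import pytest

from spatemort import (
    AgeScheme,
    build_life_table,
    decompose_change,
    expand_terminal_group,
    extend_rates,
    fit_kannisto_thatcher,
    inequality_spread,
    life_expectancy_at,
    life_expectancy_from_rates,
    national_rate,
    quintile_summary,
)
from spatemort.lifetable import KTModel, gap_after_gains, sex_gap


def random_rates(rng, scheme):
    """Plausible J-shaped rates with lognormal noise."""
    from spatemort.simulate import baseline_log_rates

    return np.exp(baseline_log_rates(scheme) + rng.normal(0, 0.2, scheme.n_groups))


class TestBuildLifeTable:
    def test_q_closed_form_by_hand(self, default_scheme):
        """q = n*m / (1 + (n-a)*m): for n=5, a=2.5, m=0.02 -> 0.1/1.05."""
        m = np.full(19, 0.02)
        lt = build_life_table(m, default_scheme)
        assert lt.q[5] == pytest.approx(0.1 / 1.05, rel=1e-12)

    def test_constant_hazard_exponential_limit(self, default_scheme):
        mu = 0.02
        lt = build_life_table(np.full(19, mu), default_scheme, "exponential")
        assert lt.e[0] == pytest.approx(1.0 / mu, abs=1e-9)

    def test_survival_to_85_then_exponential_tail(self, default_scheme):
        m = np.zeros(19)
        m[-1] = 0.5
        lt = build_life_table(m, default_scheme)
        assert lt.e[0] == pytest.approx(85.0 + 2.0, rel=1e-12)
        assert life_expectancy_at(lt, 65.0) == pytest.approx(20.0 + 2.0, rel=1e-12)
        assert life_expectancy_at(lt, 85.0) == pytest.approx(1.0 / 0.5, rel=1e-12)

    def test_identities_hold_on_random_tables(self, default_scheme):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m = random_rates(rng, default_scheme)
            lt = build_life_table(m, default_scheme)
            assert lt.l[0] == pytest.approx(100_000.0)
            assert np.all(np.diff(lt.l) <= 0)
            assert np.all(np.diff(lt.T) <= 0)
            assert lt.q[-1] == 1.0
            assert np.all(lt.L >= 0)
            assert np.allclose(lt.e, lt.T / lt.l, rtol=1e-9)
            assert np.allclose(lt.T, np.cumsum(lt.L[::-1])[::-1], rtol=1e-12)

    def test_open_group_zero_rate_rejected(self, default_scheme):
        m = np.full(19, 0.01)
        m[-1] = 0.0
        with pytest.raises(ValueError, match="open-group"):
            build_life_table(m, default_scheme)

    def test_e0_decreases_when_any_rate_rises(self, default_scheme):
        rng = np.random.default_rng(1)
        m = random_rates(rng, default_scheme)
        base = build_life_table(m, default_scheme).e[0]
        for j in [0, 7, 18]:
            bumped = m.copy()
            bumped[j] *= 1.5
            assert build_life_table(bumped, default_scheme).e[0] < base

    def test_non_boundary_age_rejected(self, default_scheme):
        lt = build_life_table(np.full(19, 0.01), default_scheme)
        with pytest.raises(ValueError):
            life_expectancy_at(lt, 87.0)


class TestKannistoThatcher:
    def test_recovers_exact_logistic(self):
        a, b = 5e-5, 0.1
        ages = np.array([72.5, 77.5, 82.5, 87.5])
        z = a * np.exp(b * ages)
        rates = z / (1 + z)
        kt = fit_kannisto_thatcher(rates, ages)
        assert kt.a_kt == pytest.approx(a, rel=1e-6)
        assert kt.b_kt == pytest.approx(b, rel=1e-6)
        assert not kt.fallback

    def test_constant_rates_trigger_fallback(self):
        with pytest.warns(UserWarning, match="degenerate"):
            kt = fit_kannisto_thatcher(np.full(4, 0.1), np.array([72.5, 77.5, 82.5, 87.5]))
        assert kt.fallback

    def test_hazard_bounded_and_increasing(self):
        kt = KTModel(5e-5, 0.1)
        x = np.linspace(85, 110, 50)
        h = kt.hazard(x)
        assert np.all(h < 1.0) and np.all(np.diff(h) > 0)

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            fit_kannisto_thatcher(np.array([0.0, 0.1]), np.array([72.5, 77.5]))

    def test_fallback_expansion_is_flat(self):
        kt = KTModel(0.1, 0.0, fallback=True)
        rates = expand_terminal_group(0.18, kt)
        assert np.allclose(rates, 0.18)

    def test_expansion_monotone_for_positive_slope(self):
        kt = KTModel(5e-5, 0.1)
        rates = expand_terminal_group(0.18, kt)
        assert np.all(np.diff(rates) > 0)

    def test_conservation_against_independent_cohort_arithmetic(self):
        """Extended rates reproduce the 85+ aggregate of a stationary cohort.

        The oracle rebuilds the stationary population with textbook abridged
        life-table formulas written out in the test.
        """
        kt = KTModel(5e-5, 0.11)
        m85 = 0.2
        rates = expand_terminal_group(m85, kt)
        l, total_l, total_d = 1.0, 0.0, 0.0
        for r in rates[:-1]:
            q = 1.0 - np.exp(-5.0 * r)   # constant hazard within the interval
            d = l * q
            total_l += d / r
            total_d += d
            l -= d
        total_l += l / rates[-1]
        total_d += l
        assert total_d / total_l == pytest.approx(m85, abs=1e-8)


class TestExtendRates:
    def test_extends_scheme_to_100_plus(self, default_scheme):
        rng = np.random.default_rng(2)
        m = random_rates(rng, default_scheme)
        ext, scheme = extend_rates(m, default_scheme)
        assert scheme.n_groups == 22
        assert scheme.group_starts[-1] == 100.0
        assert np.allclose(ext[..., :18], m[..., :18])

    def test_batched_matches_scalar_path(self, default_scheme):
        rng = np.random.default_rng(3)
        batch = np.stack([random_rates(rng, default_scheme) for _ in range(5)])
        ext_batch, _ = extend_rates(batch, default_scheme)
        for i in range(5):
            ext_one, _ = extend_rates(batch[i], default_scheme)
            assert np.allclose(ext_batch[i], ext_one, rtol=1e-10)


class TestDecomposition:
    def test_identical_tables_give_zero(self, default_scheme):
        m = np.full(19, 0.02)
        lt = build_life_table(m, default_scheme)
        assert np.allclose(decompose_change(lt, lt), 0.0, atol=1e-12)

    def test_additivity_on_random_pairs(self, default_scheme):
        rng = np.random.default_rng(4)
        for _ in range(100):
            lt1 = build_life_table(random_rates(rng, default_scheme), default_scheme)
            lt2 = build_life_table(random_rates(rng, default_scheme), default_scheme)
            contrib = decompose_change(lt1, lt2)
            assert contrib.sum() == pytest.approx(lt2.e[0] - lt1.e[0], abs=1e-9)

    def test_single_group_difference_localises(self, default_scheme):
        rng = np.random.default_rng(5)
        m1 = random_rates(rng, default_scheme)
        m2 = m1.copy()
        m2[0] *= 0.5
        lt1 = build_life_table(m1, default_scheme)
        lt2 = build_life_table(m2, default_scheme)
        contrib = decompose_change(lt1, lt2)
        assert contrib[0] == pytest.approx(lt2.e[0] - lt1.e[0], abs=1e-9)
        assert np.allclose(contrib[1:], 0.0, atol=1e-9)

    def test_reversal_antisymmetry_bounded(self, default_scheme):
        rng = np.random.default_rng(6)
        m1 = random_rates(rng, default_scheme)
        m2 = random_rates(rng, default_scheme)
        lt1 = build_life_table(m1, default_scheme)
        lt2 = build_life_table(m2, default_scheme)
        fwd = decompose_change(lt1, lt2)
        rev = decompose_change(lt2, lt1)
        # totals negate exactly (additivity both ways); per-group terms are
        # antisymmetric only to second order in the rate differences
        assert fwd.sum() == pytest.approx(-rev.sum(), abs=1e-9)
        assert np.abs(fwd + rev).max() < 0.25 * np.abs(fwd).max()

    def test_mismatched_schemes_rejected(self, default_scheme, tiny_scheme):
        lt1 = build_life_table(np.full(19, 0.02), default_scheme)
        lt2 = build_life_table(np.array([0.01, 0.1]), tiny_scheme)
        with pytest.raises(ValueError):
            decompose_change(lt1, lt2)


class TestAggregation:
    def test_national_rate_arithmetic(self):
        assert national_rate(np.array([0.01, 0.03]), np.array([100.0, 300.0])) == pytest.approx(0.025)

    def test_equal_rates_unchanged(self):
        assert national_rate(np.full(5, 0.07), np.arange(1.0, 6.0)) == pytest.approx(0.07)

    def test_convexity(self):
        rng = np.random.default_rng(7)
        m = rng.uniform(0.01, 0.1, 8)
        w = rng.uniform(10, 100, 8)
        nat = national_rate(m, w)
        assert m.min() <= nat <= m.max()

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError):
            national_rate(np.array([0.01]), np.array([0.0]))


class TestInequality:
    def test_spread_of_uniform_grid_by_hand(self):
        e0 = 70.0 + 0.1 * np.arange(101)
        spreads, _ = inequality_spread(e0)
        # linear interpolation: 1st pct = 70.1, 99th = 79.9
        assert spreads[0] == pytest.approx(9.8, abs=1e-9)

    def test_equal_districts_give_zero(self):
        spreads, q = inequality_spread(np.full((4, 10), 81.0))
        assert np.allclose(spreads, 0.0)
        assert np.allclose(q, 0.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(8)
        e0 = rng.uniform(75, 85, (6, 30))
        s1, _ = inequality_spread(e0)
        s2, _ = inequality_spread(e0 + 3.7)
        assert np.allclose(s1, s2)

    def test_single_district_rejected(self):
        with pytest.raises(ValueError):
            inequality_spread(np.array([[80.0]]))


class TestQuintiles:
    def test_rank_order_example(self):
        e0 = np.arange(71.0, 81.0)
        dep = np.arange(10.0)  # most deprived has the highest score
        pops = np.full(10, 100.0)
        table = quintile_summary(e0, dep, pops)
        assert np.allclose(table["e0"], [71.5, 73.5, 75.5, 77.5, 79.5])
        assert np.allclose(table["e0_max"] - table["e0_min"], 1.0)

    def test_identical_e0(self):
        table = quintile_summary(np.full(10, 80.0), np.arange(10.0), np.full(10, 1.0))
        assert np.allclose(table["e0"], 80.0)
        assert np.allclose(table["e0_max"] - table["e0_min"], 0.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        e0 = rng.uniform(75, 85, 15)
        dep = rng.uniform(-3, 3, 15)
        pops = rng.uniform(50, 150, 15)
        perm = rng.permutation(15)
        t1 = quintile_summary(e0, dep, pops)
        t2 = quintile_summary(e0[perm], dep[perm], pops[perm])
        assert np.allclose(t1["e0"], t2["e0"])

    def test_missing_deprivation_rejected(self):
        dep = np.array([1.0, np.nan, 3.0, 4.0, 5.0])
        with pytest.raises(ValueError):
            quintile_summary(np.full(5, 80.0), dep, np.full(5, 1.0))


class TestPipelines:
    def test_extension_changes_e0_modestly(self, default_scheme):
        rng = np.random.default_rng(10)
        m = random_rates(rng, default_scheme)
        e_plain = life_expectancy_from_rates(m, default_scheme, extend=False)
        e_ext = life_expectancy_from_rates(m, default_scheme, extend=True)
        assert abs(float(e_ext) - float(e_plain)) < 2.0

    def test_gap_helpers(self):
        assert sex_gap(83.3, 79.5) == pytest.approx(3.8)
        assert gap_after_gains(6.0, 8.2, 6.0) == pytest.approx(3.8)
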