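"""Conditional spike law, Gibbs potential, truncations and expansions."""

import copy
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gifnet as gn
from gifnet.statistics import ENUMERATION_GUARD_BITS, log_one_minus_pi, log_pi

from conftest import decoupled


class TestGaussianTail:
    def test_half_at_zero(self):
        assert gn.pi(0.0) == 0.5

    def test_quantile_value(self):
        assert gn.pi(1.959964) == pytest.approx(0.025, abs=1e-6)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(-6, 6))
    def test_symmetry(self, x):
        assert gn.pi(x) + gn.pi(-x) == pytest.approx(1.0, abs=1e-14)

    def test_strictly_decreasing(self):
        xs = np.linspace(-8, 8, 100)
        assert (np.diff(gn.pi(xs)) < 0).all()


class TestFiringArgument:
    def test_just_reset_neuron(self, example):
        omega = np.zeros((2, 6), dtype=np.int8)
        omega[0, 5] = 1
        raster = gn.Raster(omega, t0=0)
        x = gn.firing_argument(example, raster, 0, 6)
        assert x == pytest.approx(example.theta / example.sigma_R, rel=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_within_uniform_window(self, example, example_bounds, seed):
        raster = gn.fixture("random", 2, 30, seed=seed)
        X = gn.firing_arguments(example, raster, 30)
        assert (example_bounds.X_low < X).all()
        assert (X < example_bounds.X_high).all()

    def test_zero_coupling_matches_leaky_closed_form(self, example):
        p = decoupled(example)
        omega0 = gn.fixture("omega0", 2, 12)
        X = gn.firing_arguments(p, omega0, 12)
        for k in range(2):
            v_inf = p.E_L + p.i_ext.value(k, 0.0) / p.g_L[k]
            sigma = p.sigma_B / p.C[k] * math.sqrt(p.tau_L[k] / 2)
            assert X[k] == pytest.approx((p.theta - v_inf) / sigma, rel=1e-6)


class TestTransitionProbability:
    def test_single_neuron_complement(self, example):
        p1 = copy.deepcopy(example)
        p1.N = 1
        p1.C, p1.g_L = p1.C[:1], p1.g_L[:1]
        p1.G, p1.tau_syn = p1.G[:1, :1], p1.tau_syn[:1, :1]
        p1.pop = p1.pop[:1]
        p1.i_ext = gn.ExternalCurrent.constant(4.0, 1)
        raster = gn.fixture("random", 1, 15, seed=2)
        a = gn.transition_probability(p1, raster, 15, [1]).p_pattern
        b = gn.transition_probability(p1, raster, 15, [0]).p_pattern
        assert a + b == pytest.approx(1.0, abs=1e-14)

    @pytest.mark.parametrize("seed", range(10))
    def test_patterns_sum_to_one(self, seed):
        params = gn.random_parameters(3, seed=seed)
        raster = gn.fixture("random", 3, 25, seed=seed + 50)
        total = sum(
            gn.transition_probability(params, raster, 25, pat).p_pattern
            for pat in itertools.product((0, 1), repeat=3)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_factorizes_over_neurons(self, example, random_history):
        res = gn.transition_probability(example, random_history, 40, [1, 0])
        per_neuron = res.p_fire[0] * (1 - res.p_fire[1])
        assert res.p_pattern == pytest.approx(per_neuron, rel=1e-12)
        assert res.p_pattern == math.exp(res.phi)

    def test_pattern_probability_within_uniform_product_bounds(
        self, example, example_bounds
    ):
        for seed in range(5):
            raster = gn.fixture("random", 2, 30, seed=seed)
            for pat in itertools.product((0, 1), repeat=2):
                res = gn.transition_probability(example, raster, 30, pat)
                assert example_bounds.log_Pi_minus.sum() < res.phi
                assert res.phi < example_bounds.log_Pi_plus.sum()

    def test_monte_carlo_frequencies_match(self, example, random_history):
        table = gn.empirical_transition(example, random_history, 40, 100_000, seed=9)
        resid = np.abs(table["frequency"] - table["probability"])
        assert (resid <= 3 * np.maximum(table["standard_error"], 1e-12)).all()


class TestGibbsPotential:
    def test_single_step_is_log_probability(self, example, random_history):
        n = 30
        phi = gn.gibbs_potential(example, random_history, n, n)
        res = gn.transition_probability(
            example, random_history, n, random_history.column(n)
        )
        assert phi == res.phi

    def test_block_identity_with_transition_products(self, example, random_history):
        phi = gn.gibbs_potential(example, random_history, 28, 30)
        prod = 1.0
        for l in (28, 29, 30):
            prod *= gn.transition_probability(
                example, random_history, l, random_history.column(l)
            ).p_pattern
        assert math.exp(phi) == pytest.approx(prod, abs=1e-12)

    def test_exhaustive_block_normalization(self, example):
        # all 2^(2*3) continuations of a fixed past: conditional block
        # probabilities telescope, so the partition function is exactly 1
        past = gn.fixture("random", 2, 30, seed=11)
        n0 = past.t_end + 1
        total = 0.0
        for bits in itertools.product((0, 1), repeat=6):
            block = np.asarray(bits, dtype=np.int8).reshape(3, 2).T
            r = gn.Raster(np.hstack([past.omega, block]), t0=past.t0)
            total += math.exp(gn.gibbs_potential(example, r, n0, n0 + 2))
        assert total == pytest.approx(1.0, abs=1e-10)


class TestTruncatedPotential:
    def test_normalizer_makes_a_probability(self, example, rng):
        block = (rng.random((2, 3)) < 0.4).astype(np.int8)
        _, Z = gn.truncated_potential(example, block)
        assert Z > 0
        total = 0.0
        for bits in itertools.product((0, 1), repeat=2):
            blk = block.copy()
            blk[:, -1] = bits
            phi, _ = gn.truncated_potential(example, blk)
            total += math.exp(phi) / Z
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_deep_truncation_converges_to_full_potential(self, example):
        # with the memory depth at the truncation horizon, replacing the true
        # past by quiet padding changes the potential by less than the
        # variation envelope at that depth
        full = gn.fixture("random", 2, 40, seed=21)
        n = full.t_end
        phi_full = gn.transition_probability(example, full, n, full.column(n)).phi
        for D in (10, 20, 35):
            block = full.omega[:, full.T - 1 - D :]
            phi_D, _ = gn.truncated_potential(example, block)
            env = gn.analytic_envelope(example, "v_syn", D) + gn.analytic_envelope(
                example, "v_ext", D
            )
            assert abs(phi_D - phi_full) <= max(env, 1e-8) * 10
        d_err = [
            abs(gn.truncated_potential(example, full.omega[:, full.T - 1 - D :])[0] - phi_full)
            for D in (5, 15, 30)
        ]
        assert d_err[2] <= d_err[0] + 1e-12

    def test_enumeration_guard(self, example):
        with pytest.raises(ValueError, match="guard"):
            gn.monomial_expansion(example, D=ENUMERATION_GUARD_BITS // 2 + 1)


class TestMonomialExpansion:
    def test_memoryless_truncation_is_independent_bernoulli(self, example):
        # D = 0: only the constant and the N single-spike monomials survive,
        # with the log-odds of the padded-past firing probabilities
        exp0 = gn.monomial_expansion(example, D=0)
        r = gn.Raster(np.zeros((2, 1), dtype=np.int8), t0=0)
        X = gn.firing_arguments(example, r, 0)
        cross = exp0.lam[(1 << exp0.bit(0, 0)) | (1 << exp0.bit(1, 0))]
        assert abs(cross) < 1e-12
        assert exp0.lam[0] == pytest.approx(float(log_one_minus_pi(X).sum()), abs=1e-12)
        for k in range(2):
            logit = float(log_pi(X[k]) - log_one_minus_pi(X[k]))
            assert exp0.coefficient([(k, 0)]) == pytest.approx(logit, abs=1e-12)

    def test_single_neuron_depth_one_inversion_is_exact(self, example):
        p1 = copy.deepcopy(example)
        p1.N = 1
        p1.C, p1.g_L = p1.C[:1], p1.g_L[:1]
        p1.G, p1.tau_syn = p1.G[:1, :1], p1.tau_syn[:1, :1]
        p1.pop = p1.pop[:1]
        p1.i_ext = gn.ExternalCurrent.constant(4.0, 1)
        exp1 = gn.monomial_expansion(p1, D=1)
        for bits in itertools.product((0, 1), repeat=2):
            block = np.asarray(bits, dtype=np.int8).reshape(1, 2)
            phi, _ = gn.truncated_potential(p1, block)
            assert exp1.evaluate(block) == pytest.approx(phi, abs=1e-12)

    def test_constant_term_is_quiescent_block_value(self, example):
        exp1 = gn.monomial_expansion(example, D=1)
        phi0, _ = gn.truncated_potential(example, np.zeros((2, 2), dtype=np.int8))
        assert exp1.lam[0] == pytest.approx(phi0, abs=1e-12)

    def test_reconstruction_on_random_blocks(self, example, rng):
        exp1 = gn.monomial_expansion(example, D=1)
        for _ in range(6):
            block = (rng.random((2, 2)) < 0.5).astype(np.int8)
            phi, _ = gn.truncated_potential(example, block)
            assert exp1.evaluate(block) == pytest.approx(phi, abs=1e-10)


class TestNoFireBounds:
    def test_single_step_chain(self, example, example_bounds):
        lo, hi = gn.no_fire_probability_bounds(example, 0, 1, example_bounds)
        assert 0 < lo < hi <= 1

    def test_geometric_decay(self, example, example_bounds):
        prev = (1.0, 1.0)
        for L in (1, 3, 6, 12):
            lo, hi = gn.no_fire_probability_bounds(example, 0, L, example_bounds)
            assert lo < prev[0] and hi <= prev[1]
            prev = (lo, hi)


class TestUniquenessCriteria:
    def test_hypotheses_hold_numerically(self, example):
        m_lo, v_est = gn.uniqueness_criteria(example, m_max=5, n_pairs=2)
        assert m_lo > 0
        assert np.isfinite(v_est) and v_est > 0

    def test_partial_sums_increase_toward_estimate(self, example):
        rep = gn.empirical_variation(
            example, "transition", 0.0, list(range(0, 7)), n_pairs=2, seed=0
        )
        partial = np.cumsum(rep.var_m)
        assert (np.diff(partial) >= 0).all()
        _, v_est = gn.uniqueness_criteria(example, m_max=6, n_pairs=2)
        assert partial[-1] <= v_est

    def test_decoupled_network_forgets_faster(self, example):
        p0 = decoupled(example)
        rep = gn.empirical_variation(
            p0, "transition", 0.0, [3, 6, 9], n_pairs=2, seed=0
        )
        rep_c = gn.empirical_variation(
            example, "transition", 0.0, [3, 6, 9], n_pairs=2, seed=0
        )
        # without synapses only the reset-time memory remains, so the
        # variation collapses much faster than in the coupled network
        assert rep.var_m[-1] <= rep_c.var_m[-1] + 1e-12
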