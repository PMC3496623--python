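"""Effective leak, potential decomposition and the conditional Gaussian law."""

import copy
import math

import numpy as np
import pytest

import gifnet as gn
from gifnet.potential import QuadratureScheme, decompose
from gifnet.raster import NEVER

from conftest import decoupled


class TestEffectiveLeak:
    def test_coincident_endpoints_give_one(self, example, random_history):
        assert gn.effective_leak(example, random_history, 0, 3.7, 3.7) == 1.0

    def test_zero_coupling_closed_form(self, example, random_history):
        p = decoupled(example)
        for k in range(2):
            got = gn.effective_leak(p, random_history, k, 1.3, 6.8)
            assert got == pytest.approx(math.exp(-5.5 / p.tau_L[k]), rel=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_sandwiched_by_relaxation_times(self, example, example_bounds, seed):
        raster = gn.fixture("random", 2, 25, seed=seed)
        rng = np.random.default_rng(seed)
        for _ in range(5):
            t2 = float(rng.uniform(8, 24))
            t1 = t2 - float(rng.uniform(0.1, 6))
            for k in range(2):
                g = gn.effective_leak(example, raster, k, t1, t2)
                lo = math.exp(-(t2 - t1) / example_bounds.tau_M[k])
                hi = math.exp(-(t2 - t1) / example_bounds.tau_L[k])
                assert lo - 1e-10 <= g <= hi + 1e-10

    def test_semigroup_property(self, example, random_history, rng):
        for _ in range(5):
            t = float(rng.uniform(10, 35))
            t2 = t - float(rng.uniform(0.1, 3))
            t1 = t2 - float(rng.uniform(0.1, 3))
            full = gn.effective_leak(example, random_history, 0, t1, t)
            split = gn.effective_leak(example, random_history, 0, t1, t2) * gn.effective_leak(
                example, random_history, 0, t2, t
            )
            assert full == pytest.approx(split, rel=1e-10)

    def test_reversed_endpoints_rejected(self, example, random_history):
        with pytest.raises(ValueError):
            gn.effective_leak(example, random_history, 0, 5.0, 4.0)


class TestSynapticPotential:
    def test_zero_weights_give_zero(self, example, random_history):
        p = decoupled(example)
        assert gn.v_syn(p, random_history, 0, 2.0, 9.0) == 0.0

    def test_within_weight_sandwich(self, example, example_bounds):
        # bounded by (alpha+/g_L) times the inhibitory / excitatory weight sums
        W = example.W
        exc = example.pop == "E"
        for seed in range(4):
            raster = gn.fixture("random", 2, 25, seed=seed)
            for k in range(2):
                v = gn.v_syn(example, raster, k, 3.0, 22.0)
                lo = example_bounds.alpha_plus / example.g_L[k] * (W[k] * ~exc).sum()
                hi = example_bounds.alpha_plus / example.g_L[k] * (W[k] * exc).sum()
                assert lo - 1e-10 <= v <= hi + 1e-10

    def test_single_spike_matches_fine_grid_oracle(self):
        # one presynaptic spike, one synapse: compare the nested quadrature
        # against a brute-force trapezoid evaluation of the double integral
        # (degree-1 kernel: continuous at the spike time, so the fine-grid
        # reference is itself accurate to O(dt^2))
        p = gn.example_parameters(profile_degree=1)
        p.E_L = 0.0
        p.i_ext = gn.ExternalCurrent.constant(0.0, 2)
        omega = np.zeros((2, 8), dtype=np.int8)
        omega[1, 2] = 1  # presynaptic spike at time 2
        raster = gn.Raster(omega, t0=0)
        k, j, s, t = 0, 1, 0.0, 7.0
        got = gn.v_syn(p, raster, k, s, t)

        dt = 1e-4
        u = np.arange(s, t + dt / 2, dt)
        prof = p.profile(k, j)
        al = np.asarray(gn.alpha(prof, u - 2.0))
        g = p.g_L[k] + p.G[k, j] * al
        A = np.concatenate([[0.0], np.cumsum((g[1:] + g[:-1]) / 2 * dt)])
        gamma = np.exp(-(A[-1] - A) / p.C[k])
        integrand = gamma * al
        ref = p.W[k, j] / p.C[k] * np.trapezoid(integrand, dx=dt)
        assert got == pytest.approx(ref, rel=1e-6)


class TestExternalPotential:
    def test_zero_coupling_constant_current_closed_form(self, example):
        p = decoupled(example)
        omega0 = gn.fixture("omega0", 2, 10)
        i = p.i_ext.value(0, 0.0)
        for k in range(2):
            got = gn.v_ext(p, omega0, k, 1.0, 8.0)
            ref = (p.E_L + i / p.g_L[k]) * (1 - math.exp(-7.0 / p.tau_L[k]))
            assert got == pytest.approx(ref, rel=1e-9)

    def test_zero_sources_give_zero(self, example, random_history):
        p = copy.deepcopy(example)
        p.E_L = 0.0
        p.i_ext = gn.ExternalCurrent.constant(0.0, 2)
        assert gn.v_ext(p, random_history, 0, 2.0, 9.0) == 0.0

    def test_uniform_bound(self, example, example_bounds):
        cap = abs(example.E_L) + example_bounds.i_plus / example.g_L
        for seed in range(4):
            raster = gn.fixture("random", 2, 25, seed=seed)
            for k in range(2):
                v = gn.v_ext(example, raster, k, NEVER, 20.0)
                assert abs(v) <= cap[k] + 1e-9

    def test_piecewise_current_breakpoints_are_resolved(self, example):
        # sub-unit square-wave stimulus, constant conductance: compare the
        # piece-aware quadrature against an exact piecewise closed form
        p = decoupled(example)
        p.E_L = 0.0
        p.i_ext = gn.ExternalCurrent(offsets=[0.0, 0.5], values=[[4.0, 4.0], [0.0, 0.0]])
        omega0 = gn.fixture("omega0", 2, 40)
        t = 30.25
        got = gn.v_ext(p, omega0, 0, 5.0, t)
        tau = p.tau_L[0]
        edges = np.concatenate([[5.0], np.arange(5.5, t, 0.5), [t]])
        ref = 0.0
        for a, b in zip(edges[:-1], edges[1:]):
            i_val = p.i_ext.value(0, (a + b) / 2)
            ref += i_val / p.g_L[0] * (math.exp(-(t - b) / tau) - math.exp(-(t - a) / tau))
        assert got == pytest.approx(ref, rel=1e-9)


class TestNoiseVariance:
    def test_just_reset_returns_reset_variance(self, example):
        omega = np.zeros((2, 6), dtype=np.int8)
        omega[0, 5] = 1
        raster = gn.Raster(omega, t0=0)
        assert gn.noise_variance(example, raster, 0, 5.0) == example.sigma_R**2

    def test_zero_coupling_stationary_closed_form(self, example):
        p = decoupled(example)
        omega0 = gn.fixture("omega0", 2, 10)
        for k in range(2):
            got = gn.noise_variance(p, omega0, k, 8.0)
            ref = (p.sigma_B / p.C[k]) ** 2 * p.tau_L[k] / 2
            assert got == pytest.approx(ref, rel=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_within_sigma_sandwich(self, example, example_bounds, seed):
        raster = gn.fixture("random", 2, 25, seed=seed)
        rng = np.random.default_rng(seed + 40)
        for _ in range(5):
            t = float(rng.uniform(5, 24))
            for k in range(2):
                s2 = gn.noise_variance(example, raster, k, t)
                assert example_bounds.sigma_minus[k] ** 2 - 1e-9 <= s2
                assert s2 <= example_bounds.sigma_plus[k] ** 2 + 1e-9


class TestConditionalLaw:
    def test_zero_coupling_matches_leaky_closed_forms(self, example):
        p = decoupled(example)
        omega0 = gn.fixture("omega0", 2, 10)
        means, variances = gn.conditional_law(p, omega0, 9.0)
        i = p.i_ext.value(0, 0.0)
        for k in range(2):
            assert means[k] == pytest.approx(p.E_L + i / p.g_L[k], rel=1e-6)
            assert variances[k] == pytest.approx(
                (p.sigma_B / p.C[k]) ** 2 * p.tau_L[k] / 2, rel=1e-6
            )

    def test_quadrature_refinement_is_converged(self, example, random_history):
        coarse = QuadratureScheme(order=8, subdiv=1)
        fine = QuadratureScheme(order=8, subdiv=2)
        for k in range(2):
            d1 = decompose(example, random_history, k, 31.4, coarse)
            d2 = decompose(example, random_history, k, 31.4, fine)
            assert d1.V_det == pytest.approx(d2.V_det, abs=1e-9)
            assert d1.sigma2 == pytest.approx(d2.sigma2, abs=1e-9)

    def test_truncation_error_is_reported_and_small(self, example):
        omega0 = gn.fixture("omega0", 2, 10)
        d = decompose(example, omega0, 0, 9.0)
        assert d.tau_k == NEVER
        assert 0 < d.truncation_error_bound < 1e-6
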