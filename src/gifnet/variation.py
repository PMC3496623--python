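"""Memory decay: empirical m-variation curves and their analytic envelopes.

The ``m``-variation of a history-dependent quantity ``f(t, omega)`` is the
largest change of ``f`` over pairs of histories that agree on the most recent
``m + 1`` integer times and may differ arbitrarily before.  Its decay with
``m`` expresses the fading memory of the network: conductances forget at the
synaptic decay rate, membrane quantities at the slower of the synaptic and
leak rates.

The supremum runs over uncountably many pasts; here it is *lower-bounded* by
evaluating the quantity on adversarial pairs -- a shared random suffix glued
onto the all-quiet and all-firing prefixes (the extreme conductance states)
-- plus seeded random pairs.  Envelope comparisons are therefore valid
one-sided tests: the empirical curve must stay below the analytic bound
wherever the bound's constants apply.  The envelopes themselves hold in the
asymptotic (Hardy ``<~``) sense, so every comparison carries an explicit
onset depth ``m0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import kernels
from .params import ModelParameters, derive_bounds
from .potential import QuadratureScheme, decompose, effective_leak
from .raster import Raster
from .statistics import transition_probability

__all__ = [
    "VariationReport",
    "empirical_variation",
    "analytic_envelope",
    "transition_variation_tail",
    "QUANTITIES",
]

#: Fixed lag used for the effective-leak variation quantity.
GAMMA_LAG = 10.0

QUANTITIES = (
    "alpha_sum",
    "conductance",
    "gamma",
    "v_syn",
    "v_ext",
    "sigma2",
    "transition",
)


@dataclass(frozen=True)
class VariationReport:
    """Empirical variation curve of one quantity, with fit and envelope."""

    quantity: str
    m: np.ndarray
    var_m: np.ndarray  # max |difference| over sampled history pairs
    envelope: np.ndarray | None  # analytic bound where defined, else None
    fitted_slope: float  # slope of log var_m vs m over the decaying range


def _evaluate(
    params: ModelParameters,
    quantity: str,
    raster: Raster,
    t: float,
    scheme: QuadratureScheme,
) -> float:
    if quantity == "alpha_sum":
        return max(
            kernels.alpha_sum(params, raster, k, j, t, tol=scheme.tol)
            for k in range(params.N)
            for j in range(params.N)
        )
    if quantity == "conductance":
        return max(
            kernels.conductance(params, raster, k, t, tol=scheme.tol)
            for k in range(params.N)
        )
    if quantity == "gamma":
        return max(
            effective_leak(params, raster, k, t - GAMMA_LAG, t, scheme)
            for k in range(params.N)
        )
    if quantity in ("v_syn", "v_ext", "sigma2"):
        vals = []
        for k in range(params.N):
            d = decompose(params, raster, k, t, scheme)
            vals.append({"v_syn": d.V_syn, "v_ext": d.V_ext, "sigma2": d.sigma2}[quantity])
        return max(vals)
    if quantity == "transition":
        n = math.floor(t)
        return transition_probability(params, raster, n, raster.column(n), scheme).p_pattern
    raise ValueError(f"unknown quantity {quantity!r}; choose from {QUANTITIES}")


def _diff(
    params: ModelParameters,
    quantity: str,
    r1: Raster,
    r2: Raster,
    t: float,
    scheme: QuadratureScheme,
) -> float:
    if quantity == "transition":
        n = math.floor(t)
        pat = r1.column(n)  # suffix is shared, so both rasters carry it
        p1 = transition_probability(params, r1, n, pat, scheme).p_pattern
        p2 = transition_probability(params, r2, n, pat, scheme).p_pattern
        return abs(p1 - p2)
    if quantity == "alpha_sum":
        return max(
            abs(
                kernels.alpha_sum(params, r1, k, j, t, tol=scheme.tol)
                - kernels.alpha_sum(params, r2, k, j, t, tol=scheme.tol)
            )
            for k in range(params.N)
            for j in range(params.N)
        )
    if quantity == "conductance":
        return max(
            abs(
                kernels.conductance(params, r1, k, t, tol=scheme.tol)
                - kernels.conductance(params, r2, k, t, tol=scheme.tol)
            )
            for k in range(params.N)
        )
    if quantity == "gamma":
        return max(
            abs(
                effective_leak(params, r1, k, t - GAMMA_LAG, t, scheme)
                - effective_leak(params, r2, k, t - GAMMA_LAG, t, scheme)
            )
            for k in range(params.N)
        )
    out = 0.0
    for k in range(params.N):
        d1 = decompose(params, r1, k, t, scheme)
        d2 = decompose(params, r2, k, t, scheme)
        v1 = {"v_syn": d1.V_syn, "v_ext": d1.V_ext, "sigma2": d1.sigma2}[quantity]
        v2 = {"v_syn": d2.V_syn, "v_ext": d2.V_ext, "sigma2": d2.sigma2}[quantity]
        out = max(out, abs(v1 - v2))
    return out


class _PairFamily:
    """Nested history pairs: one shared suffix realization, fixed prefixes.

    The suffix (columns ``[t]-m_max .. [t]``) and all prefix realizations are
    drawn once; the pair at depth ``m`` shares the last ``m + 1`` suffix
    columns and exposes the prefixes (and everything older) as disagreement.
    Pair 0 is the adversarial all-quiet / all-firing pair (extreme
    conductance states, both as explicit columns and as padding); the rest
    use independent Bernoulli prefixes.  Nesting makes the resulting
    variation curves comparable across depths.
    """

    def __init__(
        self,
        params: ModelParameters,
        t: float,
        m_max: int,
        n_pairs: int,
        rng: np.random.Generator,
        prefix_len: int,
    ):
        N = params.N
        self.n = math.floor(t)
        self.m_max = m_max
        self.prefix_len = prefix_len
        self.suffix = (rng.random((N, m_max + 1)) < 0.4).astype(np.int8)
        self.prefixes: list[tuple[np.ndarray, str, np.ndarray, str]] = [
            (
                np.zeros((N, prefix_len), dtype=np.int8),
                "zeros",
                np.ones((N, prefix_len), dtype=np.int8),
                "ones",
            )
        ]
        for _ in range(max(0, n_pairs - 1)):
            pa = (rng.random((N, prefix_len)) < 0.5).astype(np.int8)
            pb = (rng.random((N, prefix_len)) < 0.5).astype(np.int8)
            self.prefixes.append((pa, "zeros", pb, "zeros"))

    def pairs(self, m: int) -> list[tuple[Raster, Raster]]:
        if m > self.m_max:
            raise ValueError("depth exceeds the prepared suffix length")
        suf = self.suffix[:, self.m_max - m :]
        t0 = self.n - m - self.prefix_len
        out = []
        for pa, pada, pb, padb in self.prefixes:
            out.append(
                (
                    Raster(np.hstack([pa, suf]), t0=t0, padding=pada),
                    Raster(np.hstack([pb, suf]), t0=t0, padding=padb),
                )
            )
        return out


def empirical_variation(
    params: ModelParameters,
    quantity: str,
    t: float,
    m_list,
    n_pairs: int = 4,
    seed: int | None = 0,
    scheme: QuadratureScheme | None = None,
    prefix_len: int | None = None,
) -> VariationReport:
    """Empirical (lower-bound) m-variation curve of ``quantity`` at time ``t``.

    For each depth in ``m_list`` the maximum absolute difference of the
    quantity over ``n_pairs`` nested history pairs (see :class:`_PairFamily`)
    is recorded.  The fitted slope is the least-squares slope of
    ``log var_m`` against ``m`` over the strictly positive entries.
    """
    if quantity not in QUANTITIES:
        raise ValueError(f"unknown quantity {quantity!r}; choose from {QUANTITIES}")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    scheme = scheme or QuadratureScheme()
    rng = np.random.default_rng(seed)
    if prefix_len is None:
        prefix_len = int(max(20, 3 * params.tau_L.max() + params.tau_syn.max()))
    m_arr = np.asarray(list(m_list), dtype=int)
    family = _PairFamily(params, t, int(m_arr.max()), n_pairs, rng, prefix_len)
    var = np.zeros(m_arr.size)
    for i, m in enumerate(m_arr):
        best = 0.0
        for r1, r2 in family.pairs(int(m)):
            best = max(best, _diff(params, quantity, r1, r2, t, scheme))
        var[i] = best
    env = None
    if quantity in ("v_syn", "v_ext", "sigma2"):
        b = derive_bounds(params)
        env = np.array(
            [analytic_envelope(params, quantity, int(m), bounds=b) for m in m_arr]
        )
    pos = var > 0
    slope = float("nan")
    if pos.sum() >= 2:
        slope = float(np.polyfit(m_arr[pos], np.log(var[pos]), 1)[0])
    return VariationReport(
        quantity=quantity, m=m_arr, var_m=var, envelope=env, fitted_slope=slope
    )


def _tail_poly(params: ModelParameters, k: int, j: int, m: float) -> float:
    """Kernel tail factor ``P_d(m/tau_kj) e^{-m/tau_kj}`` (tail-integral form)."""
    return kernels.tail_bound(params.profile(k, j), m)


def analytic_envelope(params: ModelParameters, quantity: str, m: int, bounds=None) -> float:
    """Closed-form variation envelope (asymptotic bound), max over neurons.

    The synaptic-potential envelope is
    ``sum_j A_kj P_d(m/tau_kj) e^{-m/tau_kj} + B_k e^{-m/tau_L,k}`` with
    constants built from the weights, the kernel-sum bound and the leak
    conductance; the external-potential and variance envelopes have the same
    structure (the variance decays at twice the leak rate in its second
    term).
    """
    b = bounds if bounds is not None else derive_bounds(params)
    W = params.W
    out = 0.0
    for k in range(params.N):
        gl = params.g_L[k]
        w_abs = np.abs(W[k]).sum()
        if quantity == "v_syn":
            B = b.alpha_plus / gl * w_abs
            val = B * math.exp(-m / params.tau_L[k])
            for j in range(params.N):
                A = (
                    2.0 * abs(W[k, j])
                    + b.alpha_plus * params.G[k, j] / gl * w_abs
                ) / gl
                val += A * _tail_poly(params, k, j, m)
        elif quantity == "v_ext":
            B = abs(params.E_L) + b.i_plus / gl
            val = B * math.exp(-m / params.tau_L[k])
            for j in range(params.N):
                A = 2.0 * params.G[k, j] / gl * B
                val += A * _tail_poly(params, k, j, m)
        elif quantity == "sigma2":
            s2 = (params.sigma_B * params.tau_L[k] / params.C[k]) ** 2
            Cs = 0.5 * s2 + 2.0 * params.sigma_R**2
            val = Cs * math.exp(-2.0 * m / params.tau_L[k])
            for j in range(params.N):
                A = params.G[k, j] / gl * s2
                val += A * _tail_poly(params, k, j, m)
        else:
            raise ValueError(
                "analytic envelopes exist for 'v_syn', 'v_ext' and 'sigma2'"
            )
        out = max(out, val)
    return out


def transition_variation_tail(params: ModelParameters, m_from: int) -> float:
    """Analytic bound on ``sum_{m > m_from} var_m`` of the transition probability.

    Combines the deterministic-potential and variance envelopes through the
    Lipschitz constant of the Gaussian tail (``1/sqrt(2 pi)``) and sums the
    resulting geometric-with-polynomial series term by term until negligible.
    """
    b = derive_bounds(params)
    total = 0.0
    for k in range(params.N):
        inv_sig = 1.0 / b.sigma_minus[k]
        x_amp = max(
            abs(params.theta - b.V_minus[k]), abs(params.theta - b.V_plus[k])
        )
        coef_sig = x_amp / (2.0 * b.sigma_minus[k] ** 3)
        m = m_from + 1
        while True:
            term = inv_sig * (
                analytic_envelope(params, "v_syn", m, bounds=b)
                + analytic_envelope(params, "v_ext", m, bounds=b)
            ) + coef_sig * analytic_envelope(params, "sigma2", m, bounds=b)
            total += term
            m += 1
            if term < 1e-14 or m > m_from + 10000:
                break
    return total / math.sqrt(2.0 * math.pi)
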