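"""Exact spike-train statistics of the conductance-based network.

Conditionally on its whole spike history the network's next spiking pattern
factorizes over neurons: neuron ``k`` fires at integer time ``n`` with
probability ``pi(X_k(n-1, omega))`` where

    X_k(n-1, omega) = (theta - V_det_k(tau_k, n-1, omega)) / sigma_k(...)

is the threshold distance in units of the conditional standard deviation and
``pi`` is the upper Gaussian tail.  The log of the one-step transition
probability is the Gibbs potential ``phi(n, omega)``; summed over a block of
times it gives the exact block probability (the partition function of the
full, infinite-memory potential is identically 1).

Finite-memory truncations replace the infinite past by a declared boundary
padding.  A truncated potential over blocks of depth ``D`` is a pseudo-Boolean
function of ``N*(D+1)`` spike bits and therefore has an exact expansion over
spike-product monomials; the coefficients are obtained by Moebius inversion.
Because the potential is causal -- the time-0 spins enter linearly, each
multiplied by a function of the strict past -- every monomial containing two
or more time-0 factors has a vanishing coefficient, which is why memoryless
(Ising-style) truncations degenerate to independent Bernoulli neurons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr, ndtr

from .params import DerivedBounds, ModelParameters, derive_bounds
from .potential import QuadratureScheme, decompose
from .raster import Raster

__all__ = [
    "pi",
    "log_pi",
    "log_one_minus_pi",
    "firing_argument",
    "firing_arguments",
    "TransitionResult",
    "transition_probability",
    "gibbs_potential",
    "truncated_potential",
    "PotentialExpansion",
    "monomial_expansion",
    "no_fire_probability_bounds",
    "uniqueness_criteria",
    "ENUMERATION_GUARD_BITS",
]

#: Exhaustive block enumerations are refused above this many spike bits.
ENUMERATION_GUARD_BITS = 22


def pi(x):
    """Upper Gaussian tail ``pi(x) = P(Z >= x)``, strictly decreasing in x."""
    return ndtr(-np.asarray(x, dtype=float)) if np.ndim(x) else float(ndtr(-x))


def log_pi(x):
    """``log pi(x)``, numerically stable far into the tail."""
    return log_ndtr(-np.asarray(x, dtype=float))


def log_one_minus_pi(x):
    """``log(1 - pi(x)) = log P(Z < x)``."""
    return log_ndtr(np.asarray(x, dtype=float))


def firing_argument(
    params: ModelParameters,
    raster: Raster,
    k: int,
    n: int,
    scheme: QuadratureScheme | None = None,
) -> float:
    """Threshold distance ``X_k(n-1, omega)`` deciding the firing probability at ``n``.

    Always finite: the conditional standard deviation is bounded below by a
    positive constant, so firing probabilities are never exactly 0 or 1.
    """
    d = decompose(params, raster, k, n - 1, scheme)
    return (params.theta - d.V_det) / math.sqrt(d.sigma2)


def firing_arguments(
    params: ModelParameters,
    raster: Raster,
    n: int,
    scheme: QuadratureScheme | None = None,
) -> np.ndarray:
    """``X_k(n-1, omega)`` for every neuron."""
    return np.array(
        [firing_argument(params, raster, k, n, scheme) for k in range(params.N)]
    )


@dataclass(frozen=True)
class TransitionResult:
    """One-step conditional law of the spiking pattern at time ``n``."""

    n: int
    X: np.ndarray  # per-neuron threshold distances at n-1
    p_fire: np.ndarray  # per-neuron firing probabilities pi(X_k)
    pattern: np.ndarray
    p_pattern: float  # probability of the queried pattern
    phi: float  # Gibbs potential value log p_pattern
    phi_k: np.ndarray  # per-neuron additive contributions


def _transition_from_X(X: np.ndarray, pattern: np.ndarray, n: int) -> TransitionResult:
    pattern = np.asarray(pattern, dtype=np.int8)
    lp = log_pi(X)
    lq = log_one_minus_pi(X)
    phi_k = np.where(pattern == 1, lp, lq)
    phi = float(phi_k.sum())
    return TransitionResult(
        n=n,
        X=X,
        p_fire=pi(X),
        pattern=pattern,
        p_pattern=math.exp(phi),
        phi=phi,
        phi_k=phi_k,
    )


def transition_probability(
    params: ModelParameters,
    raster: Raster,
    n: int,
    pattern,
    scheme: QuadratureScheme | None = None,
) -> TransitionResult:
    """Probability of spiking pattern ``pattern`` at time ``n`` given the history.

    The raster must cover (with its padding) the history up to ``n - 1``.
    The probability is the product of per-neuron Bernoulli terms, strictly
    inside (0, 1), and sums to 1 over the ``2^N`` possible patterns.
    """
    X = firing_arguments(params, raster, n, scheme)
    return _transition_from_X(X, pattern, n)


def gibbs_potential(
    params: ModelParameters,
    raster: Raster,
    m: int,
    n: int,
    scheme: QuadratureScheme | None = None,
) -> float:
    """Summed Gibbs potential ``sum_{l=m}^{n} phi(l, omega)`` along the raster.

    ``exp`` of the result is the conditional probability of the spike block
    ``omega_m^n`` given the history before ``m``.
    """
    if m > n:
        raise ValueError("gibbs_potential requires m <= n")
    total = 0.0
    for l in range(m, n + 1):
        res = transition_probability(params, raster, l, raster.column(l), scheme)
        total += res.phi
    return total


def _check_guard(n_bits: int) -> None:
    if n_bits > ENUMERATION_GUARD_BITS:
        raise ValueError(
            f"exhaustive enumeration over {n_bits} spike bits exceeds the "
            f"{ENUMERATION_GUARD_BITS}-bit guard; reduce N or the memory depth"
        )


def truncated_potential(
    params: ModelParameters,
    block: np.ndarray,
    boundary: str = "zeros",
    scheme: QuadratureScheme | None = None,
) -> tuple[float, float]:
    """Finite-memory potential ``phi^(D)`` of a spike block and its normalizer.

    ``block`` is an ``N x (D+1)`` array holding the spiking patterns at times
    ``-D .. 0``; the infinite past before ``-D`` is replaced by the declared
    ``boundary`` padding.  Returns ``(phi_D, Z)`` where ``Z`` sums
    ``exp(phi^(D))`` over the time-0 pattern given the block's own past; by
    construction ``exp(phi^(D)) / Z`` is a valid conditional probability.
    """
    block = np.asarray(block, dtype=np.int8)
    N, depth1 = block.shape
    if N != params.N:
        raise ValueError("block row count must equal the neuron count")
    _check_guard(N)  # the normalizer enumerates the 2^N time-0 patterns
    D = depth1 - 1
    r = Raster(block, t0=-D, padding=boundary)
    res = transition_probability(params, r, 0, block[:, -1], scheme)
    # X depends only on the strict past, shared by all time-0 patterns
    lp = log_pi(res.X)
    lq = log_one_minus_pi(res.X)
    Z = 0.0
    for mask in range(1 << N):
        bits = (mask >> np.arange(N)) & 1
        Z += math.exp(float(np.where(bits == 1, lp, lq).sum()))
    return res.phi, float(Z)


@dataclass(frozen=True)
class PotentialExpansion:
    """Exact monomial expansion of a depth-``D`` truncated potential.

    ``lam`` maps each subset of spike bits (an integer mask over the
    ``N*(D+1)`` positions, bit ``(n+D)*N + k`` standing for "neuron ``k``
    spikes at time ``n``") to the coefficient of the corresponding monomial
    ``prod omega_k(n)``.  The expansion reproduces the truncated potential on
    every block; its coefficients depend on the declared boundary past.
    """

    N: int
    D: int
    boundary_past: str
    lam: np.ndarray  # length 2^(N*(D+1)), indexed by bit mask
    phi_values: np.ndarray  # truncated potential on every block, same indexing

    def bit(self, k: int, n: int) -> int:
        """Bit position of the spike indicator of neuron ``k`` at time ``n`` (n in -D..0)."""
        return (n + self.D) * self.N + k

    def coefficient(self, pairs) -> float:
        """Coefficient of the monomial over ``pairs = [(k1, n1), ...]``."""
        mask = 0
        for k, n in pairs:
            mask |= 1 << self.bit(k, n)
        return float(self.lam[mask])

    def evaluate(self, block: np.ndarray) -> float:
        """Reconstruct ``phi^(D)(block)`` from the monomial coefficients."""
        block = np.asarray(block, dtype=np.int8)
        bits = block.T.ravel()  # time-major, matching the bit layout
        mask = int(np.sum(bits.astype(np.int64) << np.arange(bits.size)))
        total = 0.0
        sub = mask
        while True:
            total += self.lam[sub]
            if sub == 0:
                break
            sub = (sub - 1) & mask
        return float(total)


def monomial_expansion(
    params: ModelParameters,
    D: int,
    boundary: str = "zeros",
    scheme: QuadratureScheme | None = None,
) -> PotentialExpansion:
    """Expand the depth-``D`` truncated potential over spike monomials.

    Evaluates ``phi^(D)`` on all ``2^(N(D+1))`` binary blocks and Moebius-
    inverts the table: ``lam_S = sum_{T subset S} (-1)^{|S \\ T|} phi(T)``.
    The time-0 spins enter the potential linearly, so the histories (lower
    ``N*D`` bits) are evaluated once each and the two tail terms reused for
    every time-0 pattern.
    """
    N = params.N
    n_bits = N * (D + 1)
    _check_guard(n_bits)
    n_hist_bits = N * D
    phi_vals = np.empty(1 << n_bits)
    for hist_mask in range(1 << n_hist_bits):
        if D > 0:
            hist_bits = (hist_mask >> np.arange(n_hist_bits)) & 1
            block_past = hist_bits.reshape(D, N).T.astype(np.int8)
        else:
            block_past = np.zeros((N, 0), dtype=np.int8)
        r = Raster(
            np.hstack([block_past, np.zeros((N, 1), dtype=np.int8)]),
            t0=-D,
            padding=boundary,
        )
        X = firing_arguments(params, r, 0, scheme)
        lp = log_pi(X)
        lq = log_one_minus_pi(X)
        for now_mask in range(1 << N):
            bits = (now_mask >> np.arange(N)) & 1
            phi_vals[(now_mask << n_hist_bits) | hist_mask] = float(
                np.where(bits == 1, lp, lq).sum()
            )
    lam = phi_vals.copy()
    for b in range(n_bits):
        step = 1 << b
        mask_has = (np.arange(1 << n_bits) & step).astype(bool)
        lam[mask_has] -= lam[np.arange(1 << n_bits)[mask_has] ^ step]
    return PotentialExpansion(
        N=N, D=D, boundary_past=boundary, lam=lam, phi_values=phi_vals
    )


def no_fire_probability_bounds(
    params: ModelParameters,
    k: int,
    length: int,
    bounds: DerivedBounds | None = None,
) -> tuple[float, float]:
    """Geometric bounds on the probability that neuron ``k`` stays silent.

    Each one-step conditional silence probability lies strictly inside the
    uniform per-neuron window ``(Pi-_k, Pi+_k)``, so the probability of a
    silent stretch of ``length`` steps lies inside its ``length``-th powers --
    silence becomes exponentially unlikely, but never impossible.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    b = bounds or derive_bounds(params)
    return float(b.Pi_minus[k] ** length), float(b.Pi_plus[k] ** length)


def uniqueness_criteria(
    params: ModelParameters,
    t: float = 0.0,
    m_max: int = 8,
    n_pairs: int = 8,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Numerical check of the two uniqueness hypotheses for the spike chain.

    Returns ``(m_p_lower, v_p_estimate)``: a certified positive lower bound on
    the one-step pattern probabilities (the product of the per-neuron
    ``Pi-_k``), and an estimate of the summed transition-probability variation
    -- the empirical partial sum over depths ``0..m_max`` plus the analytic
    geometric tail of the variation envelope.  The second number is an
    estimate (the supremum over pasts is sampled, not exhausted), not a proof.
    """
    from .variation import empirical_variation, transition_variation_tail

    b = derive_bounds(params)
    m_lower = b.Pi_prod_minus
    report = empirical_variation(
        params, "transition", t, list(range(m_max + 1)), n_pairs, seed
    )
    partial = float(np.sum(report.var_m))
    tail = transition_variation_tail(params, m_max)
    return float(m_lower), partial + tail
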