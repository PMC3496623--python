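"""Membrane-potential decomposition for a fixed spike history.

Between resets the membrane potential of neuron ``k`` obeys the linear
equation ``C_k dV/dt + g_k(t, omega) V = i_k(t, omega)`` whose conductance is
fixed by the raster.  Integrating it yields, at any query time ``t``:

* the effective leak ``Gamma_k(t1, t2, omega) = exp(-1/C_k int_{t1}^{t2} g_k)``,
  the memory-decay factor of the membrane;
* the synaptic potential ``V_syn`` (leak-weighted integral of the synaptic
  current), the external potential ``V_ext`` (leak reversal plus stimulus
  term) and their sum ``V_det``, the conditional mean of ``V_k(t)``;
* the conditional variance ``sigma_k^2 = Gamma^2 sigma_R^2 +
  (sigma_B/C_k)^2 int Gamma^2``, combining the random reset value carried
  forward and the accumulated membrane noise.

Conditionally on the spike history, ``V(t)`` is Gaussian with this mean and
variance and independent across neurons (each neuron has its own noise and
reset streams).

All integrands are smooth except at integer times (where new spikes switch
on) and at external-current breakpoints, so composite Gauss-Legendre
quadrature on sub-intervals that never straddle such a point converges
spectrally.  Lower integration limits at the "never reset" sentinel are
replaced by a finite horizon chosen from the leak-decay envelope; the
neglected mass is reported as ``truncation_error_bound``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import kernels
from .params import ModelParameters
from .raster import NEVER, Raster, last_reset

__all__ = [
    "QuadratureScheme",
    "PotentialDecomposition",
    "effective_leak",
    "v_syn",
    "v_ext",
    "noise_variance",
    "decompose",
    "conditional_law",
    "truncation_window",
]

_DEFAULT_ORDER = 8


@dataclass(frozen=True)
class QuadratureScheme:
    """Composite Gauss-Legendre scheme: ``order`` nodes on each of
    ``subdiv`` equal sub-pieces of every smooth piece; ``tol`` is the
    history-truncation tolerance for infinite lower limits."""

    order: int = _DEFAULT_ORDER
    subdiv: int = 1
    tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.order < 2 or self.subdiv < 1 or not self.tol > 0:
            raise ValueError("order >= 2, subdiv >= 1, tol > 0 required")


@lru_cache(maxsize=None)
def _gl(order: int):
    x, w = np.polynomial.legendre.leggauss(order)
    return x, w


@lru_cache(maxsize=None)
def _cumint_matrix(order: int) -> np.ndarray:
    """Spectral cumulative-integration matrix on the Gauss-Legendre nodes.

    ``M[i, j] = int_{-1}^{x_i} L_j`` with ``L_j`` the Lagrange basis on the
    nodes, so that ``A(x_i) - A(-1) ~= sum_j M[i, j] f(x_j)`` for smooth
    ``f = A'``.
    """
    x, _ = _gl(order)
    M = np.empty((order, order))
    for j in range(order):
        roots = np.delete(x, j)
        p = np.polynomial.Polynomial.fromroots(roots)
        p = p / p(x[j])
        P = p.integ()
        M[:, j] = P(x) - P(-1.0)
    return M


def _piece_edges(a: float, b: float, sub_offsets: np.ndarray) -> np.ndarray:
    """Breakpoints of [a, b]: endpoints, interior integers and sub-unit offsets."""
    pts = [a, b]
    n0, n1 = math.floor(a), math.ceil(b)
    for n in range(n0, n1 + 1):
        if a < n < b:
            pts.append(float(n))
        for off in sub_offsets:
            t = n + float(off)
            if a < t < b:
                pts.append(t)
    return np.unique(np.asarray(pts, dtype=float))


class _Path:
    """Per-(neuron, window) quadrature table over ``[t_lo, t_hi]``.

    Holds global nodes/weights, the conductance and per-synapse kernel values
    at the nodes, and the cumulative conductance integral ``A(u) = int g``
    from ``t_lo`` -- everything needed to evaluate leak-weighted integrals in
    a single pass.
    """

    def __init__(
        self,
        params: ModelParameters,
        raster: Raster,
        k: int,
        t_lo: float,
        t_hi: float,
        scheme: QuadratureScheme,
        need_alphas: bool = True,
    ):
        self.params = params
        self.k = k
        self.t_lo = t_lo
        self.t_hi = t_hi
        edges = _piece_edges(t_lo, t_hi, params.i_ext.breakpoints())
        if scheme.subdiv > 1:
            fine = []
            for a, b in zip(edges[:-1], edges[1:]):
                fine.extend(np.linspace(a, b, scheme.subdiv + 1)[:-1])
            fine.append(edges[-1])
            edges = np.asarray(fine)
        xg, wg = _gl(scheme.order)
        M = _cumint_matrix(scheme.order)
        a = edges[:-1]
        h = np.diff(edges)
        # nodes[p, i]: node i of piece p (global time)
        nodes = a[:, None] + (xg[None, :] + 1.0) * (h[:, None] / 2.0)
        weights = wg[None, :] * (h[:, None] / 2.0)
        flat = nodes.ravel()
        self.alphas = np.zeros((params.N, flat.size))
        g = np.full(flat.size, params.g_L[k])
        for j in range(params.N):
            need = need_alphas or params.G[k, j] != 0.0
            if need:
                aj = kernels.alpha_sum(params, raster, k, j, flat, tol=scheme.tol)
                self.alphas[j] = aj
                if params.G[k, j] != 0.0:
                    g = g + params.G[k, j] * aj
        self.nodes = flat
        self.weights = weights.ravel()
        gp = g.reshape(nodes.shape)
        dA_piece = (weights * gp).sum(axis=1)
        A_start = np.concatenate([[0.0], np.cumsum(dA_piece)])
        self.A_total = float(A_start[-1])
        # cumulative integral at the interior nodes via the spectral matrix
        A_nodes = A_start[:-1, None] + (gp @ M.T) * (h[:, None] / 2.0)
        self.A_nodes = A_nodes.ravel()
        self.g = g
        C = params.C[k]
        self.gamma_nodes = np.exp(-(self.A_total - self.A_nodes) / C)

    def integral(self, f_nodes: np.ndarray) -> float:
        """``int_{t_lo}^{t_hi} Gamma(u, t_hi) f(u) du``."""
        return float(np.sum(self.weights * self.gamma_nodes * f_nodes))

    def integral_gamma2(self) -> float:
        return float(np.sum(self.weights * self.gamma_nodes**2))

    @property
    def gamma_total(self) -> float:
        """``Gamma_k(t_lo, t_hi, omega)``."""
        return math.exp(-self.A_total / self.params.C[self.k])


def truncation_window(params: ModelParameters, k: int, tol: float) -> float:
    """Length of history kept when the lower limit is the infinite past.

    Beyond this window the leak envelope ``e^{-u/tau_L,k}`` alone pushes every
    integrand below ``tol`` relative to its uniform bound.
    """
    tau_L = float(params.tau_L[k])
    return float(math.ceil(tau_L * math.log(1.0 / tol) + 1.0))


def effective_leak(
    params: ModelParameters,
    raster: Raster,
    k: int,
    t1: float,
    t2: float,
    scheme: QuadratureScheme | None = None,
) -> float:
    """Effective leak factor ``Gamma_k(t1, t2, omega)`` in ``(0, 1]``.

    Equals 1 at coincident endpoints and decays between the constant-
    conductance extremes ``e^{-(t2-t1)/tau_M,k}`` and ``e^{-(t2-t1)/tau_L,k}``.
    """
    if t1 > t2:
        raise ValueError("effective_leak requires t1 <= t2")
    if t1 == t2:
        return 1.0
    scheme = scheme or QuadratureScheme()
    path = _Path(params, raster, k, t1, t2, scheme, need_alphas=False)
    return path.gamma_total


def _window_start(
    params: ModelParameters, k: int, s: float, t: float, scheme: QuadratureScheme
) -> tuple[float, bool]:
    """Finite lower limit for an integral from ``s`` (possibly the infinite past)."""
    if s == NEVER or s < t - truncation_window(params, k, scheme.tol):
        return t - truncation_window(params, k, scheme.tol), True
    return float(s), False


def v_syn(
    params: ModelParameters,
    raster: Raster,
    k: int,
    s: float,
    t: float,
    scheme: QuadratureScheme | None = None,
) -> float:
    """Synaptic potential: leak-weighted integral of the synaptic current."""
    scheme = scheme or QuadratureScheme()
    lo, _ = _window_start(params, k, s, t, scheme)
    if lo >= t:
        return 0.0
    path = _Path(params, raster, k, lo, t, scheme)
    W = params.W[k]
    total = 0.0
    for j in range(params.N):
        if W[j] != 0.0:
            total += W[j] * path.integral(path.alphas[j])
    return total / params.C[k]


def v_ext(
    params: ModelParameters,
    raster: Raster,
    k: int,
    s: float,
    t: float,
    scheme: QuadratureScheme | None = None,
) -> float:
    """Leak-reversal plus external-stimulus potential."""
    scheme = scheme or QuadratureScheme()
    lo, _ = _window_start(params, k, s, t, scheme)
    if lo >= t:
        return 0.0
    path = _Path(params, raster, k, lo, t, scheme, need_alphas=False)
    i_vals = params.i_ext.value(k, path.nodes)
    tau_L = params.tau_L[k]
    return params.E_L / tau_L * path.integral(np.ones_like(path.nodes)) + path.integral(
        np.asarray(i_vals)
    ) / params.C[k]


def noise_variance(
    params: ModelParameters,
    raster: Raster,
    k: int,
    t: float,
    scheme: QuadratureScheme | None = None,
) -> float:
    """Conditional variance of ``V_k(t)`` given the raster (reset + membrane noise)."""
    return decompose(params, raster, k, t, scheme).sigma2


@dataclass(frozen=True)
class PotentialDecomposition:
    """All conditional-law ingredients of one neuron at one query time."""

    k: int
    t: float
    tau_k: float  # last reset time (NEVER if none)
    Gamma: float  # Gamma_k(tau_k, t, omega); 0 in the never-reset limit
    V_syn: float
    V_ext: float
    sigma2: float
    truncation_error_bound: float

    @property
    def V_det(self) -> float:
        return self.V_syn + self.V_ext


def decompose(
    params: ModelParameters,
    raster: Raster,
    k: int,
    t: float,
    scheme: QuadratureScheme | None = None,
) -> PotentialDecomposition:
    """Evaluate ``Gamma``, ``V_syn``, ``V_ext`` and ``sigma^2`` in one pass.

    The window runs from the last reset time of neuron ``k`` (a spike at
    integer ``n`` resets at ``n``) to ``t``; a never-reset past is truncated
    at the leak-envelope horizon, with the reset-variance term dropped (its
    leak factor is below the truncation tolerance).
    """
    scheme = scheme or QuadratureScheme()
    tau_k = last_reset(raster, k, t)
    lo, truncated = _window_start(params, k, tau_k, t, scheme)
    C = params.C[k]
    if lo >= t:
        # just reset: zero-length window
        return PotentialDecomposition(
            k=k, t=t, tau_k=tau_k, Gamma=1.0, V_syn=0.0, V_ext=0.0,
            sigma2=params.sigma_R**2, truncation_error_bound=0.0,
        )
    path = _Path(params, raster, k, lo, t, scheme)
    W = params.W[k]
    vs = 0.0
    for j in range(params.N):
        if W[j] != 0.0:
            vs += W[j] * path.integral(path.alphas[j])
    vs /= C
    i_vals = np.asarray(params.i_ext.value(k, path.nodes))
    ones = np.ones_like(path.nodes)
    ve = params.E_L / params.tau_L[k] * path.integral(ones) + path.integral(i_vals) / C
    gamma = path.gamma_total
    sig2 = (params.sigma_B / C) ** 2 * path.integral_gamma2()
    err = 0.0
    if truncated:
        # leak-envelope bound on everything older than the window
        db_like = abs(params.E_L) + params.i_ext.i_plus / params.g_L[k]
        tail = math.exp(-(t - lo) / params.tau_L[k]) * params.tau_L[k]
        w_abs = np.abs(W).sum()
        alpha_bound = max(
            kernels.sup_sum(params.profile(k, j)) for j in range(params.N)
        )
        err = tail * (alpha_bound * w_abs / C + db_like / params.tau_L[k] + (params.sigma_B / C) ** 2)
        gamma_term = 0.0  # Gamma(tau_k, t)^2 sigma_R^2 <= tol^2 sigma_R^2
        gamma = 0.0
    else:
        gamma_term = gamma**2 * params.sigma_R**2
    sig2 += gamma_term
    return PotentialDecomposition(
        k=k, t=t, tau_k=tau_k, Gamma=gamma, V_syn=vs, V_ext=ve,
        sigma2=sig2, truncation_error_bound=err,
    )


def conditional_law(
    params: ModelParameters,
    raster: Raster,
    t: float,
    scheme: QuadratureScheme | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional Gaussian law of ``V(t)`` given the raster.

    Returns per-neuron means ``V_det(tau_k, t, omega)`` and variances
    ``sigma_k^2``; the covariance is diagonal (neurons are conditionally
    independent given the spike history).
    """
    means = np.empty(params.N)
    variances = np.empty(params.N)
    for k in range(params.N):
        d = decompose(params, raster, k, t, scheme)
        means[k] = d.V_det
        variances[k] = d.sigma2
    return means, variances
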