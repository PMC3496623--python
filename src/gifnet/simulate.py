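"""Raster generation: exact sequential sampling and an SDE oracle.

Two independent routes produce spike trains from the same model:

* :func:`sample_exact` draws each spiking pattern from the closed-form
  one-step conditional law (threshold distance ``X_k`` -> Gaussian tail
  probability -> independent per-neuron Bernoulli draws).  For exponential
  and alpha-function kernels (degree 0 or 1) the spike-history sums obey
  exact one-step recursions, so the sampler carries per-synapse filter
  states instead of re-summing history, and evolves many independent
  replicas at once.

* :func:`simulate_sde` integrates the underlying stochastic membrane
  equation ``C dV = (-g(t, omega) V + i(t, omega)) dt + sigma_B dB`` by
  Euler-Maruyama (the noise is additive, so the scheme is strong order 1)
  with threshold detection and random reset.  It knows nothing about the
  closed-form law, which makes it the independent oracle for the discrete
  pipeline: conditional moments, one-step firing frequencies and
  conditional independence can all be cross-checked against it.

Randomness uses counter-style substreams spawned from a single seed so the
exact and SDE routes are independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import kernels
from .params import ModelParameters
from .potential import QuadratureScheme, _cumint_matrix, _gl, truncation_window
from .raster import NEVER, Raster, last_reset
from .statistics import firing_arguments, pi

__all__ = [
    "SimulationConfig",
    "sample_exact",
    "sample_exact_batch",
    "simulate_sde",
    "sde_conditional_samples",
    "empirical_transition",
]


@dataclass
class SimulationConfig:
    """Run-length, seeding and discretization choices for a simulation."""

    T: int
    seed: int = 0
    burn_in: int = 0
    method: str = "exact"
    sde_dt: float = 1e-3
    n_paths: int = 1

    def __post_init__(self) -> None:
        if self.T < 1 or self.n_paths < 1:
            raise ValueError("T and n_paths must be >= 1")
        if not 0 < self.sde_dt <= 0.1:
            raise ValueError("sde_dt must lie in (0, 0.1]")
        if self.method not in ("exact", "sde"):
            raise ValueError("method must be 'exact' or 'sde'")


# ---------------------------------------------------------------------------
# unit-interval quadrature layout (shared by the batched exact engine)


class _UnitQuad:
    """Gauss-Legendre nodes/weights on one unit interval, split at the
    external-current breakpoints, with the matrix giving the cumulative
    integral at every node from samples at all nodes."""

    def __init__(self, params: ModelParameters, order: int):
        edges = np.concatenate([[0.0], params.i_ext.breakpoints(), [1.0]])
        xg, wg = _gl(order)
        M1 = _cumint_matrix(order)
        xs, ws = [], []
        n_total = order * (len(edges) - 1)
        Mu = np.zeros((n_total, n_total))
        pos = 0
        for a, b in zip(edges[:-1], edges[1:]):
            h = b - a
            xs.append(a + (xg + 1.0) * h / 2.0)
            ws.append(wg * h / 2.0)
            sl = slice(pos, pos + order)
            Mu[sl, :pos] = np.concatenate(ws[:-1]) if pos else 0.0
            Mu[sl, sl] = M1 * h / 2.0
            pos += order
        self.x = np.concatenate(xs)  # node offsets in (0, 1)
        self.w = np.concatenate(ws)
        self.M = Mu


class _ExactEngine:
    """Replica-batched exact sampler for kernel degrees 0 and 1.

    Carries, per replica and synapse, the filter states
    ``E = sum_s omega_j(s) q^{m-s}`` and (degree 1)
    ``D = sum_s omega_j(s) ((m-s)/tau) q^{m-s}`` with ``q = e^{-1/tau}``;
    the kernel sum at any intra-interval time ``m + x`` is then
    ``e^{-x/tau} E`` (degree 0) or ``e^{-x/tau} ((x/tau) E + D)`` (degree 1),
    exact over the *entire* history.  Only the leak-weighted integrals are
    truncated, at the per-neuron leak-envelope horizon.
    """

    def __init__(
        self,
        params: ModelParameters,
        n_replicas: int,
        initial_past: Raster | None = None,
        order: int = 8,
        tol: float = 1e-10,
        rng: np.random.Generator | None = None,
    ):
        if params.profile_degree not in (0, 1):
            raise NotImplementedError(
                "the batched exact engine supports kernel degrees 0 and 1"
            )
        self.params = params
        self.R = n_replicas
        self.rng = rng or np.random.default_rng(0)
        self.tol = tol
        N = params.N
        self.H = max(int(truncation_window(params, k, tol)) for k in range(N))
        self.quad = _UnitQuad(params, order)
        x = self.quad.x
        self.q = np.exp(-1.0 / params.tau_syn)  # (N, N)
        self.ex = np.exp(-x[None, None, :] / params.tau_syn[:, :, None])  # (N,N,n)
        self.xt = x[None, None, :] / params.tau_syn[:, :, None]
        self.i_vals = np.stack(
            [np.asarray(params.i_ext.value(k, x)) for k in range(N)]
        ).reshape(N, -1)

        # ring buffers of filter states at the last H+1 integer times
        self.E_hist = np.zeros((self.H + 1, self.R, N, N))
        self.D_hist = np.zeros((self.H + 1, self.R, N, N))
        self.last_spike = np.full((self.R, N), NEVER)

        padding = initial_past.padding if initial_past is not None else "zeros"
        if padding == "ones":
            E_inf = 1.0 / (1.0 - self.q)
            D_inf = self.q / (params.tau_syn * (1.0 - self.q) ** 2)
            self.E_hist[:] = E_inf[None, None, :, :]
            self.D_hist[:] = D_inf[None, None, :, :]
        self.E = self.E_hist[-1].copy()
        self.D = self.D_hist[-1].copy()

        if initial_past is not None:
            if padding == "ones":
                self.last_spike[:] = initial_past.t0 - 1
            self.t_cur = initial_past.t0 - 1
            for i in range(initial_past.T):
                col = np.broadcast_to(
                    initial_past.omega[:, i].astype(float), (self.R, N)
                )
                self._push(col)
        else:
            self.t_cur = -1

    def _push(self, col: np.ndarray) -> None:
        """Advance one integer step with spiking pattern ``col`` (R x N)."""
        q, tau = self.q, self.params.tau_syn
        self.D = q[None] * (self.D + self.E / tau[None])
        self.E = q[None] * self.E + col[:, None, :]
        self.E_hist = np.roll(self.E_hist, -1, axis=0)
        self.D_hist = np.roll(self.D_hist, -1, axis=0)
        self.E_hist[-1] = self.E
        self.D_hist[-1] = self.D
        self.t_cur += 1
        fired = col > 0.5
        self.last_spike[fired] = self.t_cur

    def firing_arguments(self) -> np.ndarray:
        """Threshold distances ``X_k(t_cur, .)`` for every replica (R x N)."""
        p = self.params
        N, R, H = p.N, self.R, self.H
        t = self.t_cur
        d = p.profile_degree
        # states at integer times t-H .. t-1 (piece starts), oldest first
        E_m = self.E_hist[:H]  # (H, R, N, N)
        D_m = self.D_hist[:H]
        X = np.empty((R, N))
        for k in range(N):
            ex, xt = self.ex[k], self.xt[k]  # (N, n_nodes)
            if d == 0:
                al = E_m[:, :, k, :, None] * ex[None, None, :, :]
            else:
                al = (
                    E_m[:, :, k, :, None] * xt[None, None, :, :]
                    + D_m[:, :, k, :, None]
                ) * ex[None, None, :, :]
            # al: (H, R, N_presyn, n_nodes)
            g = p.g_L[k] + np.einsum("j,hrjn->hrn", p.G[k], al)
            dA = np.einsum("n,hrn->hr", self.quad.w, g)
            A_start = np.concatenate(
                [np.zeros((1, R)), np.cumsum(dA, axis=0)], axis=0
            )  # (H+1, R); last row = A_total
            A_total = A_start[-1]
            A_within = np.einsum("mn,hrn->hrm", self.quad.M, g)
            gamma = np.exp(
                -(A_total[None, :, None] - A_start[:-1, :, None] - A_within)
                / p.C[k]
            )  # (H, R, n_nodes)
            Jsyn = np.einsum("n,hrn,hrjn->hrj", self.quad.w, gamma, al)
            Jg = np.einsum("n,hrn->hr", self.quad.w, gamma)
            Ji = np.einsum("n,hrn->hr", self.quad.w * self.i_vals[k], gamma)
            Jg2 = np.einsum("n,hrn->hr", self.quad.w, gamma**2)

            def suffix(arr):  # sum over pieces h..H-1, with an all-zero row at H
                s = np.concatenate(
                    [np.cumsum(arr[::-1], axis=0)[::-1], np.zeros((1,) + arr.shape[1:])]
                )
                return s

            Ssyn, Sg, Si, Sg2 = suffix(Jsyn), suffix(Jg), suffix(Ji), suffix(Jg2)
            tau_r = self.last_spike[:, k]
            in_window = tau_r >= t - H
            h_idx = np.where(in_window, np.clip(tau_r - (t - H), 0, H), 0).astype(int)
            r_idx = np.arange(R)
            vs = Ssyn[h_idx, r_idx, :] @ p.W[k] / p.C[k]
            ve = p.E_L / p.tau_L[k] * Sg[h_idx, r_idx] + Si[h_idx, r_idx] / p.C[k]
            gamma_rt = np.exp(-(A_total - A_start[h_idx, r_idx]) / p.C[k])
            sig2 = (p.sigma_B / p.C[k]) ** 2 * Sg2[h_idx, r_idx]
            sig2 = sig2 + np.where(in_window, gamma_rt**2 * p.sigma_R**2, 0.0)
            X[:, k] = (p.theta - vs - ve) / np.sqrt(sig2)
        return X

    def step(self) -> np.ndarray:
        """Sample the next spiking pattern for every replica; returns R x N."""
        X = self.firing_arguments()
        col = (self.rng.random((self.R, self.params.N)) < pi(X)).astype(float)
        self._push(col)
        return col.astype(np.int8)


def sample_exact_batch(
    params: ModelParameters,
    n_replicas: int,
    T: int,
    seed: int = 0,
    initial_past: Raster | None = None,
    burn_in: int = 0,
    tol: float = 1e-10,
) -> np.ndarray:
    """Draw ``n_replicas`` independent rasters of ``T`` steps at once.

    Returns an ``(n_replicas, N, T)`` binary array.  All replicas share the
    (optional) initial past and are advanced synchronously; each carries its
    own filter states, reset times and random stream.
    """
    rng = np.random.default_rng(seed)
    eng = _ExactEngine(params, n_replicas, initial_past, tol=tol, rng=rng)
    for _ in range(burn_in):
        eng.step()
    out = np.empty((n_replicas, params.N, T), dtype=np.int8)
    for i in range(T):
        out[:, :, i] = eng.step()
    return out


def sample_exact(
    params: ModelParameters,
    config: SimulationConfig,
    initial_past: Raster | None = None,
) -> Raster:
    """Sequentially sample a raster from the exact one-step conditional law.

    Bit-reproducible under ``config.seed``.  Kernel degrees above 1 fall back
    to a per-step quadrature evaluation of the threshold distances.
    """
    t0 = 0 if initial_past is None else initial_past.t_end + 1
    if params.profile_degree in (0, 1):
        block = sample_exact_batch(
            params, 1, config.T, seed=config.seed,
            initial_past=initial_past, burn_in=config.burn_in,
        )[0]
        return Raster(block, t0=t0 + config.burn_in, padding="zeros")
    # generic (slow) path: grow the raster one column at a time
    rng = np.random.default_rng(config.seed)
    hist = initial_past or Raster(np.zeros((params.N, 0), dtype=np.int8), t0=0)
    for _ in range(config.burn_in + config.T):
        X = firing_arguments(params, hist, hist.t_end + 1)
        col = (rng.random(params.N) < pi(X)).astype(np.int8)
        hist = hist.extended(col)
    keep = hist.omega[:, hist.T - config.T :]
    return Raster(keep, t0=hist.t_end - config.T + 1, padding="zeros")


# ---------------------------------------------------------------------------
# SDE oracle


def _clamped_grid(
    params: ModelParameters, raster: Raster, k: int, lo: float, t: float, dt: float
):
    """Conductance and deterministic current of neuron ``k`` on a dt-grid,
    for a fixed (clamped) raster."""
    n = int(round((t - lo) / dt))
    u = lo + dt * np.arange(n)
    g = np.full(n, params.g_L[k])
    syn = np.zeros(n)
    for j in range(params.N):
        aj = kernels.alpha_sum(params, raster, k, j, u)
        if params.G[k, j] != 0.0:
            g = g + params.G[k, j] * aj
        if params.W[k, j] != 0.0:
            syn = syn + params.W[k, j] * aj
    i_det = params.g_L[k] * params.E_L + syn + np.asarray(params.i_ext.value(k, u))
    return u, g, i_det


def sde_conditional_samples(
    params: ModelParameters,
    raster: Raster,
    k: int,
    t: float,
    n_paths: int,
    dt: float = 1e-3,
    seed: int = 0,
    tol: float = 1e-10,
) -> np.ndarray:
    """Monte-Carlo samples of ``V_k(t)`` given a clamped spike history.

    Integrates the membrane SDE by Euler-Maruyama from the last reset of
    neuron ``k`` (initial value drawn from the reset law) -- or from the
    leak-envelope horizon with an irrelevant initial value if the neuron
    never reset -- to ``t``.  Returns ``n_paths`` samples; their mean and
    variance estimate the conditional Gaussian law.
    """
    rng = np.random.default_rng(seed)
    tau_k = last_reset(raster, k, t)
    if tau_k == NEVER or tau_k < t - truncation_window(params, k, tol):
        lo = t - truncation_window(params, k, tol)
        V = np.zeros(n_paths)
    else:
        lo = tau_k
        V = params.sigma_R * rng.standard_normal(n_paths)
    if lo >= t:
        return V
    _, g, i_det = _clamped_grid(params, raster, k, lo, t, dt)
    C = params.C[k]
    amp = params.sigma_B / C * math.sqrt(dt)
    for i in range(g.size):
        V = V + dt / C * (-g[i] * V + i_det[i]) + amp * rng.standard_normal(n_paths)
    return V


def simulate_sde(
    params: ModelParameters,
    config: SimulationConfig,
    initial_past: Raster | None = None,
    spike_rule: str = "endpoint",
) -> tuple[Raster, np.ndarray]:
    """Free-running SDE integration with threshold, spike and reset.

    The conductances are driven by the raster the simulation itself produces,
    updated on integer spike times only.  Two spike-registration rules are
    supported: ``"endpoint"`` registers a spike at ``n`` when ``V(n-1)`` is at
    or above threshold (matching the discrete pipeline's conditional law),
    ``"crossing"`` when the membrane reaches threshold anywhere in
    ``(n-1, n]`` (first crossing; the membrane is then frozen until the reset
    at ``n``, the spike shape playing no role).  Either way at most one spike
    per neuron per unit interval is registered and the reset draws a fresh
    Gaussian value.

    Requires kernel degree 0 or 1 (closed-form filter states).  Returns the
    sampled raster and the membrane potentials at integer times
    (``N x (T+1)``, first column the initial state).
    """
    if params.profile_degree not in (0, 1):
        raise NotImplementedError("simulate_sde supports kernel degrees 0 and 1")
    if spike_rule not in ("endpoint", "crossing"):
        raise ValueError("spike_rule must be 'endpoint' or 'crossing'")
    p = params
    N = p.N
    rng = np.random.default_rng(config.seed)
    n_sub = int(round(1.0 / config.sde_dt))
    if abs(n_sub * config.sde_dt - 1.0) > 1e-12:
        raise ValueError("sde_dt must divide the unit time step exactly")
    dt = 1.0 / n_sub
    x_sub = dt * np.arange(n_sub)  # offsets of sub-step starts
    q = np.exp(-1.0 / p.tau_syn)
    ex = np.exp(-x_sub[None, None, :] / p.tau_syn[:, :, None])  # (N,N,n_sub)
    xt = x_sub[None, None, :] / p.tau_syn[:, :, None]
    i_sub = np.stack([np.asarray(p.i_ext.value(k, x_sub)) for k in range(N)]).reshape(N, -1)

    E = np.zeros((N, N))
    D = np.zeros((N, N))
    t0 = 0
    if initial_past is not None:
        if initial_past.padding == "ones":
            E = 1.0 / (1.0 - q)
            D = q / (p.tau_syn * (1.0 - q) ** 2)
        for i in range(initial_past.T):
            col = initial_past.omega[:, i].astype(float)
            D = q * (D + E / p.tau_syn)
            E = q * E + col[None, :]
        t0 = initial_past.t_end + 1

    V = np.zeros(N)
    omega = np.zeros((N, config.T), dtype=np.int8)
    v_trace = np.zeros((N, config.T + 1))
    v_trace[:, 0] = V
    amp = p.sigma_B / p.C * math.sqrt(dt)
    for step in range(config.T):
        if params.profile_degree == 0:
            al = E[:, :, None] * ex  # (N_post, N_pre, n_sub)
        else:
            al = (E[:, :, None] * xt + D[:, :, None]) * ex
        g = p.g_L[:, None] + np.einsum("kj,kjn->kn", p.G, al)
        i_det = (
            p.g_L[:, None] * p.E_L
            + np.einsum("kj,kjn->kn", p.W, al)
            + i_sub
        )
        if spike_rule == "endpoint":
            will_spike = V >= p.theta
            for i in range(n_sub):
                noise = amp * rng.standard_normal(N)
                dV = dt / p.C * (-g[:, i] * V + i_det[:, i]) + noise
                V = np.where(will_spike, V, V + dV)
        else:
            will_spike = np.zeros(N, dtype=bool)
            for i in range(n_sub):
                will_spike |= V >= p.theta
                noise = amp * rng.standard_normal(N)
                dV = dt / p.C * (-g[:, i] * V + i_det[:, i]) + noise
                V = np.where(will_spike, V, V + dV)
            will_spike |= V >= p.theta
        col = will_spike.astype(float)
        V = np.where(will_spike, p.sigma_R * rng.standard_normal(N), V)
        omega[:, step] = col
        v_trace[:, step + 1] = V
        D = q * (D + E / p.tau_syn)
        E = q * E + col[None, :]
    return Raster(omega, t0=t0, padding="zeros"), v_trace


def empirical_transition(
    params: ModelParameters,
    raster: Raster,
    n: int,
    n_draws: int,
    seed: int = 0,
    scheme: QuadratureScheme | None = None,
) -> dict:
    """Empirical one-step pattern frequencies against the closed-form law.

    Draws ``n_draws`` spiking patterns at time ``n`` from the exact
    conditional law given the raster history, and tabulates the frequency of
    each of the ``2^N`` patterns together with its binomial standard error
    and the exact probability.  Intended for small ``N`` (<= 6).
    """
    if params.N > 6:
        raise ValueError("empirical_transition is an exhaustive check; N <= 6")
    rng = np.random.default_rng(seed)
    X = firing_arguments(params, raster, n, scheme)
    p_fire = pi(X)
    draws = rng.random((n_draws, params.N)) < p_fire[None, :]
    codes = draws @ (1 << np.arange(params.N))
    counts = np.bincount(codes, minlength=1 << params.N)
    freq = counts / n_draws
    bits = (np.arange(1 << params.N)[:, None] >> np.arange(params.N)[None, :]) & 1
    p_exact = np.prod(np.where(bits == 1, p_fire[None, :], 1.0 - p_fire[None, :]), axis=1)
    se = np.sqrt(np.clip(p_exact * (1 - p_exact), 0.0, None) / n_draws)
    return {
        "frequency": freq,
        "probability": p_exact,
        "standard_error": se,
        "n_draws": n_draws,
        "patterns": bits,
    }
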