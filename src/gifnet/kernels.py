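"""Synaptic response kernels ("alpha" profiles) and their spike-history sums.

A presynaptic spike at integer time ``s`` contributes a conductance transient
``alpha(t - s)`` to each of its postsynaptic targets.  The profiles implemented
here are the causal family

    alpha(t) = (t / tau)**d * exp(-t / tau) * H(t),

with ``H`` the Heaviside step, ``d = 0`` the plain exponential and ``d = 1``
the smoothly delayed ("alpha function") response.  All profiles are
dimensionless and decay exponentially with characteristic time ``tau``, which
is what makes the network's memory of its past fade geometrically.

The module also provides the closed-form tail bound on the summed contribution
of spikes older than a horizon ``m`` -- the quantity that controls every
history-truncation error downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import TYPE_CHECKING

import numpy as np
from scipy.special import gammaincc

if TYPE_CHECKING:  # pragma: no cover
    from .params import ModelParameters
    from .raster import Raster

__all__ = [
    "AlphaProfile",
    "alpha",
    "alpha_sum",
    "conductance",
    "tail_bound",
    "truncation_horizon",
    "sup_sum",
]


@dataclass(frozen=True)
class AlphaProfile:
    """Causal synaptic conductance kernel ``(t/tau)^d e^{-t/tau} H(t)``.

    Parameters
    ----------
    degree
        Polynomial degree ``d >= 0``.  ``d = 0`` is the exponential profile
        (value 1 at ``t -> 0+``), ``d = 1`` peaks at ``t = tau`` with value
        ``1/e``.
    tau
        Decay time of the evoked postsynaptic conductance, in units of the
        spike duration (> 0).
    """

    degree: int
    tau: float

    def __post_init__(self) -> None:
        if self.degree < 0:
            raise ValueError("profile degree must be >= 0")
        if not self.tau > 0:
            raise ValueError("profile tau must be > 0")


def alpha(profile: AlphaProfile, t):
    """Evaluate the profile at time(s) ``t`` (vectorized, 0 for ``t < 0``).

    For ``d = 0`` the value at ``t = 0`` is taken as the right limit 1;
    spikes only ever contribute at strictly positive lag, so only the
    ``t -> 0+`` side of the Heaviside step is exercised.
    """
    t = np.asarray(t, dtype=float)
    x = t / profile.tau
    with np.errstate(invalid="ignore"):
        val = np.where(t >= 0.0, x ** profile.degree * np.exp(-np.clip(x, 0.0, None)), 0.0)
    if val.ndim == 0:
        return float(val)
    return val


def tail_bound(profile: AlphaProfile, m: float) -> float:
    """Upper bound on the summed kernel mass of spikes older than lag ``m``.

    The sum ``sum_{r < t-m} alpha(t - r)`` over integer spike times is bounded
    by the tail integral ``int_m^inf (u/tau)^d e^{-u/tau} du`` once the kernel
    is decreasing there (``m >= d*tau``); the integral evaluates in closed
    form to ``tau * Gamma(d+1, m/tau)`` (upper incomplete gamma), i.e. a
    degree-``d`` polynomial times ``e^{-m/tau}``.
    """
    if m < 0:
        m = 0.0
    d, tau = profile.degree, profile.tau
    return tau * math.factorial(d) * float(gammaincc(d + 1, m / tau))


@lru_cache(maxsize=4096)
def truncation_horizon(profile: AlphaProfile, tol: float = 1e-10) -> int:
    """Smallest integer lag beyond which the tail bound drops below ``tol``."""
    m = max(1, int(profile.degree * profile.tau))
    while tail_bound(profile, m) > tol:
        m *= 2
        if m > 10**7:  # pragma: no cover - pathological tau
            raise RuntimeError("truncation horizon did not converge")
    lo = m // 2
    while lo < m:
        mid = (lo + m) // 2
        if tail_bound(profile, mid) <= tol:
            m = mid
        else:
            lo = mid + 1
    return m


@lru_cache(maxsize=4096)
def sup_sum(profile: AlphaProfile, tol: float = 1e-12) -> float:
    """Upper bound on ``sum_{r < t} alpha(t - r)``, uniform in real ``t``.

    Writing ``t = [t] + {t}`` the sum equals ``sum_{n>=0} alpha(n + {t})``
    (the ``n = 0`` term is the spike at the integer just before ``t``, at
    sub-unit lag) and is bounded by the sum of per-interval suprema
    ``A(n) = sup alpha([n, n+1))``.  The kernel is unimodal with mode
    ``d*tau``, so each supremum is attained at an interval end or at the
    mode; the series is closed with the tail bound.  For the exponential
    kernel this evaluates to ``1 / (1 - e^{-1/tau})``.
    """
    mode = profile.degree * profile.tau
    m_stop = max(truncation_horizon(profile, tol), int(mode) + 2)
    n = np.arange(0, m_stop + 1, dtype=float)
    sup = np.maximum(alpha(profile, n), alpha(profile, n + 1))
    in_mode = (n <= mode) & (mode < n + 1)
    if in_mode.any():
        sup = np.where(in_mode, alpha(profile, mode), sup)
    return float(np.sum(sup)) + tail_bound(profile, m_stop)


def _spike_times_before(
    raster: "Raster", j: int, t: float, horizon: int
) -> np.ndarray:
    """Integer spike times of neuron ``j`` in ``[t - horizon, t)``.

    Padding columns left of the raster window are included according to the
    raster's padding convention (all-ones padding spikes at every integer).
    """
    lo = int(math.ceil(t - horizon))
    hi_excl = int(math.ceil(t))  # integers n with n < t
    if hi_excl <= lo:
        return np.empty(0, dtype=np.int64)
    times = []
    if raster.padding == "ones" and lo < raster.t0:
        times.append(np.arange(lo, min(raster.t0, hi_excl), dtype=np.int64))
    w_lo = max(lo, raster.t0)
    w_hi = min(hi_excl, raster.t0 + raster.T)
    if w_hi > w_lo:
        cols = raster.omega[j, w_lo - raster.t0 : w_hi - raster.t0]
        times.append(np.nonzero(cols)[0].astype(np.int64) + w_lo)
    if not times:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(times)


def alpha_sum(
    params: "ModelParameters",
    raster: "Raster",
    k: int,
    j: int,
    t,
    tol: float = 1e-10,
):
    """Spike-history kernel sum ``alpha_kj(t, omega)`` for the synapse j -> k.

    Sums ``alpha_kj(t - s)`` over all spike times ``s < t`` of presynaptic
    neuron ``j`` (window plus padding).  History older than an automatically
    chosen horizon is dropped; the neglected mass is below the closed-form
    tail bound at that horizon, itself below ``tol``.

    ``t`` may be a scalar or an array of query times.
    """
    profile = params.profile(k, j)
    # +1: spikes dropped beyond the window have lags strictly above the
    # horizon, and the tail integral from (horizon) dominates a unit-spaced
    # sum only when every lag exceeds horizon + 1
    horizon = truncation_horizon(profile, tol) + 1
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    t_max = float(t_arr.max())
    t_min = float(t_arr.min())
    spikes = _spike_times_before(raster, j, t_max, horizon + int(math.ceil(t_max - t_min)))
    if spikes.size == 0:
        out = np.zeros_like(t_arr)
    else:
        lags = t_arr[:, None] - spikes[None, :]
        vals = alpha(profile, lags)
        vals = np.where(lags > 0, vals, 0.0)
        out = vals.sum(axis=1)
    if np.isscalar(t) or np.asarray(t).ndim == 0:
        return float(out[0])
    return out


def conductance(
    params: "ModelParameters",
    raster: "Raster",
    k: int,
    t,
    tol: float = 1e-10,
):
    """Total membrane conductance ``g_k(t, omega) = g_L,k + sum_j G_kj alpha_kj``."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    g = np.full_like(t_arr, params.g_L[k])
    for j in range(params.N):
        if params.G[k, j] != 0.0:
            g = g + params.G[k, j] * alpha_sum(params, raster, k, j, t_arr, tol=tol)
    if np.isscalar(t) or np.asarray(t).ndim == 0:
        return float(g[0])
    return g
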