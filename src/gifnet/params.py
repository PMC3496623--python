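"""Model parameters of the conductance-based integrate-and-fire network.

The full parameter vector gathers, per neuron: membrane capacitance ``C_k``
and leak conductance ``g_L,k``; the shared firing threshold ``theta``; the
reversal potentials (leak ``E_L``, excitatory ``E_plus``, inhibitory
``E_minus``); the synaptic amplitude matrix ``G`` (``G[k, j]`` is the maximal
conductance of the synapse j -> k, 0 meaning no synapse) with per-synapse
decay times ``tau_syn``; the population label of each *presynaptic* neuron
(``E`` or ``I``), which fixes the sign of the synaptic weight
``W_kj = E_plus * G_kj`` (excitatory j) or ``E_minus * G_kj`` (inhibitory j);
the noise amplitudes ``sigma_B`` (membrane current noise) and ``sigma_R``
(random reset value); and the external current.

Units: time is measured in units of the spike duration (so one raster column
per time unit); voltages in mV with the rest potential at 0 (the reset value
has mean 0); conductances and capacitances in consistent arbitrary units.
These conventions are documented, not enforced.

:func:`derive_bounds` evaluates the closed-form constants that bound every
dynamical quantity uniformly in time and history: the conductance sandwich
``g_L,k <= g_k <= g_M,k``, the fastest/slowest membrane relaxation times
``tau_M,k <= tau_L,k``, the deterministic-potential window ``(V-, V+)``, the
conditional standard-deviation window ``[sigma-, sigma+]``, and the resulting
uniform per-neuron firing-probability bounds ``0 < Pi- < Pi+ < 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from . import kernels
from .kernels import AlphaProfile

__all__ = [
    "ExternalCurrent",
    "ModelParameters",
    "DerivedBounds",
    "validate",
    "derive_bounds",
    "random_parameters",
    "load_params",
    "save_params",
]


@dataclass(frozen=True)
class ExternalCurrent:
    """Piecewise-constant external current, periodic within each unit interval.

    ``offsets`` is a sorted grid ``0 = o_0 < o_1 < ... < o_{P-1} < 1``;
    ``values`` is a ``P x N`` array and the current fed to neuron ``k`` at
    time ``t`` is ``values[p, k]`` with ``p`` the sub-interval containing the
    fractional part of ``t``.  The default single-piece grid is a constant
    current.
    """

    offsets: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "offsets", np.asarray(self.offsets, dtype=float))
        object.__setattr__(self, "values", np.atleast_2d(np.asarray(self.values, dtype=float)))
        if self.offsets.ndim != 1 or self.offsets.size != self.values.shape[0]:
            raise ValueError("offsets and values rows must match")
        if self.offsets[0] != 0.0 or (np.diff(self.offsets) <= 0).any() or self.offsets[-1] >= 1.0:
            raise ValueError("offsets must be sorted in [0, 1) starting at 0")

    @classmethod
    def constant(cls, values, N: int) -> "ExternalCurrent":
        vals = np.broadcast_to(np.asarray(values, dtype=float), (N,)).copy()
        return cls(offsets=np.zeros(1), values=vals.reshape(1, N))

    @property
    def i_plus(self) -> float:
        """Uniform bound ``i+`` on ``|i_ext_k(t)|``."""
        return float(np.abs(self.values).max()) if self.values.size else 0.0

    def value(self, k: int, t):
        frac = np.mod(np.asarray(t, dtype=float), 1.0)
        idx = np.searchsorted(self.offsets, frac, side="right") - 1
        out = self.values[idx, k]
        return float(out) if out.ndim == 0 else out

    def breakpoints(self) -> np.ndarray:
        """Sub-unit offsets at which the current may jump (excluding 0)."""
        return self.offsets[1:]


def _as_vec(x, N: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(x, dtype=float), (N,)).copy()
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass
class ModelParameters:
    """Full parameter vector of an N-neuron network (see module docstring)."""

    N: int
    C: np.ndarray
    theta: float
    E_L: float
    E_plus: float
    E_minus: float
    g_L: np.ndarray
    G: np.ndarray
    pop: np.ndarray  # length-N labels 'E' / 'I' of each presynaptic neuron
    tau_syn: np.ndarray
    profile_degree: int = 0
    sigma_B: float = 1.0
    sigma_R: float = 1.0
    i_ext: ExternalCurrent | None = None
    tau_sep: float = 1.0
    tol: float = 1e-10  # history-truncation tolerance used by derived code

    def __post_init__(self) -> None:
        self.N = int(self.N)
        self.C = _as_vec(self.C, self.N, "C")
        self.g_L = _as_vec(self.g_L, self.N, "g_L")
        self.G = np.broadcast_to(np.asarray(self.G, dtype=float), (self.N, self.N)).copy()
        self.tau_syn = np.broadcast_to(
            np.asarray(self.tau_syn, dtype=float), (self.N, self.N)
        ).copy()
        self.pop = np.asarray(self.pop, dtype="U1")
        if self.pop.shape != (self.N,):
            raise ValueError("pop must be a length-N list of 'E'/'I' labels")
        if self.i_ext is None:
            self.i_ext = ExternalCurrent.constant(0.0, self.N)

    @property
    def W(self) -> np.ndarray:
        """Synaptic weight matrix: ``E_plus*G`` on excitatory columns, ``E_minus*G`` on inhibitory."""
        rev = np.where(self.pop == "E", self.E_plus, self.E_minus)
        return self.G * rev[None, :]

    @property
    def tau_L(self) -> np.ndarray:
        """Per-neuron leak time ``C_k / g_L,k`` (slowest membrane relaxation)."""
        return self.C / self.g_L

    def profile(self, k: int, j: int) -> AlphaProfile:
        return AlphaProfile(self.profile_degree, float(self.tau_syn[k, j]))


def validate(params: ModelParameters) -> list[str]:
    """Check the physical constraints on the parameter vector.

    Returns an empty list when all constraints hold; otherwise a list of
    human-readable violations, each naming the offending field.
    """
    v: list[str] = []
    if params.N < 1:
        v.append("N: neuron count must be >= 1")
    if (params.C <= 0).any():
        v.append("C: capacitances must be strictly positive")
    if (params.g_L <= 0).any():
        v.append("g_L: leak conductances must be strictly positive")
    if (params.G < 0).any():
        v.append("G: synaptic amplitudes must be nonnegative")
    if (params.tau_syn <= 0).any():
        v.append("tau_syn: synaptic decay times must be strictly positive")
    if params.profile_degree < 0:
        v.append("profile_degree: must be a nonnegative integer")
    if not params.sigma_B > 0:
        v.append("sigma_B: membrane noise amplitude must be > 0")
    if not params.sigma_R > 0:
        v.append("sigma_R: reset standard deviation must be > 0")
    if not params.tau_sep >= 1:
        v.append("tau_sep: spike separation time must be >= 1")
    if not np.isin(params.pop, ("E", "I")).all():
        v.append("pop: population labels must be 'E' or 'I'")
    for name in ("theta", "E_L", "E_plus", "E_minus"):
        if not np.isfinite(getattr(params, name)):
            v.append(f"{name}: must be finite")
    if not np.isfinite(params.i_ext.values).all():
        v.append("i_ext: current values must be finite")
    return v


@dataclass(frozen=True)
class DerivedBounds:
    """Closed-form uniform bounds derived from a parameter vector.

    ``alpha_plus`` bounds every spike-history kernel sum; ``g_M`` the total
    conductance from above; ``tau_L``/``tau_M`` are the slowest/fastest
    membrane relaxation times; ``(V_minus, V_plus)`` sandwich the
    deterministic membrane potential, ``(sigma_minus, sigma_plus)`` the
    conditional standard deviation, ``(pi_minus, pi_plus)`` the one-step
    firing probability and ``(Pi_minus, Pi_plus)`` the probability of either
    one-step outcome; the ``Pi_prod_*`` products over neurons bound whole
    spiking-pattern probabilities.
    """

    alpha_plus: float
    g_M: np.ndarray
    tau_L: np.ndarray
    tau_M: np.ndarray
    i_plus: float
    V_minus: np.ndarray
    V_plus: np.ndarray
    sigma_minus: np.ndarray
    sigma_plus: np.ndarray
    X_low: np.ndarray
    X_high: np.ndarray
    pi_minus: np.ndarray
    pi_plus: np.ndarray
    Pi_minus: np.ndarray
    Pi_plus: np.ndarray
    Pi_prod_minus: float
    Pi_prod_plus: float
    # log-space duplicates: the strict inequalities 0 < Pi- < Pi+ < 1 can sit
    # below double-precision resolution in linear scale (probabilities within
    # 1e-17 of 0 or 1) while remaining exactly representable as logs.
    log_Pi_minus: np.ndarray = None
    log_Pi_plus: np.ndarray = None


def derive_bounds(params: ModelParameters) -> DerivedBounds:
    """Evaluate all closed-form bounds for a valid parameter vector."""
    violations = validate(params)
    if violations:
        raise ValueError("invalid parameters: " + "; ".join(violations))
    from scipy.special import log_ndtr

    from .statistics import pi as _pi  # local import to avoid a cycle

    N = params.N
    # alpha_plus: worst-case kernel sum over all synapses (uniform in t).
    sups = [
        kernels.sup_sum(params.profile(k, j))
        for k in range(N)
        for j in range(N)
        if params.G[k, j] != 0.0
    ]
    alpha_plus = max(sups) if sups else kernels.sup_sum(AlphaProfile(params.profile_degree, float(params.tau_syn.max())))

    g_M = params.g_L + alpha_plus * params.G.sum(axis=1)
    tau_L = params.C / params.g_L
    tau_M = params.C / g_M
    i_plus = params.i_ext.i_plus

    W = params.W
    exc = params.pop == "E"
    w_exc = (W * exc[None, :]).sum(axis=1)
    w_inh = (W * (~exc)[None, :]).sum(axis=1)
    ext_bound = np.abs(params.E_L) + i_plus / params.g_L
    V_minus = alpha_plus / params.g_L * w_inh - ext_bound
    V_plus = alpha_plus / params.g_L * w_exc + ext_bound

    sigma_minus = np.minimum(params.sigma_B / params.C * np.sqrt(tau_M / 2.0), params.sigma_R)
    sigma_plus = np.maximum(params.sigma_B / params.C * np.sqrt(tau_L / 2.0), params.sigma_R)

    # X = (theta - V_det)/sigma with theta - V_det in (theta-V_plus, theta-V_minus)
    # and sigma in [sigma_minus, sigma_plus]; extremize over the box (the sign
    # of the numerator decides which sigma extremizes).
    num_lo = params.theta - V_plus
    num_hi = params.theta - V_minus
    X_low = np.minimum(num_lo / sigma_minus, num_lo / sigma_plus)
    X_high = np.maximum(num_hi / sigma_minus, num_hi / sigma_plus)

    pi_minus = _pi(X_high)  # pi is decreasing
    pi_plus = _pi(X_low)
    # Pi- = min(pi-, 1-pi+) and Pi+ = max(pi+, 1-pi-), evaluated without
    # cancellation: 1 - pi(x) = pi(-x), and in log space via log_ndtr.
    Pi_minus = np.minimum(pi_minus, _pi(-X_low))
    Pi_plus = np.maximum(pi_plus, _pi(-X_high))
    log_Pi_minus = np.minimum(log_ndtr(-X_high), log_ndtr(X_low))
    log_Pi_plus = np.maximum(log_ndtr(-X_low), log_ndtr(X_high))

    return DerivedBounds(
        alpha_plus=float(alpha_plus),
        g_M=g_M,
        tau_L=tau_L,
        tau_M=tau_M,
        i_plus=i_plus,
        V_minus=V_minus,
        V_plus=V_plus,
        sigma_minus=sigma_minus,
        sigma_plus=sigma_plus,
        X_low=X_low,
        X_high=X_high,
        pi_minus=pi_minus,
        pi_plus=pi_plus,
        Pi_minus=Pi_minus,
        Pi_plus=Pi_plus,
        Pi_prod_minus=float(np.prod(Pi_minus)),
        Pi_prod_plus=float(np.prod(Pi_plus)),
        log_Pi_minus=log_Pi_minus,
        log_Pi_plus=log_Pi_plus,
    )


def example_parameters(profile_degree: int = 0) -> ModelParameters:
    """Documented two-neuron reference network (one excitatory, one inhibitory).

    Potentials are measured relative to the rest potential (the reset value
    has mean 0): leak reversal at rest, excitatory reversal 65 mV above rest
    (AMPA-like), inhibitory reversal 5 mV below (GABA-A-like), threshold
    12 mV above rest.  The leak time is 2 time units (about 2 ms with
    millisecond spikes), synaptic decay times 2 and 3, and a constant drive
    plus noise put the quiescent one-step firing probability near 0.15 --
    an active but not saturated operating point.  The synaptic amplitudes
    are moderate so that the worst-case threshold distances stay within the
    range where the uniform probability window is strictly inside (0, 1)
    even in linear double precision.
    """
    return ModelParameters(
        N=2,
        C=[1.0, 1.0],
        theta=12.0,
        E_L=0.0,
        E_plus=65.0,
        E_minus=-5.0,
        g_L=[0.5, 0.5],
        G=[[0.0, 0.10], [0.15, 0.0]],
        pop=["E", "I"],
        tau_syn=[[2.0, 3.0], [2.0, 3.0]],
        profile_degree=profile_degree,
        sigma_B=4.0,
        sigma_R=2.0,
        i_ext=ExternalCurrent.constant(4.0, 2),
    )


def random_parameters(
    N: int,
    seed=None,
    profile_degree: int = 0,
    connection_prob: float = 0.7,
) -> ModelParameters:
    """Draw a physiologically plausible random parameter vector.

    The sampling box keeps all constraints of :func:`validate` satisfied by
    construction: capacitances in [0.8, 1.2], leak conductances in [0.4, 1]
    (leak times roughly 1-3 time units), threshold 10-20 mV above rest,
    reversal potentials near 0 (leak), 30-60 (excitatory), -20..-5
    (inhibitory) relative to rest, random synaptic topology with decay times
    in [1, 4], noise amplitudes giving membrane-potential fluctuations of a
    few mV, and a bounded constant drive.  Synaptic amplitudes are rescaled
    so the worst-case synaptic potential stays within 8 mV per neuron: this
    keeps the parameter box in the moderate-coupling regime where the
    uniform probability bounds remain resolvable in double precision.
    """
    rng = np.random.default_rng(seed)
    G = rng.uniform(0.05, 1.0, size=(N, N))
    G *= rng.random((N, N)) < connection_prob
    pop = np.where(rng.random(N) < 0.7, "E", "I")
    g_L = rng.uniform(0.4, 1.0, size=N)
    E_plus = rng.uniform(30.0, 60.0)
    E_minus = rng.uniform(-20.0, -5.0)
    tau_syn = rng.uniform(1.0, 4.0, size=(N, N))
    if G.any():
        alpha_plus = max(
            kernels.sup_sum(AlphaProfile(profile_degree, float(t)))
            for t in np.unique(tau_syn[G > 0])
        )
        e_max = max(abs(E_plus), abs(E_minus))
        worst = alpha_plus * e_max * (G.sum(axis=1) / g_L).max()
        if worst > 8.0:
            G *= 8.0 / worst
    return ModelParameters(
        N=N,
        C=rng.uniform(0.8, 1.2, size=N),
        theta=rng.uniform(10.0, 20.0),
        E_L=rng.uniform(-3.0, 3.0),
        E_plus=E_plus,
        E_minus=E_minus,
        g_L=g_L,
        G=G,
        pop=pop,
        tau_syn=tau_syn,
        profile_degree=profile_degree,
        sigma_B=rng.uniform(3.0, 6.0),
        sigma_R=rng.uniform(2.0, 4.0),
        i_ext=ExternalCurrent.constant(rng.uniform(-2.0, 4.0, size=N), N),
    )


def _params_to_dict(params: ModelParameters) -> dict:
    d = {
        "N": params.N,
        "C": params.C.tolist(),
        "theta": float(params.theta),
        "E_L": float(params.E_L),
        "E_plus": float(params.E_plus),
        "E_minus": float(params.E_minus),
        "g_L": params.g_L.tolist(),
        "G": params.G.tolist(),
        "pop": params.pop.tolist(),
        "tau_syn": params.tau_syn.tolist(),
        "profile_degree": int(params.profile_degree),
        "sigma_B": float(params.sigma_B),
        "sigma_R": float(params.sigma_R),
        "tau_sep": float(params.tau_sep),
        "i_ext": {
            "offsets": params.i_ext.offsets.tolist(),
            "values": params.i_ext.values.tolist(),
        },
    }
    return d


def save_params(params: ModelParameters, path) -> None:
    """Write a parameter file (YAML mirroring the field names)."""
    with open(path, "w") as fh:
        yaml.safe_dump(_params_to_dict(params), fh, sort_keys=False)


def load_params(path) -> ModelParameters:
    """Read a YAML/JSON parameter file; scalars broadcast to per-neuron vectors."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    N = int(d["N"])
    i_ext = d.get("i_ext", 0.0)
    if isinstance(i_ext, dict):
        current = ExternalCurrent(np.asarray(i_ext["offsets"]), np.asarray(i_ext["values"]))
    else:
        current = ExternalCurrent.constant(i_ext, N)
    return ModelParameters(
        N=N,
        C=d.get("C", 1.0),
        theta=float(d["theta"]),
        E_L=float(d.get("E_L", 0.0)),
        E_plus=float(d.get("E_plus", 65.0)),
        E_minus=float(d.get("E_minus", -10.0)),
        g_L=d.get("g_L", 1.0),
        G=d.get("G", 0.0),
        pop=np.asarray(d.get("pop", ["E"] * N)),
        tau_syn=d.get("tau_syn", 2.0),
        profile_degree=int(d.get("profile_degree", 0)),
        sigma_B=float(d.get("sigma_B", 1.0)),
        sigma_R=float(d.get("sigma_R", 1.0)),
        i_ext=current,
        tau_sep=float(d.get("tau_sep", 1.0)),
    )
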