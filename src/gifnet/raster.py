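"""Binary spike rasters with an explicit padding convention for the far past.

A raster is an ``N x T`` binary matrix ``omega_k(n)`` recording which neurons
spike at each integer time.  The theory treats rasters as bi-infinite
sequences; here a finite window stands in for them, with the ``padding`` field
declaring what every column left of the window is assumed to be:

* ``"zeros"`` -- the quiescent state (no neuron ever fired before the window);
  this is the lowest-conductance extension of the data and the default.
* ``"ones"`` -- every neuron fired at every past integer; the
  highest-conductance extension, useful as an adversarial extreme.

Columns right of the window are simply undefined: all operations only ever
query the past of their time argument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NEVER",
    "Raster",
    "fixture",
    "last_reset",
    "agree_depth",
    "spike_times",
    "write_raster",
    "read_raster",
]

#: Sentinel for "the neuron was never reset" (quiescent infinite past).
NEVER = float("-inf")

_PADDINGS = ("zeros", "ones")


@dataclass
class Raster:
    """Finite window of a spike raster.

    Attributes
    ----------
    omega
        ``N x T`` array with entries in {0, 1}; ``omega[k, i]`` is the spiking
        state of neuron ``k`` at integer time ``t0 + i``.
    t0
        Integer time of the first column.
    padding
        Assumed value of every column at times ``< t0`` ("zeros" or "ones").
    """

    omega: np.ndarray
    t0: int = 0
    padding: str = "zeros"

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega)
        if self.omega.ndim != 2:
            raise ValueError("omega must be a 2-D (neurons x time) array")
        vals = np.unique(self.omega)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("raster entries must be exactly 0 or 1")
        self.omega = self.omega.astype(np.int8)
        if self.padding not in _PADDINGS:
            raise ValueError(f"padding must be one of {_PADDINGS}")
        self.t0 = int(self.t0)

    @property
    def N(self) -> int:
        return self.omega.shape[0]

    @property
    def T(self) -> int:
        return self.omega.shape[1]

    @property
    def t_end(self) -> int:
        """Time of the last column."""
        return self.t0 + self.T - 1

    def value(self, k: int, n: int) -> int:
        """Spiking state of neuron ``k`` at integer time ``n`` (uses padding)."""
        if n < self.t0:
            return 1 if self.padding == "ones" else 0
        if n > self.t_end:
            raise IndexError(f"time {n} is beyond the raster window")
        return int(self.omega[k, n - self.t0])

    def column(self, n: int) -> np.ndarray:
        if n < self.t0:
            fill = 1 if self.padding == "ones" else 0
            return np.full(self.N, fill, dtype=np.int8)
        if n > self.t_end:
            raise IndexError(f"time {n} is beyond the raster window")
        return self.omega[:, n - self.t0].copy()

    def extended(self, pattern: np.ndarray) -> "Raster":
        """New raster with ``pattern`` appended as the next column."""
        col = np.asarray(pattern, dtype=np.int8).reshape(self.N, 1)
        return Raster(np.hstack([self.omega, col]), t0=self.t0, padding=self.padding)


def fixture(
    kind: str,
    N: int,
    T: int,
    t0: int = 0,
    seed: int | None = None,
    p: float = 0.3,
) -> Raster:
    """Reference rasters used throughout the test suite.

    ``omega0`` is the all-zero raster (no neuron ever fires, zeros padding),
    ``omega1`` the all-one raster (every neuron fires at every integer, ones
    padding), ``random`` an i.i.d. Bernoulli(``p``) raster with zeros padding,
    reproducible under ``seed``.
    """
    if N < 1 or T < 1:
        raise ValueError("N and T must be >= 1")
    if kind == "omega0":
        return Raster(np.zeros((N, T), dtype=np.int8), t0=t0, padding="zeros")
    if kind == "omega1":
        return Raster(np.ones((N, T), dtype=np.int8), t0=t0, padding="ones")
    if kind == "random":
        rng = np.random.default_rng(seed)
        omega = (rng.random((N, T)) < p).astype(np.int8)
        return Raster(omega, t0=t0, padding="zeros")
    raise ValueError(f"unknown fixture kind {kind!r}")


def last_reset(raster: Raster, k: int, t: float) -> float:
    """Most recent integer time ``n <= [t]`` with ``omega_k(n) = 1``.

    A spike recorded at integer ``n`` is treated as a reset at ``n`` itself.
    Returns :data:`NEVER` if the neuron never fired (zeros padding); with ones
    padding every integer is a spike, so the result is ``floor(t)``.
    """
    n_hi = math.floor(t)
    w_hi = min(n_hi, raster.t_end)
    if w_hi >= raster.t0:
        cols = raster.omega[k, : w_hi - raster.t0 + 1]
        idx = np.nonzero(cols)[0]
        if idx.size:
            return float(raster.t0 + idx[-1])
    if raster.padding == "ones":
        return float(min(n_hi, raster.t0 - 1))
    return NEVER


def spike_times(raster: Raster, j: int) -> np.ndarray:
    """Strictly increasing spike times of neuron ``j`` within the window."""
    return np.nonzero(raster.omega[j])[0].astype(np.int64) + raster.t0


def agree_depth(r1: Raster, r2: Raster, n: int) -> int:
    """Largest ``m >= 0`` such that the rasters agree on columns ``n-m .. n``.

    Returns ``-1`` if they already differ at column ``n``.  The depth is
    capped at the joint extent of the explicit windows plus padding: if the
    rasters agree on every comparable column and share the same padding
    convention, the cap ``n - min(t0) + 1`` is returned (agreement then
    extends to the infinite past by convention).
    """
    if r1.N != r2.N:
        raise ValueError("rasters must have the same neuron count")
    if n > r1.t_end or n > r2.t_end:
        raise ValueError("both windows must cover time n")
    lo = min(r1.t0, r2.t0)
    m = -1
    for r in range(n, lo - 1, -1):
        if np.array_equal(r1.column(r), r2.column(r)):
            m = n - r
        else:
            return m
    if r1.padding == r2.padding:
        return n - lo + 1
    return m


def write_raster(raster: Raster, path) -> None:
    """Write a raster as plain text: header line then one line per time step.

    Header: ``# gifnet-raster N=<N> t0=<t0> padding=<zeros|ones>``.  Each of
    the ``T`` following lines holds ``N`` space-separated 0/1 entries (CSV
    dialect with commas if the filename ends in ``.csv``).
    """
    path = str(path)
    sep = "," if path.endswith(".csv") else " "
    with open(path, "w") as fh:
        fh.write(f"# gifnet-raster N={raster.N} t0={raster.t0} padding={raster.padding}\n")
        for i in range(raster.T):
            fh.write(sep.join(str(int(v)) for v in raster.omega[:, i]) + "\n")


def read_raster(path) -> Raster:
    """Read a raster written by :func:`write_raster` (space- or comma-separated)."""
    path = str(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# gifnet-raster"):
            raise ValueError("not a gifnet raster file (missing header)")
        meta = dict(tok.split("=", 1) for tok in header.split()[2:])
        N = int(meta["N"])
        t0 = int(meta["t0"])
        padding = meta["padding"]
        rows = []
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.split(",") if "," in line else line.split()
            rows.append([int(v) for v in parts])
    omega = np.asarray(rows, dtype=np.int8).T
    if omega.size and omega.shape[0] != N:
        raise ValueError("raster body inconsistent with header neuron count")
    if omega.size == 0:
        omega = np.zeros((N, 0), dtype=np.int8)
    return Raster(omega, t0=t0, padding=padding)
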