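"""Reference identities recomputed from scratch at run time.

Each quantity here is an analytic identity of the model -- the effective
leak at coincident endpoints, the normalization of the one-step conditional
law, the unit partition function of the summed Gibbs potential, and the
vanishing kernel sum on the quiescent raster -- evaluated by actually running
the package on seeded random inputs, never asserted.
"""

from __future__ import annotations

import itertools

import numpy as np

from .kernels import alpha_sum
from .params import random_parameters
from .potential import effective_leak
from .raster import Raster, fixture
from .statistics import firing_arguments, log_one_minus_pi, log_pi, pi

__all__ = ["run_targets"]


def gamma_coincident(seed: int) -> float:
    """Effective leak Gamma_k(t1, t2, omega) at t1 = t2 = 3.7 (identity: 1)."""
    params = random_parameters(2, seed=seed)
    raster = fixture("random", 2, 10, t0=0, seed=seed + 1)
    return effective_leak(params, raster, 0, 3.7, 3.7)


def transition_normalization(seed: int) -> float:
    """Sum of the one-step conditional law over all 2^3 patterns (identity: 1)."""
    params = random_parameters(3, seed=seed)
    past = fixture("random", 3, 50, t0=0, seed=seed + 1)
    X = firing_arguments(params, past, past.t_end + 1)
    p_fire = pi(X)
    total = 0.0
    for pattern in itertools.product((0, 1), repeat=3):
        pat = np.asarray(pattern)
        total += float(np.prod(np.where(pat == 1, p_fire, 1.0 - p_fire)))
    return total


def partition_function(seed: int) -> float:
    """Partition function of the summed Gibbs potential (identity: 1).

    Enumerates all 2^(2*3) = 64 three-step continuation blocks of a fixed
    seeded 50-step past for the two-neuron network and sums exp of the summed
    potential.  Conditional probabilities telescope, so the sum is exactly 1.
    """
    params = random_parameters(2, seed=seed)
    past = fixture("random", 2, 50, t0=0, seed=seed + 1)
    n0 = past.t_end + 1
    total = 0.0
    for bits in itertools.product((0, 1), repeat=6):
        block = np.asarray(bits, dtype=np.int8).reshape(3, 2).T  # N x 3
        r = Raster(np.hstack([past.omega, block]), t0=past.t0, padding="zeros")
        phi = 0.0
        for i, l in enumerate(range(n0, n0 + 3)):
            X = firing_arguments(params, r, l)
            pat = block[:, i]
            phi += float(
                np.where(pat == 1, log_pi(X), log_one_minus_pi(X)).sum()
            )
        total += float(np.exp(phi))
    return total


def quiescent_kernel_sum(seed: int) -> float:
    """Spike-history kernel sum on the raster where no neuron ever fires (identity: 0)."""
    params = random_parameters(2, seed=seed)
    omega0 = fixture("omega0", 2, 12, t0=0)
    return alpha_sum(params, omega0, 0, 1, 10.5)


def run_targets(seed: int = 1):
    """Compute every reference quantity; return (results, pass/fail table)."""
    results = {
        "t1": {"value": gamma_coincident(seed), "n": 2},
        "t2": {"value": transition_normalization(seed), "n": 8},
        "t3": {"value": partition_function(seed), "n": 64},
        "t4": {"value": quiescent_kernel_sum(seed), "n": 2},
    }
    checks = {
        "effective leak, coincident endpoints (=1)": (
            abs(results["t1"]["value"] - 1.0) < 1e-14,
            f"value {results['t1']['value']:.15g}",
        ),
        "one-step law normalization, N=3 (=1)": (
            abs(results["t2"]["value"] - 1.0) < 1e-12,
            f"value {results['t2']['value']:.15g}",
        ),
        "Gibbs partition function, 3-step blocks (=1)": (
            abs(results["t3"]["value"] - 1.0) < 1e-10,
            f"value {results['t3']['value']:.15g}",
        ),
        "kernel sum on the quiescent raster (=0)": (
            results["t4"]["value"] == 0.0,
            f"value {results['t4']['value']:.15g}",
        ),
    }
    return results, checks
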