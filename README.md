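# gifnet

Simulation and exact spike-train statistics for conductance-based
integrate-and-fire networks.

## The problem

In a network of *N* integrate-and-fire neurons whose synaptic conductances
are driven by past spikes through causal kernels, the membrane potential of
neuron *k* obeys, below threshold,

    C_k dV_k/dt + g_k(t, ω) V_k = i_k(t, ω) + σ_B ξ_k(t),

where the conductance `g_k(t, ω) = g_L,k + Σ_j G_kj α_kj(t, ω)` sums a leak
term and kernel responses `α_kj(t, ω) = Σ_r α_kj(t − t_j^(r))` over all past
spike times of the presynaptic neurons, with `α(t) = (t/τ)^d e^{−t/τ} H(t)`
(exponential for d = 0, delayed-peak "alpha function" for d = 1).  When
`V_k` reaches the threshold θ a spike is registered at the next integer time
and the potential is reset to a Gaussian random value (mean 0, s.d. σ_R)
one spike duration later.  Time is measured in units of the spike duration,
so rasters are binary matrices ω_k(n) over integer times.

Because conductances integrate the entire spike history, the raster process
is **non-Markovian**: the probability of the next spiking pattern depends on
the infinite past.  It is nevertheless known in closed form.  Conditionally
on the history, the potentials are independent Gaussians with computable
mean `V_k^{det}` and variance `σ_k²`, so

    P[ω(n) | past] = Π_k [ ω_k(n) π(X_k) + (1 − ω_k(n)) (1 − π(X_k)) ],
    X_k = (θ − V_k^{det}) / σ_k,       π(x) = P(Z ≥ x),  Z ~ N(0,1).

The log of this one-step law is a Gibbs potential φ(n, ω) with infinite
range; summed over a block of times, its exponential is the exact block
probability (partition function identically 1).  Memory fades
exponentially — the *m*-variation of every history-dependent quantity
decays like `e^{−m/max(τ_kj, τ_L,k)}` — which is what keeps the
infinite-memory chain well behaved and uniquely determined.

## Who this is for

Researchers studying spike-train statistics (maximum-entropy / Ising-style
raster models, GLM-like point processes) who want a network model whose
exact distribution is *known*, to use as ground truth: for testing
statistical estimators, for quantifying what finite-memory truncations
lose, and for exploring how synaptic parameters shape the resulting Gibbs
potential.

## What the package provides

* `params` — parameter container, validation, and all closed-form uniform
  bounds (conductance sandwich, relaxation times, potential and variance
  windows, per-neuron firing-probability bounds 0 < Π⁻ < Π⁺ < 1).
* `raster` — binary rasters with explicit past-padding conventions, reset
  times, agreement depth, plain-text I/O.
* `kernels` — alpha profiles, spike-history sums with certified truncation
  tail bounds.
* `potential` — effective leak Γ_k, synaptic/external potential, noise
  variance, and the full conditional Gaussian law, via composite
  Gauss–Legendre quadrature on kink-free pieces.
* `statistics` — exact transition probabilities, the Gibbs potential,
  finite-memory truncations and their exact monomial (spike-product)
  expansions by Möbius inversion, no-fire probability bounds, and numerical
  checks of the uniqueness hypotheses.
* `simulate` — an exact sequential sampler (replica-batched, with
  closed-form kernel recursions) and an independent Euler–Maruyama SDE
  oracle for cross-validation.
* `variation` — empirical memory-decay curves against the analytic
  envelopes.
* `gifnet` CLI — `validate`, `simulate`, `analyze`, `potential`,
  `variation`, `acceptance`.

## Worked example

```python
import gifnet as gn

p = gn.load_params("examples/params_2neuron.yaml")   # documented E/I pair
b = gn.derive_bounds(p)
print(b.alpha_plus)          # 3.5277  – uniform kernel-sum bound
print(b.tau_L, b.tau_M)      # [2. 2.] [1.1726 0.9717]  – slow/fast relaxation

r = gn.sample_exact(p, gn.SimulationConfig(T=1000, seed=42, burn_in=50))
print(r.omega.mean(axis=1))  # [0.075 0.145]  – per-neuron firing rates

n = r.t_end
res = gn.transition_probability(p, r, n, r.column(n))
print(res.X)                 # [6.     1.0223] – threshold distances X_k
print(res.p_fire)            # [0.     0.1533] – firing probabilities π(X_k)
print(res.p_pattern)         # 0.846672 – probability of the observed pattern
print(gn.gibbs_potential(p, r, n - 2, n))   # -2.63538 = log P[last 3 steps]
```

The threshold distances say how many conditional standard deviations each
neuron sits below threshold given the whole spike history: neuron 0 had
just been reset (X = θ/σ_R = 6, firing probability ≈ 1e−9) while neuron 1
is one deviation below threshold and fires with probability 0.153.  The
summed potential over the last three columns is the exact log-probability
of that block given everything before it.

The same model can be run from the shell:

```
gifnet simulate --params examples/params_2neuron.yaml --steps 1000 \
       --seed 42 --burn-in 50 --out raster.txt
gifnet analyze --params examples/params_2neuron.yaml --raster raster.txt --t 900.5
```

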