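# Methods

This note documents the model as implemented, the numerical choices, the
design decisions taken where the design was genuinely open, and the limits
of what the test suite demonstrates.

## Model and conventions

The network couples continuous membrane dynamics to discrete spike events.
Spikes have unit duration (time is measured in spike durations), are
registered on the integer grid, and reset the membrane potential to a
Gaussian random value with mean 0 (the rest potential) and standard
deviation σ_R > 0.  The refractory period is shorter than one time unit, so
consecutive 1s are allowed in a neuron's spike row.  Membrane noise enters
as additive white noise of amplitude σ_B > 0.  Both noise amplitudes must
be strictly positive: the conditional variance is then bounded away from
zero, every firing probability lies strictly inside (0, 1), and the
conditional law is well defined for every history.

Potentials are in mV relative to rest, conductances and capacitances in
consistent arbitrary units; these conventions are documented, not enforced.

Reset timing: a spike recorded at integer n is treated as a reset at n
itself.  With unit spike separation the alternative (resetting one integer
later) shifts nothing observable, because the reset value is random and the
potential during the spike is never queried; choosing the spike integer
keeps the threshold distance well defined even when the neuron fired at the
immediately preceding step (the window is then empty: conditional mean 0,
variance σ_R²).

Finite rasters stand in for the bi-infinite histories of the theory through
an explicit `padding` field: every column left of the window is all-quiet
(`zeros`, the lowest-conductance state, default) or all-firing (`ones`, the
highest).  All truncation errors this introduces are controlled by two
certified decay estimates: the kernel tail bound and the leak envelope
(below).

## Kernels and the uniform kernel-sum bound

Synaptic kernels are `α(t) = (t/τ)^d e^{−t/τ} H(t)`; degrees 0 and 1 cover
the synaptic responses in common use and get closed-form treatment; higher
degrees are supported through the same incomplete-gamma tail formula.  The
spike-history sum over a raster is truncated at the smallest horizon whose
tail bound (the tail integral `τ Γ(d+1, m/τ)`, a polynomial times
`e^{−m/τ}`) falls below a tolerance (default 1e−10), plus one unit interval
of guard: a unit-spaced sum with all lags above m+1 is dominated by the
integral from m, not the sum with lags above m.

The uniform bound α₊ on the kernel sum — the worst case over all histories
and all real query times — is the series of per-unit-interval suprema
**including the sub-unit-lag interval**: a spike at the integer just below
a non-integer query time contributes at lag below 1.  For the exponential
kernel α₊ = 1/(1 − e^{−1/τ}).  Dropping the sub-unit interval (i.e.
starting the series at lag 1) produces a constant that randomized
conductance-sandwich trials falsify at non-integer times; the corrected
constant propagates unchanged through every downstream bound.

## Quadrature

All potential-type quantities are leak-weighted time integrals whose
integrands are smooth except at integers (where new spikes switch kernels
on) and at external-current breakpoints.  They are evaluated by composite
Gauss–Legendre quadrature (default order 8) on pieces that never straddle
such a point, which restores spectral accuracy.  The cumulative conductance
integral at the interior nodes is obtained with a precomputed
Lagrange-basis integration matrix, making the nested integral (effective
leak inside the potential integral) a single pass.  Doubling the
subdivision changes the outputs by less than 1e−9 on the reference network
(asserted in the suite).

Infinite-past lower limits are replaced by a window of length
`τ_L ln(1/tol)` (about 46 time units for the reference network at
tol = 1e−10): beyond it the effective leak alone suppresses every integrand
below tolerance.  The neglected mass is reported as
`truncation_error_bound`; the reset-variance term is dropped in that limit
(its leak factor is below tolerance squared).

The external current is piecewise-constant per neuron on a declared
sub-grid of the unit interval, repeated every interval (default: constant).
This keeps integrands piecewise-smooth with known breakpoints and covers
constant and pulsed stimuli; slowly varying stimuli can be staircased on
the sub-grid.

## Exact sampler

For kernel degrees 0 and 1 the spike-history sums obey exact one-step
filter recursions (states E and D per synapse), so the sampler carries
states instead of re-summing history and evolves many independent replicas
as vectorized arrays; only the leak-weighted integrals are windowed, at the
leak-envelope horizon.  The recursion route and the generic quadrature
route are developed independently and are asserted to agree to 1e−8 on
random histories under both padding conventions — this is the package's
internal double-entry bookkeeping.  Replica counts of 10⁴ over short
windows run in seconds; memory grows as replicas × synapses × horizon.

## SDE oracle

The Euler–Maruyama integrator knows nothing about the closed-form law: it
integrates the membrane equation directly (additive noise, hence strong
order 1; higher-order schemes would buy nothing) with threshold detection
and random reset, recomputing conductances from the raster.  Two
spike-registration rules are provided: `endpoint` (a spike at n when the
potential at n−1 is at or above threshold) matches the discrete pipeline's
conditional law exactly and is the rule used in consistency tests;
`crossing` (threshold reached anywhere in the preceding unit interval, the
membrane then frozen until reset — the spike shape plays no role) is the
more physical variant, and the difference between the two is a genuine
model-discretization gap that the package exposes rather than hides.
Consistency tolerances in tests are three standard errors plus an explicit
O(dt) allowance for the Euler bias.

## Statistics

The Gaussian tail π and its logarithm use the scipy normal-distribution
primitives (`ndtr`, `log_ndtr`), stable far into the tails.  The uniform
probability bounds Π±_k are carried both linearly and in log space: in the
moderate-coupling regime they can sit within one floating-point ulp of 0 or
1 in linear scale while remaining exactly representable as logs, and all
strict-inequality assertions compare logs.

Truncating the potential to memory depth D replaces the infinite past by
the declared boundary padding.  The truncated potential is normalized by
construction (its normalizer, computed by enumeration over the 2^N time-0
patterns, is 1 up to rounding), because it *is* a conditional probability
given the padded past — truncation schemes that instead truncate the
monomial series need not be normalized.  The monomial expansion over spike
products is obtained by exact Möbius inversion over all 2^{N(D+1)} binary
blocks; the time-0 spins enter the potential linearly, so every coefficient
with two or more time-0 factors vanishes (asserted below 1e−10), and the
depth-0 truncation is an independent-Bernoulli model — the reason
memoryless Ising-style fits cannot represent this process at the native
time resolution.  Exhaustive enumerations are refused above 22 spike bits.
The expansion coefficients are computed numerically relative to a named
boundary past; no closed form is attempted.

The no-fire probability bounds use the per-neuron constants (Π−_k, Π+_k):
each one-step conditional silence probability lies strictly inside that
window, so a silent stretch of length L lies inside its L-th powers.  The
product over all neurons is *not* a valid upper bound for a single neuron's
silence (a product of numbers below 1 only shrinks) and is used only where
a full-pattern probability is bounded: the uniqueness lower bound
m(p) ≥ Π_k Π−_k.

The summed-variation hypothesis v(p) < ∞ cannot be computed exactly (it
involves a supremum over uncountably many pasts and an infinite sum); the
package reports an empirical partial sum plus the analytic geometric tail
of the variation envelope, labeled an estimate, not a proof.

## Variation curves

The m-variation supremum is lower-bounded by evaluating quantities on
nested adversarial history pairs: one shared random suffix realization
glued onto the all-quiet / all-firing prefixes (the extreme conductance
states) plus seeded Bernoulli prefixes, with suffix and prefixes drawn once
so curves are comparable across depths.  Envelope comparisons are one-sided
(a lower bound must stay below an upper bound) and carry an explicit onset
depth m₀, because the envelope constants hold asymptotically; for the
reference network m₀ = 1 (scanned).  Fitted log-slopes approach
−1/max(τ_kj, τ_L,k) — memory is lost at the slower of the synaptic and leak
rates — with the synaptic-potential fit taken over depths 8–19 where the
faster transient terms have died out.

## Parameter choices

The reference two-neuron network (one excitatory, one inhibitory;
`examples/params_2neuron.yaml`) uses physiological reversal potentials
relative to rest (AMPA-like +65 mV, GABA-A-like −5 mV), a 2-unit leak
time, 2–3-unit synaptic decay times, and drive/noise placing the quiescent
one-step firing probability near 0.15 — active but far from saturation.

The random-parameter box used by the property suites keeps the same
physiological ranges but rescales synaptic amplitudes so the worst-case
synaptic potential stays within 8 mV per neuron.  This is the
moderate-coupling regime in which the uniform worst-case bounds are
informative; with strong coupling the bounds remain true but the extreme
probabilities fall below double-precision resolution even in log space, and
asserting strict inequalities would be vacuous.  The box is a package
choice: the theory itself only requires parameters bounded and noise
amplitudes positive, and imposes no numeric defaults.

Problem sizes in the verification suite — 2–3 neurons, 10³–10⁴ sampled
replicas or SDE paths, 10³ randomized bound triples, depth-16 variation
curves — are desk-scale choices that keep the whole suite under a minute
while leaving every statistical check at three standard errors or better.

## What passing tests do and do not show

All test inputs are generated by the package itself (seeded random
parameters and rasters, the two extreme rasters, simulator output); there
are no recorded data.  The suite therefore validates the *mathematics and
numerics* of the model — identities, bounds, decay rates, cross-route
consistency — not any claim about biological spike trains.  Real
recordings differ in every inconvenient way: unknown and non-stationary
parameters, unobserved neurons, spike-sorting errors, and binning effects
(amalgamating spikes within a time window reintroduces same-bin
correlations that the native-resolution independence structure forbids).

## Known limitations

* Kernel degrees above 1 take the generic quadrature path throughout
  (no filter recursions), so sampling is markedly slower there.
* Saturating (non-additive) synaptic summation is deliberately out of
  scope: kernel contributions add linearly.
* Refractory periods longer than one time unit (which would forbid spike
  patterns and turn the raster space into a constrained grammar), synaptic
  plasticity on the amplitude matrix, and fitting parameters or expansion
  coefficients from empirical rasters are not implemented.
* The empirical variation curves are lower bounds on a supremum; envelope
  checks are one-sided by design.
* Free-running SDE simulation evolves a single path per call; batched paths
  are provided only for clamped-history conditional sampling, which is what
  the consistency checks need.
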