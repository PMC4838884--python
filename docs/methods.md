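# Methods

## Continuous dynamics

The model is the normalized coarse-grained rate equation
dx_i/dt = f_i(x) − x_i on [0, 1]^N. Time is measured in units of the
(common, unit) degradation timescale; all activities are dimensionless
fractions of their saturating maximum. The generation rate multiplies one
activation gate by one repression gate:

* activation gate: S_A/(1 + S_A) with S_A = Σ_j (x_j/a_j)^{n_j} over the
  activating in-edges (so parallel activators are OR-like: any saturated
  activator opens the gate);
* repression gate: 1/(1 + S_I) with S_I summed over inhibiting in-edges
  (any saturated inhibitor closes it — a veto);
* a node with no activators but some inhibitors has f_i equal to the
  repression gate alone (constitutive generation under repressive
  control); a node with no in-edges has f_i = 0 and decays.

With a single regulator and shared (n, a) this is the textbook Hill pair
xⁿ/(aⁿ + xⁿ) and aⁿ/(aⁿ + xⁿ); the two are complementary, and both equal
1/2 at x = a. The per-edge scaling (x/a_e)^{n_e} is the natural
generalization that keeps the additive composition well-defined when each
interaction carries its own parameters and reduces exactly to the global
form when they are shared.

Parameters: n (Hill coefficient, steepness, dimensionless, ≥ 1) and a
(activity threshold on the normalized scale, in (0,1)). Defaults n = 3,
a = 0.5: on a [0,1] scale with activity conventionally read as "on" above
0.5, the midpoint is the natural threshold, and n = 3 gives switch-like
but not discontinuous responses. Per-edge values on an edge override
either mode. The rate law sits behind a small interface
(`dynamics.RateLaw`) so alternative algebraic forms can be swapped in for
sensitivity checks without touching the census or landscape code.

Because 0 ≤ f ≤ 1 and degradation is −x, the vector field points inward
on the boundary of the unit box; trajectories never leave it (checked
numerically to solver tolerance in the acceptance suite).

Integration uses an adaptive stiff-capable solver (LSODA) with the
analytic Jacobian, rtol 1e-8 / atol 1e-10 — steep Hill terms at large n
make stiffness routine. Convergence-to-steady-state stops integration
when the max-norm of the free-coordinate derivative falls below the
requested tolerance; the internal stopping event fires at half that
tolerance so the endpoint strictly satisfies the stated bound despite
event-location error.

## Boolean dynamics

The discrete analogue sets a node to 1 iff its activation condition holds
and no inhibitor is on. The activation condition is "at least one
activator on" for nodes that have activators and vacuous otherwise, so an
inhibitor-only node is on exactly when uninhibited — the same logic as
the continuous f, whose inhibitor-only value is 1 at zero inhibition.
Input-free nodes go to 0 (decay). This choice is what makes the
continuous-to-Boolean cross-validation meaningful: with a literal
"needs an activator" rule, the high state of a plain mutual-inhibition
toggle would be Boolean-transient even though it is a continuous
attractor.

Synchronous update is the default; asynchronous single-node update is
available for sensitivity checks. Attractor enumeration is exact up to 20
nodes (vectorized successor map plus pointer doubling to land every state
on its cycle); larger networks fall back to sampled trajectories with
cycle detection.

## Fixed-point census

Two independent mechanisms:

1. **Attractors**: integrate from uniform random initial states (default
   10⁴ for ~100-node networks, far fewer for the small fixtures), declare
   convergence at max-norm residual < 1e-6 within horizon 100 (deep
   relaxation when the decay time is 1), Newton-polish the endpoints, and
   deduplicate greedily at 1e-3 in max norm — well below the
   inter-attractor distances of near-binary profiles and well above
   solver noise. Basin tallies count starts per attractor; endpoints that
   stall on slow manifolds near non-stable points are excluded from the
   attractor census and reported as non-converged. The census is sampled,
   not certified: it covers attractors with non-negligible basins.
2. **Saddle/unstable points**: damped Newton (backtracking line search,
   iterates projected into the box) from random interior seeds and from
   midpoints of attractor pairs — saddles sit on basin boundaries between
   adjacent attractors, so pair midpoints are productive seeds.

Classification reads the Jacobian spectrum at the refined point: index =
number of eigenvalues with positive real part; 0 attractor, 1 saddle,
≥ 2 unstable. Eigenvalues with |Re λ| < 1e-6 flag the point as degenerate
rather than forcing a class.

## Transition landscape

For each non-attractor fixed point, displace by ±1e-3 along each unit
unstable eigenvector (complex pairs contribute their normalized real and
imaginary parts, spanning the unstable plane), integrate to convergence,
and match the endpoint to the nearest known attractor within the dedup
tolerance; unmatched endpoints are kept and reported, never dropped.
Attractor adjacency is derived from shared *saddles* only (index 1) —
the generic one-dimensional passes between basins; higher-index points
appear in the graph but do not define routes. Routes between attractors
are simple paths in this adjacency, shortest first with lexicographic
tie-breaks.

## Perturbation protocols

A clamp sets the chosen coordinates to their values and holds them there
(zero derivative) for the stage duration — the coordinate-holding
semantics of "node values are changed to v" — then releases and lets the
free dynamics relax to convergence before the next stage. One consequence
worth knowing: a full clamp to 0/1 is a jump, and if the jumped state
already lies across a basin boundary the switch commits at any dwell
time; dwell-time dependence appears with partial clamps (the acceptance
suite demonstrates both on the toggle). Screens enumerate clamp sets
size-ascending with lexicographic order over (node, level ∈ {0,1}) for
reproducibility, returning all successful sets of the smallest successful
size.

## Robustness

Each resample draws independent per-edge (n_i, a_i) uniformly from
configurable ranges (defaults n ∈ [2,5], a ∈ [0.3,0.7]; a coupled mode
draws one fraction per edge for both). Reference attractors are matched
in the resampled system primarily by identity of the >0.5-discretized
profile — parameter changes move attractor coordinates continuously but
phenotype identity is profile-level — with a max-norm distance fallback.
Recurrence for the plain toggle over the default wide ranges is genuinely
below 1 (≈0.8): bistability needs the loop gain at the symmetric point to
exceed 1, roughly n > 4a for matched parameters, so draws with n near 2
and a above 0.5 are monostable. This is a property of the model family,
not a search failure; narrow ranges around the defaults give recurrence 1.

## Profiles and concordance

Discretization is strictly greater-than-threshold (default 0.5); a value
exactly at threshold is inactive. Differential calls between two states
use a minimal change δ = 0.2 — large enough to separate the near-binary
attractor levels while tolerating parameter jitter, configurable.
Observed tables are pre-discretized gene-level up/down/flat calls;
gene-to-node maps may be one-to-many, aggregated per node by majority
with ties going to flat. Concordance scores agreement over nodes called
non-flat on both sides.

## Synthetic fixtures

The generators produce the study systems, with oracle-known structure:

* self-activator (1 node): three fixed points at 0, 1/2, (1+√5)/4 for the
  defaults, verifiable by a 1-D root scan;
* plain toggle switch: two mirror attractors plus the symmetric saddle
  (2-D grid-scan oracle); the self-activating variant adds a quiescent
  (0,0) attractor;
* inhibition ring (3 nodes): oscillatory, no point attractors — it
  exercises the no-attractor paths;
* miniature fate network (8 nodes, wiring frozen in a versioned data
  file): two mutually suppressing self-activating fate hubs with
  downstream targets and a survival/apoptosis toggle; exactly four
  attractors (fate A, fate B, apoptotic, null), cross-checked with 3000
  random starts;
* random signed networks: Poisson in-degrees around a mean (floored at 1
  so no degenerate source nodes unless requested), i.i.d. signs,
  fully seeded;
* expression tables: per-gene true differential calls flipped to another
  call with a given rate, for concordance-recovery tests with a binomial
  closed-form expectation.

What the fixtures do **not** emulate: real expression noise models,
probe-level microarray structure, unequal degradation rates, and the
scale/heterogeneity of literature-curated disease networks. Passing
tests certify the machinery (census completeness on systems where
exhaustive oracles exist, invariance, determinism), not the biological
fidelity of any particular wiring.

## Numerical choices and limitations

* Dedup/matching tolerance 1e-3 (max norm); escape displacement 1e-3;
  degeneracy tolerance 1e-6; Newton residual target 1e-10 with projection
  into the box and failure reported with the best iterate.
* All stochastic procedures take explicit integer seeds and are
  bit-for-bit reproducible; start sets extend monotonically with the
  budget under a fixed seed.
* Problem sizes in the shipped tests and acceptance script (hundreds of
  starts on ≤20-node fixtures, 50 robustness resamples at 50 starts each)
  were chosen as the smallest budgets at which the fixture censuses are
  stable across seeds.
* Global enumeration is not certified (no interval or homotopy methods);
  saddle counts on large networks depend on seed budget. Basin *volumes*
  are not computed, only hit counts from uniform sampling.
* The stochastic extension (noise-driven transitions, potential
  landscapes) and parameter fitting to time series are out of scope.
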