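# Methods

This note records the modelling conventions, numerical choices and known
limitations of `boolmut`, in the order a user meets them: dynamics, random
model generation, mutation semantics, sensitivity measures, the synergy
workflow, and the simulation engine.

## Dynamics and attractors

States are bit vectors aligned to the network's node order and are updated
synchronously: every node evaluates its rule on the pre-step state. A
nested canalyzing rule is evaluated by scanning its terms in precedence
order and returning the canalyzed value of the first term whose input sits
at its canalyzing value, else the default output. A node with no incoming
edges holds its current state (`v(t+1) = v(t)`); this is the only
convention that keeps such nodes well-defined without inventing an external
input.

Attractors are found by exact trajectory hashing: every visited state is
recorded with its first-visit time, and the first revisit at time *t* of a
state first seen at *t₀* yields transient *t₀*, period *p = t − t₀*, and
the cycle as the recorded slice — exactness is required because the
distance measures need the full cyclic state list and the minimal
transient, which Floyd/Brent-style constant-memory detection would have to
re-derive. The cycle is stored anchored at its first-visited state; both
distance measures are rotation-invariant, so the anchor is internal. The
step budget defaults to 10,000 (a revisit is guaranteed within 2^N steps,
which is not a usable bound for large N); exceeding it raises an error that
names the offending initial state rather than returning a partial answer.

Initial-state samples are drawn uniformly without replacement; if the
requested count reaches 2^N (N ≤ 24) the full state space is returned in
integer order, making small-network ensembles exhaustive and deterministic.

## Random networks and rules

The built-in network generator draws M distinct ordered pairs uniformly
from the N² possible (self-loops allowed) and signs each edge positive with
probability `positive_fraction` (default 0.5). It is a fixture generator:
it makes no attempt at scale-free degree structure, so absolute
sensitivities on real signaling topologies will differ; only distributional
and ordering properties should be read off synthetic ensembles.

Random rules give each node a uniformly random permutation of its incoming
edges as term order (no statement ties precedence to file order, and file
order would bias position-dependent statistics), then sample
`I_k ~ Bernoulli(1/2)` and `O_k ~ Bernoulli(σ(−θ·2⁻ᵏ))` with k the 1-based
position and θ = 7 by default — at that value Pr(O₁=1) ≈ 0.029, so
high-precedence outputs are strongly biased to 0, which is what makes
knockouts systematically milder than overexpressions. The grouping of θ in
the exponent is ambiguous in parts of the literature (σ(−θ·2⁻ᵏ) vs
σ(−2⁻ᵏ/θ)); we use σ(−θ·2⁻ᵏ), the only reading under which the stated
bias toward 0 at small k is strong (the other reading gives Pr(O₁=1) ≈
0.48). The default output is always 1 − O_d for generated rules; rule
files may set any default.

Because sampling I and O independently can contradict an edge's stored
sign, a `sign-constrained` mode forces I_k = O_k on positive edges and
I_k = 1 − O_k on negative ones (the correspondence sign ⇔ [I = O] follows
from expanding the rule into and/or form). Independent sampling remains
the default.

All randomness flows from one master seed through fixed substreams (rule
generation, initial states, per-mutation randomness), so changing the
number of initial states never perturbs which rules are generated, and any
reported number can be replayed from the logged seed.

## Mutation semantics

Mutations are pure transformations: `apply_mutation` returns fresh copies
and the wild-type model is never touched. A mutation group may contain
several nodes or edges; all are transformed simultaneously, and removing
{e₁, e₂} in one group equals removing them sequentially in either order.

Decisions worth recording:

- **Duration.** A mutation with duration τ governs steps t ∈ [1, τ]; the
  attractor of the composite trajectory is detected on the post-reversion
  dynamics, with the state at t = τ as effective initial state. Only the
  post-reversion dynamics admit a well-defined attractor — the composite
  system is eventually governed by the wild-type rules alone. `permanent`
  detects the attractor wholly under the mutant model.
- **State-flip** is output negation applied at every step while in force
  (f′ = 1 − f), not a one-time state toggle; for a zero-in-degree node this
  negates the held state each step.
- **Rule-flip** flips every I_k and O_k and also the default output,
  preserving the default = 1 − O_d invariant; flipping only the printed
  term values would silently break it.
- **Outcome-shuffle** samples its permutation once per `apply_mutation`
  call from the spec's seed substream, so one fixed mutant network is used
  across the whole initial-state ensemble — resampling per initial state
  would make λ average over different mutants.
- **Edge-addition** samples the new term's (I, O) at position k = 1 from
  the random-rule distribution, once per spec (overridable via
  `params["io"]`). The new edge's sign defaults to positive iff I = O,
  matching the sign ⇔ [I = O] correspondence; there is no canonical
  candidate set of non-existent edges, so ensemble drivers require explicit
  candidate edges rather than guessing one.
- **Edge-sign-switch / edge-reverse** rewrite the term (I_j → 1 − I_j,
  O_j → 1 − O_j respectively) and also flip the stored sign of the edge in
  the mutant network copy, keeping G′ and F′ consistent under the same
  correspondence. Note that attenuation is keyed by edge: re-applying it
  to the same edge is a no-op (its term already sits at the lowest
  precedence); the involutive property holds positionally (repeating the
  transposition (j, d) restores the rule).

User-defined operators register a node transform and/or an edge transform
(pure functions `(rule, network, rng) → rule` and
`(rule, edge, network, rng) → rule`), by call or from a script file.
Returned rules are validated against the mutant topology; no biological
plausibility checks are made.

## Sensitivity measures

The identicalness distance is 0 iff the two attractors have equal period
and some cyclic rotation aligns them exactly, else 1 — so λ is the
fraction of initial states whose attractor changed. (The opposite polarity
would make λ the fraction of *unchanged* attractors, contradicting the
notion of sensitivity; we use changed = 1.)

The similarity distance extends both cycles to their least common period
c = lcm(p, p′) by modular indexing and returns the minimum over time lags
m of the mean per-bit Hamming mismatch. The lag only ranges over
0..gcd(p, p′)−1: the windowed mismatch is periodic in m with period
gcd(p, p′), so nothing beyond it can attain a smaller minimum. This is
property-tested against the brute-force scan over all c lags.

Mutation-susceptibility scores node v as λ({v}) for node-based operators
and as max over λ({e}) for edges e incident to v for edgetic ones.
"Incident" is taken as incoming *or* outgoing — the looser reading; users
who want only regulatory inputs can score edges directly. The ranking AUC
is the Mann–Whitney probability that a random positive outranks a random
negative with ties counted ½ (delegated to scikit-learn's
`roc_auc_score`; the tie convention is pinned independently in tests).

λ values entering the synergy deviation use the same rule set and the same
initial-state sample for singles and doubles; pairing them otherwise would
confound ε with sampling noise. ψ_ROOT is implemented exactly as
√(x² + y²) even though it can exceed 1; capping it would silently change
the classification near the boundary.

## Simulation engine and parallelism

Networks with at most 62 nodes are packed into one 64-bit word per state
and stepped by numba-compiled kernels; cycle detection scans the stored
trajectory (quadratic in trajectory length, negligible at the trajectory
lengths NCF dynamics produce). Wider networks use the object-level Python
path with identical semantics; the equivalence of the two paths is
property-tested across operators, durations and measures.

Parallelism follows a determinism-first contract: the initial-state sample
is split into contiguous chunks, evaluated by threads, and reduced in
sample order, so any `workers` setting produces bit-identical results for
a fixed seed. Tests assert byte-identical command outputs for workers ∈
{1, 2, 4}.

## Problem sizes used by the bundled analyses

The test-suite ensembles use 500 random rules (exhaustive over ≤ 2⁴ input
combinations), 200 random networks of up to 8 nodes checked over their full
state space, 1,000 synthetic attractor pairs per distance property, 20,000
sampled terms per rule position for the sampling distribution, a 15-node /
30-edge network with 100 initial states for the synergy orderings, and 100
random 30-node / 60-edge networks with 200 initial states and τ = 10 for
the mutation-type tendency ensemble. `scripts/acceptance.py` runs one
30-node / 60-edge network with ten rule sets and 200 initial states for
the per-kind means (τ = 10), the same scale for the susceptibility AUCs
(τ = 20), and a 10-node / 22-edge network with five rule sets for the
synergy counts (τ = 10, β = 0.1); on a 22-edge network a single rule set
often has no synergistic pair at all, so counts are reported as means over
the five rule sets.

## Limitations

- Updates are synchronous only; asynchronous or probabilistic schemes
  would need additional scheduling parameters the model does not carry.
- NCFs cover most but not all experimentally curated Boolean rules;
  non-canalyzing logic (e.g. XOR-like rules) cannot be expressed.
- The random network generator has no degree-distribution realism (see
  above); conclusions about real networks should rerun the drivers on real
  edge lists.
- Neutral (unsigned) interactions are not representable; sign is required
  on every edge.
- The identicalness measure is blind to *how* different two attractors
  are; the similarity measure is blind to transient behaviour. Both
  compare attractors only.
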