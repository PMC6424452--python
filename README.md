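# boolmut

Boolean-network sensitivity analysis against node-based and edgetic
mutations.

`boolmut` is for systems biologists who want to ask, *in silico*, how much a
signed gene-regulatory or signaling network's long-run behaviour changes
when a gene — or a single interaction — is perturbed. It implements
synchronous Boolean dynamics with nested canalyzing update rules, ten
predefined mutation operators (plus a plugin contract for novel ones),
control over the mutation area (any set of nodes and/or edges) and duration,
two attractor-distance sensitivity measures, per-node mutation-susceptibility
scoring for target prioritisation, and a double-mutation synergy analysis.

## Model

A network is a directed graph *G*(*V*, *E*) with activation/inhibition edge
signs. Each node carries a Boolean state; all nodes update synchronously.
The update rule of a node with inputs *u*₁, …, *u_d* is a **nested
canalyzing function** (NCF): an ordered sequence of pairs (*I_k*, *O_k*) —
the first input sitting at its canalyzing value *I_k* fixes the output to
the canalyzed value *O_k*; if none matches, a default output applies
(*O*_default = 1 − *O_d* by convention). Unknown rules are sampled randomly
with

    Pr(I_k = 1) = 1/2,    Pr(O_k = 1) = σ(−θ · 2⁻ᵏ),    θ = 7 by default,

so high-precedence terms are strongly biased toward output 0.

Every deterministic trajectory ends in an attractor (fixed point or limit
cycle). The **sensitivity** of the network to a mutation is

    λ = Σ_{v(0) ∈ S} d(⟨G,F,v(0)⟩, ⟨G′,F′,v(0)⟩) / |S|

the mean attractor distance between wild-type (*G*, *F*) and mutant
(*G*′, *F*′) over a shared sample *S* of initial states. Two distances are
provided: *identicalness* (0 iff the attractors coincide up to a cyclic
rotation, so λ is the fraction of changed attractors) and *similarity* (the
minimal per-bit Hamming mismatch over time lags, averaged over the least
common period). A mutation may be **permanent** or act only for steps
*t* ∈ [1, τ], after which the wild-type rules govern again.

Mutation operators: **node-based** — state-flip (f′ = 1 − f), knockout
(f′ ≡ 0), overexpression (f′ ≡ 1), rule-flip (all *I_k*, *O_k* flipped),
outcome-shuffle (canalyzed values permuted); **edgetic** — edge-removal,
edge-addition, edge-attenuation (term demoted to lowest precedence),
edge-sign-switch (*I_j* → 1 − *I_j*), edge-reverse (*O_j* → 1 − *O_j*).

For double edge-removal mutations, the synergy deviation
ε(eᵢ, eⱼ) = λ({eᵢ, eⱼ}) − ψ(λ(eᵢ), λ(eⱼ)) compares the double-mutant
sensitivity with an expectation ψ ∈ {max(x,y), √(x²+y²), min(x+y,1)};
pairs with ε > β are labelled synergistic.

## Worked example

```python
from boolmut import (generate_random_network, generate_random_rules,
                     random_initial_states, MutationSpec, calc_sensitivity,
                     find_attractor)

net = generate_random_network(10, 22, positive_fraction=0.6, seed=42)
rules = generate_random_rules(net, theta=7.0, seed=42)
states = random_initial_states(net.n_nodes, 200, seed=42)

attr = find_attractor(net, rules, states[0])
print(f"first initial state reaches a period-{attr.period} attractor "
      f"after {attr.transient} transient steps")

edge = next((s, t) for s, t, _ in net.edges if s == "v03" or t == "v03")
for kind, target in [("knockout", ("v03",)),
                     ("overexpression", ("v03",)),
                     ("edge-removal", (edge,))]:
    spec = MutationSpec(kind, target, duration=10, seed=0)
    res = calc_sensitivity(net, rules, spec, states, measure="identicalness")
    name = target[0] if isinstance(target[0], str) else "->".join(target[0])
    print(f"lambda({kind:>14s} @ {name}) = {res.lam:.3f}")
```

prints

```
first initial state reaches a period-1 attractor after 8 transient steps
lambda(      knockout @ v03) = 0.490
lambda(overexpression @ v03) = 0.510
lambda(  edge-removal @ v03->v04) = 0.000
```

Half of the 200 sampled initial states settle into a different attractor
when `v03` is clamped off for the first ten steps (λ = 0.49); clamping it on
is slightly more disruptive; deleting one of its outgoing interactions
changes no attractor at all in this rule set.

The same analyses are available from the shell:

```sh
boolmut generate --nodes 10 --edges 22 --seed 42 \
    --out-network net.tsv --out-rules rules.txt
boolmut sensitivity --network net.tsv --rules rules.txt \
    --mutation knockout --targets all-nodes --tau 1,2,5,10 \
    --num-states 200 --seed 42 --out lambdas.tsv
boolmut synergy --network net.tsv --rules rules.txt --tau 10 \
    --num-states 200 --beta 0.1 --seed 42 --out synergy.tsv
```

All commands honor `--seed` (byte-identical outputs across runs and
`--workers` settings) and accept a YAML `--config` mirroring the flags.

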