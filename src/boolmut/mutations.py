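"""The ten predefined mutation operators, duration semantics, and plugins.

Node-based operators rewrite a node's whole update rule (state-flip,
knockout, overexpression, rule-flip, outcome-shuffle); edgetic operators
rewrite the single term of a specific incoming interaction (edge-removal,
edge-addition, edge-attenuation, edge-sign-switch, edge-reverse).  A
mutation spec names the operator, the mutation group (the nodes/edges
perturbed simultaneously), and a duration: the mutation is in force for
steps t in [1, tau_m], after which the wild-type rules govern again;
``duration="permanent"`` never reverts.

All transformations are pure: ``apply_mutation`` returns fresh copies and
never touches the wild-type model.  User-defined operators plug in through
``register_plugin`` / ``load_plugin_file`` with the same two-transform
contract (one for node targets, one for edge targets).
"""

from __future__ import annotations

import importlib.util
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from ._random import STREAM_MUTATION, substream
from .dynamics import (
    DEFAULT_MAX_STEPS,
    Attractor,
    State,
    find_attractor,
    step,
)
from .network_io import (
    ConstantRule,
    NCFRule,
    NegatedRule,
    POSITIVE,
    NEGATIVE,
    Rule,
    RuleSet,
    SignedNetwork,
    canalyzed_prob_one,
    negate_rule,
)

__all__ = [
    "NODE_KINDS",
    "EDGE_KINDS",
    "PREDEFINED_KINDS",
    "PERMANENT",
    "MutationSpec",
    "MutantModel",
    "MutationError",
    "apply_mutation",
    "mutant_trajectory",
    "register_plugin",
    "unregister_plugin",
    "load_plugin_file",
]

NODE_KINDS = frozenset(
    {"state-flip", "knockout", "overexpression", "rule-flip", "outcome-shuffle"}
)
EDGE_KINDS = frozenset(
    {"edge-removal", "edge-addition", "edge-attenuation", "edge-sign-switch",
     "edge-reverse"}
)
PREDEFINED_KINDS = NODE_KINDS | EDGE_KINDS

PERMANENT = "permanent"

Edge = tuple[str, str]


class MutationError(ValueError):
    """Invalid mutation spec or target."""


@dataclass(frozen=True)
class MutationSpec:
    """One mutation to simulate: operator, group, duration, parameters.

    ``group`` members are node ids (str) for node-based operators and
    ``(source, target)`` pairs for edgetic ones.  ``duration`` is an integer
    >= 1 or ``"permanent"``.  ``params`` carries operator-specific options:
    ``sign`` / ``io`` / ``theta`` for edge-addition, ``permutation`` for
    outcome-shuffle.  ``seed`` feeds the spec's private randomness substream
    (outcome-shuffle permutations, edge-addition term sampling), which is
    drawn once per ``apply_mutation`` call so a mutant model is fixed across
    the whole initial-state ensemble.
    """

    kind: str
    group: tuple[str | Edge, ...]
    duration: int | str = PERMANENT
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", tuple(
            tuple(g) if isinstance(g, (tuple, list)) else g for g in self.group
        ))
        if self.duration != PERMANENT:
            if not isinstance(self.duration, (int, np.integer)) or self.duration < 1:
                raise MutationError(
                    f"duration must be an integer >= 1 or {PERMANENT!r}, "
                    f"got {self.duration!r}"
                )
            object.__setattr__(self, "duration", int(self.duration))

    @property
    def is_permanent(self) -> bool:
        return self.duration == PERMANENT

    @property
    def tau(self) -> int:
        if self.is_permanent:
            raise MutationError("permanent mutation has no finite duration")
        return int(self.duration)


@dataclass(frozen=True)
class MutantModel:
    """Mutated (G', F') plus the untouched wild-type (G, F)."""

    network: SignedNetwork
    rules: RuleSet
    wild_network: SignedNetwork
    wild_rules: RuleSet
    spec: MutationSpec


# ---------------------------------------------------------------------------
# plugin registry

NodeTransform = Callable[[Rule, SignedNetwork, np.random.Generator], Rule]
EdgeTransform = Callable[[Rule, Edge, SignedNetwork, np.random.Generator], Rule]


@dataclass(frozen=True)
class _Plugin:
    name: str
    node_transform: NodeTransform | None
    edge_transform: EdgeTransform | None


_PLUGINS: dict[str, _Plugin] = {}


def register_plugin(
    name: str,
    node_transform: NodeTransform | None = None,
    edge_transform: EdgeTransform | None = None,
) -> None:
    """Register a user-defined mutation operator under ``name``.

    At least one transform must be supplied.  A node transform maps
    ``(rule, network, rng) -> rule``; an edge transform maps
    ``(rule, edge, network, rng) -> rule``.  Transforms must be pure (the
    rule objects are immutable; returned rules are validated against the
    mutant topology).
    """
    if node_transform is None and edge_transform is None:
        raise MutationError("plugin needs a node transform and/or an edge transform")
    if name in PREDEFINED_KINDS:
        raise MutationError(f"plugin name {name!r} collides with a predefined kind")
    if name in _PLUGINS:
        raise MutationError(f"plugin {name!r} is already registered")
    _PLUGINS[name] = _Plugin(name, node_transform, edge_transform)


def unregister_plugin(name: str) -> None:
    _PLUGINS.pop(name, None)


def load_plugin_file(path) -> str:
    """Load a plugin script exposing ``node_transform`` and/or
    ``edge_transform`` (and optionally ``MUTATION_NAME``); returns the
    registered name (default: the file stem)."""
    path = Path(path)
    spec = importlib.util.spec_from_file_location(f"boolmut_plugin_{path.stem}", path)
    if spec is None or spec.loader is None:
        raise MutationError(f"cannot load plugin file {path}")
    module = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(module)
    name = getattr(module, "MUTATION_NAME", path.stem)
    register_plugin(
        name,
        node_transform=getattr(module, "node_transform", None),
        edge_transform=getattr(module, "edge_transform", None),
    )
    return name


# ---------------------------------------------------------------------------
# predefined transformations


def _as_ncf(rule: Rule, kind: str) -> NCFRule:
    if not isinstance(rule, NCFRule):
        raise MutationError(
            f"{kind} requires an NCF rule, got {type(rule).__name__} "
            f"for {rule.target!r}"
        )
    return rule


def _flip_rule(rule: NCFRule) -> NCFRule:
    """Flip every canalyzing and canalyzed value; the default is flipped too,
    preserving the ``default = 1 - O_d`` convention."""
    terms = tuple((u, 1 - i, 1 - o) for u, i, o in rule.terms)
    return NCFRule(rule.target, terms, 1 - rule.default_output)


def _shuffle_outcomes(rule: NCFRule, perm: Sequence[int]) -> NCFRule:
    if sorted(perm) != list(range(rule.depth)):
        raise MutationError(
            f"permutation {tuple(perm)} is not a permutation of "
            f"0..{rule.depth - 1}"
        )
    outs = [o for _, _, o in rule.terms]
    terms = tuple(
        (u, i, outs[perm[k]]) for k, (u, i, _) in enumerate(rule.terms)
    )
    return NCFRule(rule.target, terms, rule.default_output)


def _term_index(rule: NCFRule, source: str, edge: Edge) -> int:
    for j, (u, _, _) in enumerate(rule.terms):
        if u == source:
            return j
    raise MutationError(f"rule for {edge[1]!r} has no term for input {source!r}")


def apply_mutation(
    network: SignedNetwork, rules: RuleSet, spec: MutationSpec
) -> MutantModel:
    """Build the mutant model (G', F') for ``spec``; pure transformation.

    Every group member is mutated simultaneously.  Kind-specific semantics:

    - state-flip: f' = 1 - f (output negated at every step while in force)
    - knockout / overexpression: f' pinned to 0 / 1
    - rule-flip: every I_k, O_k (and the default) flipped
    - outcome-shuffle: canalyzed values permuted uniformly at random, sampled
      once per call from the spec's seed substream
    - edge-removal: edge deleted; its term deleted from the target's rule
    - edge-addition: a non-existent edge added; a term sampled at position
      k=1 from the random-rule distribution is inserted at the front
    - edge-attenuation: the edge's term swapped with the last (lowest
      precedence) term; a no-op when it already is last
    - edge-sign-switch: I_j -> 1 - I_j (edge sign flipped in G')
    - edge-reverse: O_j -> 1 - O_j (edge sign flipped in G')
    """
    kind = spec.kind
    rng = substream(spec.seed, STREAM_MUTATION)
    edges = list(network.edges)
    current: dict[str, Rule] = {
        n: r for n, r in zip(network.nodes, rules.rules)
    }
    node_set = set(network.nodes)

    plugin = _PLUGINS.get(kind)
    if plugin is None and kind not in PREDEFINED_KINDS:
        raise MutationError(f"unknown mutation kind {kind!r}")

    for target in spec.group:
        is_edge = isinstance(target, tuple)
        if kind in NODE_KINDS or (plugin is not None and not is_edge):
            if is_edge:
                raise MutationError(f"node-based kind {kind!r} given edge {target!r}")
            node = target
            if node not in node_set:
                raise MutationError(f"unknown node {node!r}")
            rule = current[node]
            if plugin is not None:
                if plugin.node_transform is None:
                    raise MutationError(
                        f"plugin {kind!r} has no node transform for {node!r}"
                    )
                current[node] = plugin.node_transform(rule, network, rng)
            elif kind == "state-flip":
                current[node] = negate_rule(rule)
            elif kind == "knockout":
                current[node] = ConstantRule(node, 0)
            elif kind == "overexpression":
                current[node] = ConstantRule(node, 1)
            elif kind == "rule-flip":
                current[node] = _flip_rule(_as_ncf(rule, kind))
            elif kind == "outcome-shuffle":
                ncf = _as_ncf(rule, kind)
                perm = spec.params.get("permutation")
                if perm is None:
                    perm = rng.permutation(ncf.depth)
                current[node] = _shuffle_outcomes(ncf, [int(p) for p in perm])
        else:
            if not is_edge:
                raise MutationError(f"edgetic kind {kind!r} given node {target!r}")
            source, tnode = target
            if source not in node_set or tnode not in node_set:
                raise MutationError(f"edge {target!r} references unknown node")
            if plugin is not None:
                if plugin.edge_transform is None:
                    raise MutationError(
                        f"plugin {kind!r} has no edge transform for {target!r}"
                    )
                current[tnode] = plugin.edge_transform(
                    current[tnode], (source, tnode), network, rng
                )
                continue
            exists = any(s == source and t == tnode for s, t, _ in edges)
            if kind == "edge-addition":
                if exists:
                    raise MutationError(
                        f"edge-addition target ({source},{tnode}) already exists"
                    )
                ncf = _as_ncf(current[tnode], kind)
                io = spec.params.get("io")
                if io is None:
                    theta = float(spec.params.get("theta", 7.0))
                    o = int(rng.random() < canalyzed_prob_one(1, theta))
                    i = int(rng.random() < 0.5)
                else:
                    i, o = int(io[0]), int(io[1])
                sign = spec.params.get("sign")
                if sign is None:
                    sign = POSITIVE if i == o else NEGATIVE
                edges.append((source, tnode, int(sign)))
                current[tnode] = NCFRule(
                    tnode, ((source, i, o),) + ncf.terms, ncf.default_output
                )
                continue
            if not exists:
                raise MutationError(f"edge ({source},{tnode}) does not exist")
            ncf = _as_ncf(current[tnode], kind)
            j = _term_index(ncf, source, target)
            terms = list(ncf.terms)
            if kind == "edge-removal":
                del terms[j]
                edges[:] = [e for e in edges if not (e[0] == source and e[1] == tnode)]
                current[tnode] = NCFRule(tnode, tuple(terms), ncf.default_output)
            elif kind == "edge-attenuation":
                terms[j], terms[-1] = terms[-1], terms[j]
                current[tnode] = NCFRule(tnode, tuple(terms), ncf.default_output)
            elif kind in ("edge-sign-switch", "edge-reverse"):
                u, i, o = terms[j]
                terms[j] = (u, 1 - i, o) if kind == "edge-sign-switch" else (u, i, 1 - o)
                edges[:] = [
                    (s, t, -sg) if (s == source and t == tnode) else (s, t, sg)
                    for s, t, sg in edges
                ]
                current[tnode] = NCFRule(tnode, tuple(terms), ncf.default_output)

    mutant_network = SignedNetwork(network.nodes, tuple(edges))
    mutant_rules = RuleSet(
        mutant_network,
        tuple(current[n] for n in network.nodes),
        provenance="mutant",
        seed=spec.seed,
        theta=rules.theta,
    )
    return MutantModel(mutant_network, mutant_rules, network, rules, spec)


def mutant_trajectory(
    network: SignedNetwork,
    rules: RuleSet,
    spec: MutationSpec,
    initial_state: Sequence[int],
    max_steps: int = DEFAULT_MAX_STEPS,
) -> Attractor:
    """Attractor of the mutated trajectory from ``initial_state``.

    States v(1)..v(tau_m) evolve under the mutant model; from there the
    wild-type rules govern and the attractor is detected on the
    post-reversion dynamics.  The reported transient is measured on the
    composite timeline (tau_m + post-reversion transient).  For a permanent
    mutation the attractor is detected wholly under the mutant model.
    """
    model = apply_mutation(network, rules, spec)
    if spec.is_permanent:
        return find_attractor(model.network, model.rules, initial_state, max_steps)
    state: State = tuple(int(b) for b in initial_state)
    for _ in range(spec.tau):
        state = step(model.network, model.rules, state)
    attr = find_attractor(network, rules, state, max_steps)
    return Attractor(attr.transient + spec.tau, attr.period, attr.states)
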