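"""Signed interaction networks, nested-canalyzing rules, and their file formats.

A network is a directed graph ``G(V, E)`` whose edges carry an activation
(+1) or inhibition (-1) sign.  Each node's update rule is a nested
canalyzing function (NCF): an ordered sequence of (input, canalyzing value
``I_k``, canalyzed value ``O_k``) terms followed by a default output.  The
first term whose input matches its canalyzing value fixes the node's next
state; if none matches the default applies.

The module also provides the random generators used throughout the package:
Erdos-Renyi-style signed digraphs and random NCF rule sets in which
``Pr(I_k = 1) = 1/2`` and ``Pr(O_k = 1) = sigma(-theta * 2**-k)`` with the
logistic function ``sigma`` — so low-precedence positions are strongly
biased toward output 0 at the conventional ``theta = 7``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._random import STREAM_NETWORK, STREAM_RULES, substream

__all__ = [
    "SignedNetwork",
    "NCFRule",
    "ConstantRule",
    "NegatedRule",
    "RuleSet",
    "NetworkFormatError",
    "RuleFormatError",
    "read_network",
    "write_network",
    "parse_rules",
    "write_rules",
    "generate_random_rules",
    "generate_random_network",
]

POSITIVE = 1
NEGATIVE = -1

_SIGN_TOKENS = {
    "+": POSITIVE,
    "1": POSITIVE,
    "activates": POSITIVE,
    "-": NEGATIVE,
    "-1": NEGATIVE,
    "inhibits": NEGATIVE,
}
_SIGN_CHAR = {POSITIVE: "+", NEGATIVE: "-"}


class NetworkFormatError(ValueError):
    """Raised for malformed or inconsistent network files."""


class RuleFormatError(ValueError):
    """Raised for malformed or topology-inconsistent rule files."""


@dataclass(frozen=True)
class SignedNetwork:
    """Directed graph with signed edges.

    ``nodes`` is an ordered tuple of unique identifiers; ``edges`` an ordered
    tuple of ``(source, target, sign)`` with sign in {+1, -1}.  Self-loops
    are permitted; parallel edges on the same ordered pair are not.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, int], ...]

    def __post_init__(self) -> None:
        if len(self.nodes) < 1:
            raise NetworkFormatError("a network needs at least one node")
        if len(set(self.nodes)) != len(self.nodes):
            raise NetworkFormatError("duplicate node identifiers")
        node_set = set(self.nodes)
        seen: set[tuple[str, str]] = set()
        for s, t, sign in self.edges:
            if s not in node_set or t not in node_set:
                raise NetworkFormatError(f"edge ({s},{t}) references unknown node")
            if sign not in (POSITIVE, NEGATIVE):
                raise NetworkFormatError(f"edge ({s},{t}) has invalid sign {sign!r}")
            if (s, t) in seen:
                raise NetworkFormatError(f"duplicate edge ({s},{t})")
            seen.add((s, t))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def _index_map(self) -> dict[str, int]:
        m = self.__dict__.get("_index_cache")
        if m is None:
            m = {n: i for i, n in enumerate(self.nodes)}
            object.__setattr__(self, "_index_cache", m)
        return m

    def _in_map(self) -> dict[str, tuple[tuple[str, str, int], ...]]:
        m = self.__dict__.get("_in_cache")
        if m is None:
            acc: dict[str, list] = {n: [] for n in self.nodes}
            for e in self.edges:
                acc[e[1]].append(e)
            m = {n: tuple(es) for n, es in acc.items()}
            object.__setattr__(self, "_in_cache", m)
        return m

    def index(self, node: str) -> int:
        try:
            return self._index_map()[node]
        except KeyError:
            raise KeyError(f"unknown node {node!r}") from None

    def has_edge(self, source: str, target: str) -> bool:
        return any(s == source for s, _, _ in self._in_map().get(target, ()))

    def edge_sign(self, source: str, target: str) -> int:
        for s, _, sign in self._in_map().get(target, ()):
            if s == source:
                return sign
        raise KeyError(f"no edge ({source},{target})")

    def in_edges(self, target: str) -> tuple[tuple[str, str, int], ...]:
        return self._in_map()[target]

    def incident_edges(self, node: str) -> tuple[tuple[str, str], ...]:
        """Edges touching ``node`` as source or target (used for
        edgetic mutation-susceptibility)."""
        return tuple((s, t) for s, t, _ in self.edges if s == node or t == node)


@dataclass(frozen=True)
class NCFRule:
    """Nested canalyzing update rule for one node.

    ``terms`` is the ordered sequence of ``(input node, I_k, O_k)``; order
    encodes update precedence (the first matching term wins).  A zero-term
    rule denotes a zero in-degree node, which holds its current state.
    """

    target: str
    terms: tuple[tuple[str, int, int], ...]
    default_output: int

    def __post_init__(self) -> None:
        inputs = [u for u, _, _ in self.terms]
        if len(set(inputs)) != len(inputs):
            raise RuleFormatError(f"rule for {self.target!r}: duplicate inputs")
        for u, i, o in self.terms:
            if i not in (0, 1) or o not in (0, 1):
                raise RuleFormatError(
                    f"rule for {self.target!r}: I/O values must be 0 or 1"
                )
        if self.default_output not in (0, 1):
            raise RuleFormatError(f"rule for {self.target!r}: default must be 0 or 1")

    @property
    def depth(self) -> int:
        return len(self.terms)

    @property
    def inputs(self) -> tuple[str, ...]:
        return tuple(u for u, _, _ in self.terms)


@dataclass(frozen=True)
class ConstantRule:
    """Update rule pinned to a constant (knockout: 0, overexpression: 1)."""

    target: str
    value: int

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise RuleFormatError("constant rule value must be 0 or 1")


@dataclass(frozen=True)
class NegatedRule:
    """Output-negated wrapper around an NCF rule (state-flip: f' = 1 - f)."""

    base: NCFRule

    @property
    def target(self) -> str:
        return self.base.target


Rule = NCFRule | ConstantRule | NegatedRule


def negate_rule(rule: Rule) -> Rule:
    """Return the rule computing ``1 - f``; double negation is the identity."""
    if isinstance(rule, NegatedRule):
        return rule.base
    if isinstance(rule, ConstantRule):
        return ConstantRule(rule.target, 1 - rule.value)
    return NegatedRule(rule)


@dataclass(frozen=True)
class RuleSet:
    """One update rule per node, aligned with a network's node order."""

    network: SignedNetwork
    rules: tuple[Rule, ...]
    provenance: str = "user-defined"
    seed: int | None = None
    theta: float | None = None
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        if len(self.rules) != self.network.n_nodes:
            raise RuleFormatError(
                f"expected {self.network.n_nodes} rules, got {len(self.rules)}"
            )
        for node, rule in zip(self.network.nodes, self.rules):
            if rule.target != node:
                raise RuleFormatError(
                    f"rule order mismatch: expected {node!r}, got {rule.target!r}"
                )
        if self.validate:
            for node, rule in zip(self.network.nodes, self.rules):
                base = rule.base if isinstance(rule, NegatedRule) else rule
                if isinstance(base, NCFRule):
                    expected = {s for s, _, _ in self.network.in_edges(node)}
                    got = set(base.inputs)
                    if got - expected:
                        raise RuleFormatError(
                            f"rule for {node!r} references non-edge input(s) "
                            f"{sorted(got - expected)}"
                        )
                    if expected - got:
                        raise RuleFormatError(
                            f"rule for {node!r}: incomplete input set, missing "
                            f"{sorted(expected - got)}"
                        )

    def rule_for(self, node: str) -> Rule:
        return self.rules[self.network.index(node)]

    def replace(self, network: SignedNetwork, updates: dict[str, Rule],
                validate: bool = True) -> "RuleSet":
        """A copy bound to ``network`` with some nodes' rules replaced."""
        new = tuple(updates.get(n, r) for n, r in zip(self.network.nodes, self.rules))
        return RuleSet(network, new, provenance="mutant", seed=self.seed,
                       theta=self.theta, validate=validate)


# ---------------------------------------------------------------------------
# file formats


def read_network(path, dialect: str = "source_sign_target") -> SignedNetwork:
    """Read a whitespace/tab-delimited signed edge list.

    Default dialect is ``source sign target`` (SIF-compatible: the sign
    field accepts ``+ - 1 -1 activates inhibits``); ``source_target_sign``
    puts the sign last.  Lines starting with ``#`` are comments.  Duplicate
    identical edges are collapsed with a warning; duplicates that disagree
    on sign are an error.
    """
    if dialect not in ("source_sign_target", "source_target_sign"):
        raise ValueError(f"unknown dialect {dialect!r}")
    nodes: list[str] = []
    node_seen: set[str] = set()
    edges: dict[tuple[str, str], int] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("# nodes:"):
                # optional header fixing node order (written by write_network)
                for n in line[len("# nodes:"):].split():
                    if n not in node_seen:
                        node_seen.add(n)
                        nodes.append(n)
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 3:
                raise NetworkFormatError(
                    f"{path}: line {lineno}: expected 3 fields, got {len(fields)}"
                )
            if dialect == "source_sign_target":
                source, sign_tok, target = fields
            else:
                source, target, sign_tok = fields
            sign = _SIGN_TOKENS.get(sign_tok.lower())
            if sign is None:
                raise NetworkFormatError(
                    f"{path}: line {lineno}: invalid sign token {sign_tok!r}"
                )
            for n in (source, target):
                if n not in node_seen:
                    node_seen.add(n)
                    nodes.append(n)
            key = (source, target)
            if key in edges:
                if edges[key] != sign:
                    raise NetworkFormatError(
                        f"{path}: line {lineno}: conflicting sign for edge "
                        f"({source},{target})"
                    )
                warnings.warn(
                    f"{path}: line {lineno}: duplicate edge ({source},{target}) collapsed"
                )
                continue
            edges[key] = sign
    if not edges:
        raise NetworkFormatError(f"{path}: no edges")
    return SignedNetwork(
        tuple(nodes), tuple((s, t, sg) for (s, t), sg in edges.items())
    )


def write_network(network: SignedNetwork, path) -> None:
    """Write ``source sign target`` lines; round-trips through read_network.

    A ``# nodes:`` header pins the node order (read back by read_network,
    ignored by other SIF consumers).  The format is an edge list, so an
    edgeless network is rejected (use the rules file to carry node lists).
    """
    if network.n_edges == 0:
        raise NetworkFormatError(
            "cannot write a network with no edges (format has no isolated-node "
            "representation); write the rule set instead"
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# nodes: {' '.join(network.nodes)}\n")
        for s, t, sign in network.edges:
            fh.write(f"{s}\t{_SIGN_CHAR[sign]}\t{t}\n")


def _parse_rule_line(line: str, lineno: int, path) -> NCFRule:
    if "=" not in line:
        raise RuleFormatError(f"{path}: line {lineno}: missing '='")
    node, _, body = line.partition("=")
    node = node.strip()
    if not node:
        raise RuleFormatError(f"{path}: line {lineno}: empty node name")
    terms: list[tuple[str, int, int]] = []
    default: int | None = None
    for part in (p.strip() for p in body.split(";")):
        if not part:
            continue
        if part.startswith("default"):
            _, _, val = part.partition("=")
            try:
                default = int(val.strip())
            except ValueError:
                raise RuleFormatError(
                    f"{path}: line {lineno}: bad default {val.strip()!r}"
                ) from None
        elif part.startswith("(") and part.endswith(")"):
            pieces = [q.strip() for q in part[1:-1].split(",")]
            if len(pieces) != 3:
                raise RuleFormatError(
                    f"{path}: line {lineno}: term must be (input,I,O): {part!r}"
                )
            u, i_s, o_s = pieces
            try:
                i, o = int(i_s), int(o_s)
            except ValueError:
                raise RuleFormatError(
                    f"{path}: line {lineno}: non-integer I/O in {part!r}"
                ) from None
            terms.append((u, i, o))
        else:
            raise RuleFormatError(f"{path}: line {lineno}: unrecognized token {part!r}")
    if default is None:
        raise RuleFormatError(f"{path}: line {lineno}: missing default")
    try:
        return NCFRule(node, tuple(terms), default)
    except RuleFormatError as exc:
        raise RuleFormatError(f"{path}: line {lineno}: {exc}") from None


def parse_rules(path, network: SignedNetwork) -> RuleSet:
    """Parse one rule line per node: ``v = (u,I,O);(u,I,O);...;default=O``.

    Rules are validated against the network: the inputs of each rule must be
    exactly the sources of the node's incoming edges, in any order (the file
    order is the update precedence).
    """
    parsed: dict[str, NCFRule] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            rule = _parse_rule_line(line, lineno, path)
            if rule.target not in set(network.nodes):
                raise RuleFormatError(
                    f"{path}: line {lineno}: unknown node {rule.target!r}"
                )
            if rule.target in parsed:
                raise RuleFormatError(
                    f"{path}: line {lineno}: duplicate rule for {rule.target!r}"
                )
            parsed[rule.target] = rule
    missing = [n for n in network.nodes if n not in parsed]
    if missing:
        raise RuleFormatError(f"{path}: missing rule(s) for node(s) {missing}")
    return RuleSet(network, tuple(parsed[n] for n in network.nodes),
                   provenance="user-defined")


def write_rules(ruleset: RuleSet, path) -> None:
    """Write the rule file (network node order); inverse of parse_rules."""
    with open(path, "w", encoding="utf-8") as fh:
        for rule in ruleset.rules:
            if not isinstance(rule, NCFRule):
                raise RuleFormatError(
                    f"only NCF rules are writable, got {type(rule).__name__} "
                    f"for {rule.target!r}"
                )
            parts = [f"({u},{i},{o})" for u, i, o in rule.terms]
            parts.append(f"default={rule.default_output}")
            fh.write(f"{rule.target} = {';'.join(parts)}\n")


# ---------------------------------------------------------------------------
# random generation


def canalyzed_prob_one(k: int, theta: float) -> float:
    """Pr(O_k = 1) = sigma(-theta * 2**-k) for 1-based position k."""
    x = -theta * 2.0 ** (-k)
    return 1.0 / (1.0 + math.exp(-x))


def generate_random_rules(
    network: SignedNetwork,
    theta: float = 7.0,
    seed: int | None = None,
    sign_mode: str = "independent",
    rng: np.random.Generator | None = None,
) -> RuleSet:
    """Sample a random NCF rule set for ``network``.

    Per node, term order is a uniformly random permutation of its incoming
    edges; ``I_k ~ Bernoulli(1/2)`` and ``O_k ~ Bernoulli(sigma(-theta *
    2**-k))`` with k the 1-based position; ``default = 1 - O_d``.  In
    ``sign_mode="sign-constrained"`` the sampled ``O_k`` is kept and ``I_k``
    is forced so that ``I_k == O_k`` exactly for positive edges (an input at
    its canalyzing value then drives the output the same way the edge sign
    says).  The default mode samples both independently.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if sign_mode not in ("independent", "sign-constrained"):
        raise ValueError(f"unknown sign_mode {sign_mode!r}")
    if rng is None:
        rng = substream(seed, STREAM_RULES)
    rules: list[NCFRule] = []
    for node in network.nodes:
        in_edges = network.in_edges(node)
        order = rng.permutation(len(in_edges))
        terms: list[tuple[str, int, int]] = []
        for pos, j in enumerate(order, start=1):
            source, _, sign = in_edges[j]
            o = int(rng.random() < canalyzed_prob_one(pos, theta))
            i = int(rng.random() < 0.5)
            if sign_mode == "sign-constrained":
                i = o if sign == POSITIVE else 1 - o
            terms.append((source, i, o))
        default = 1 - terms[-1][2] if terms else 0
        rules.append(NCFRule(node, tuple(terms), default))
    return RuleSet(network, tuple(rules), provenance="random",
                   seed=seed, theta=theta)


def generate_random_network(
    n_nodes: int,
    n_edges: int,
    positive_fraction: float = 0.5,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SignedNetwork:
    """Sample a signed digraph: ``n_edges`` distinct ordered pairs drawn
    uniformly (self-loops allowed), each positive with probability
    ``positive_fraction``."""
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if not 0 <= n_edges <= n_nodes * n_nodes:
        raise ValueError(f"n_edges must be in [0, {n_nodes * n_nodes}]")
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError("positive_fraction must be in [0, 1]")
    if rng is None:
        rng = substream(seed, STREAM_NETWORK)
    width = len(str(n_nodes))
    nodes = tuple(f"v{idx + 1:0{width}d}" for idx in range(n_nodes))
    flat = rng.choice(n_nodes * n_nodes, size=n_edges, replace=False)
    edges = []
    for code in flat:
        s, t = divmod(int(code), n_nodes)
        sign = POSITIVE if rng.random() < positive_fraction else NEGATIVE
        edges.append((nodes[s], nodes[t], sign))
    return SignedNetwork(nodes, tuple(edges))
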