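"""Attractor distances, network sensitivity lambda, and susceptibility.

The network sensitivity to a mutation is the ensemble average

    lambda = sum over v(0) in S of d(<G,F,v(0)>, <G',F',v(0)>) / |S|

over a shared sample S of initial states, where d is one of two attractor
distances:

- identicalness: 0 when the wild-type and mutant attractors are identical
  up to a cyclic rotation (same period, some time lag aligns every state),
  1 otherwise — so lambda is the fraction of initial states whose attractor
  changed;
- similarity: the minimum over time lags of the mean per-bit Hamming
  mismatch between the two cyclic state sequences, each extended by modular
  indexing over their least common period lcm(p, p').  The lag only needs to
  range over 0..gcd(p, p')-1; the windowed mismatch is periodic in the lag
  with period gcd(p, p') (property-tested against the brute-force scan).

Mutation-susceptibility scores a node: its own lambda for node-based
operators, the maximum single-edge lambda over incident edges for edgetic
ones; ``rank_auc`` turns such scores into a ranking AUC against binary
labels (e.g. drug-target flags).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gcd, lcm
from typing import Sequence

import numpy as np
from joblib import Parallel, delayed

from ._random import STREAM_MUTATION, STREAM_RULES, derive_seed, substream
from . import _engine
from .dynamics import (
    DEFAULT_MAX_STEPS,
    Attractor,
    AttractorBudgetError,
    State,
    find_attractor,
    random_initial_states,
)
from .mutations import (
    EDGE_KINDS,
    MutationError,
    MutationSpec,
    NODE_KINDS,
    apply_mutation,
    mutant_trajectory,
)
from .network_io import RuleSet, SignedNetwork, generate_random_rules

__all__ = [
    "SensitivityResult",
    "hamming",
    "distance_identicalness",
    "distance_similarity",
    "calc_sensitivity",
    "ensemble_sensitivity",
    "node_susceptibility",
    "rank_auc",
    "SensitivityEngine",
]


def hamming(a: Sequence[int], b: Sequence[int]) -> int:
    """Number of differing bits between two equal-length Boolean vectors."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return int(sum(abs(int(x) - int(y)) for x, y in zip(a, b)))


# packed-cycle implementations shared by the object API and the fast engine


def _identicalness_packed(cyc_a: Sequence[int], cyc_b: Sequence[int]) -> int:
    p, q = len(cyc_a), len(cyc_b)
    if p != q:
        return 1
    for m in range(p):
        if all(cyc_a[(l + m) % p] == cyc_b[l] for l in range(p)):
            return 0
    return 1


def _similarity_packed(
    cyc_a: Sequence[int], cyc_b: Sequence[int], n_nodes: int
) -> float:
    p, q = len(cyc_a), len(cyc_b)
    c = lcm(p, q)
    best = None
    for m in range(gcd(p, q)):
        total = 0
        for l in range(c):
            total += ((cyc_a[(l + m) % p] ^ cyc_b[l % q])).bit_count()
        if best is None or total < best:
            best = total
    return best / (c * n_nodes)


def _check_pair(a: Attractor, b: Attractor) -> None:
    if a.n_nodes != b.n_nodes:
        raise ValueError(
            f"attractors have different widths: {a.n_nodes} vs {b.n_nodes}"
        )


def distance_identicalness(a: Attractor, b: Attractor) -> int:
    """0 iff the attractors are identical up to rotation, else 1."""
    _check_pair(a, b)
    return _identicalness_packed(
        [_engine.pack_state(s) for s in a.states],
        [_engine.pack_state(s) for s in b.states],
    )


def distance_similarity(a: Attractor, b: Attractor) -> float:
    """Minimum mean per-bit mismatch over time lags, in [0, 1]."""
    _check_pair(a, b)
    return _similarity_packed(
        [_engine.pack_state(s) for s in a.states],
        [_engine.pack_state(s) for s in b.states],
        a.n_nodes,
    )


_MEASURES = ("identicalness", "similarity")


@dataclass(frozen=True)
class SensitivityResult:
    """One lambda value with the parameters that produced it."""

    target: tuple
    measure: str
    lam: float
    n_initial_states: int
    tau: int | str
    rule_set_index: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda out of [0,1]: {self.lam}")


class SensitivityEngine:
    """Caches wild-type attractors across many mutation specs.

    All sensitivity drivers (tau sweeps, susceptibility, the double-mutation
    synergy scan) evaluate many specs against one (network, rules, S)
    triple; the wild-type attractor of every initial state is computed once.
    Uses the packed numba engine when the network fits in 62 bits, the
    object-level path otherwise — the two are property-tested equivalent.
    """

    def __init__(
        self,
        network: SignedNetwork,
        rules: RuleSet,
        initial_states: Sequence[State],
        measure: str = "identicalness",
        max_steps: int = DEFAULT_MAX_STEPS,
        workers: int = 1,
    ):
        if measure not in _MEASURES:
            raise ValueError(f"measure must be one of {_MEASURES}")
        if len(initial_states) < 1:
            raise ValueError("need at least one initial state")
        self.network = network
        self.rules = rules
        self.initial_states = [tuple(int(b) for b in s) for s in initial_states]
        self.measure = measure
        self.max_steps = max_steps
        self.workers = max(1, int(workers))
        self._fast = _engine.supports(network)
        if self._fast:
            self._wt_model = _engine.compile_model(network, rules)
            self._packed = [_engine.pack_state(s) for s in self.initial_states]
            self._wt_cycles = [
                self._run_packed(self._wt_model, s, None, 0) for s in self._packed
            ]
        else:
            self._wt_attrs = [
                self._run_object(lambda st: find_attractor(
                    network, rules, st, max_steps), s)
                for s in self.initial_states
            ]

    def _run_packed(self, model, packed_state, mutant, tau):
        try:
            _, _, cycle = _engine.run_attractor(
                model, packed_state, self.max_steps, mutant=mutant, tau=tau
            )
        except AttractorBudgetError as exc:
            state = _engine.unpack_state(packed_state, self.network.n_nodes)
            raise self._budget_error(exc, state) from None
        return cycle

    @staticmethod
    def _budget_error(exc: AttractorBudgetError, state) -> AttractorBudgetError:
        err = AttractorBudgetError(exc.steps)
        err.args = (f"{exc.args[0]} (initial state {''.join(map(str, state))})",)
        return err

    def _run_object(self, fn, state):
        try:
            return fn(state)
        except AttractorBudgetError as exc:
            raise self._budget_error(exc, state) from None

    def _distances(self, spec: MutationSpec) -> list[float]:
        n = self.network.n_nodes
        if self._fast:
            model = apply_mutation(self.network, self.rules, spec)
            mut = _engine.compile_model(model.network, model.rules)
            if spec.is_permanent:
                base, mutant, tau = mut, None, 0
            else:
                base, mutant, tau = self._wt_model, mut, spec.tau

            def one(idx: int) -> float:
                cyc = self._run_packed(base, self._packed[idx], mutant, tau)
                wt = self._wt_cycles[idx]
                if self.measure == "identicalness":
                    return float(_identicalness_packed(wt, cyc))
                return _similarity_packed(wt, cyc, n)
        else:

            def one(idx: int) -> float:
                state = self.initial_states[idx]
                attr = self._run_object(
                    lambda st: mutant_trajectory(
                        self.network, self.rules, spec, st, self.max_steps
                    ),
                    state,
                )
                wt = self._wt_attrs[idx]
                if self.measure == "identicalness":
                    return float(distance_identicalness(wt, attr))
                return distance_similarity(wt, attr)

        indices = range(len(self.initial_states))
        if self.workers == 1:
            return [one(i) for i in indices]
        chunks = np.array_split(np.asarray(indices), self.workers)
        parts = Parallel(n_jobs=self.workers, backend="threading")(
            delayed(lambda ch: [one(int(i)) for i in ch])(ch) for ch in chunks
        )
        return [d for part in parts for d in part]

    def lambda_for(self, spec: MutationSpec) -> float:
        """Eq-style average distance over the cached initial-state sample."""
        d = self._distances(spec)
        return sum(d) / len(d)


def calc_sensitivity(
    network: SignedNetwork,
    rules: RuleSet,
    spec: MutationSpec,
    initial_states: Sequence[State],
    measure: str = "identicalness",
    max_steps: int = DEFAULT_MAX_STEPS,
    workers: int = 1,
) -> SensitivityResult:
    """Network sensitivity lambda for one mutation spec.

    Averages the chosen attractor distance between the wild-type and mutant
    trajectories over ``initial_states``.  Bit-identical for any ``workers``
    count (per-initial-state tasks, order-independent reduction).
    """
    eng = SensitivityEngine(network, rules, initial_states, measure, max_steps,
                            workers)
    return SensitivityResult(
        target=spec.group,
        measure=measure,
        lam=eng.lambda_for(spec),
        n_initial_states=len(initial_states),
        tau=spec.duration,
        seed=spec.seed,
    )


def ensemble_sensitivity(
    network: SignedNetwork,
    spec: MutationSpec,
    n_rule_sets: int,
    theta: float = 7.0,
    initial_states: int | Sequence[State] = 100,
    measure: str = "identicalness",
    seed: int | None = None,
    sign_mode: str = "independent",
    max_steps: int = DEFAULT_MAX_STEPS,
    workers: int = 1,
) -> tuple[float, list[float]]:
    """Mean lambda over independently generated random rule sets.

    Rule sets come from per-set substreams of ``seed``; the initial-state
    sample (an explicit list, or a count drawn once from the state
    substream) is shared across rule sets.  Returns (mean, per-set values).
    """
    if n_rule_sets < 1:
        raise ValueError("n_rule_sets must be >= 1")
    if isinstance(initial_states, int):
        initial_states = random_initial_states(network.n_nodes, initial_states, seed)
    values = []
    for i in range(n_rule_sets):
        rules = generate_random_rules(
            network, theta=theta, sign_mode=sign_mode,
            rng=substream(seed, STREAM_RULES, i),
        )
        eng = SensitivityEngine(network, rules, initial_states, measure,
                                max_steps, workers)
        values.append(eng.lambda_for(spec))
    return sum(values) / len(values), values


def average_sensitivity(
    network: SignedNetwork,
    rules: RuleSet,
    kind: str,
    initial_states: Sequence[State],
    tau: int | str,
    measure: str = "identicalness",
    max_steps: int = DEFAULT_MAX_STEPS,
    seed: int | None = None,
    workers: int = 1,
    engine: SensitivityEngine | None = None,
) -> float:
    """Mean single-mutation lambda over every node (node-based kinds) or
    every edge (edgetic kinds) of the network — the per-mutation-type
    summary used by the tau-sweep case study."""
    if engine is None:
        engine = SensitivityEngine(network, rules, initial_states, measure,
                                   max_steps, workers)
    if kind in NODE_KINDS:
        targets: list = list(network.nodes)
    elif kind in EDGE_KINDS:
        if kind == "edge-addition":
            raise MutationError(
                "edge-addition has no canonical target set (the non-existent "
                "edges are unbounded); pass explicit candidate edges through "
                "calc_sensitivity instead"
            )
        targets = [(s, t) for s, t, _ in network.edges]
    else:
        raise MutationError(f"unknown mutation kind {kind!r}")
    total = 0.0
    for idx, tgt in enumerate(targets):
        spec = MutationSpec(kind, (tgt,), duration=tau,
                            seed=derive_seed(seed, STREAM_MUTATION, idx))
        total += engine.lambda_for(spec)
    return total / len(targets)


def node_susceptibility(
    network: SignedNetwork,
    rules: RuleSet,
    kind: str,
    node: str,
    tau: int | str,
    initial_states: Sequence[State],
    measure: str = "identicalness",
    max_steps: int = DEFAULT_MAX_STEPS,
    seed: int | None = None,
    engine: SensitivityEngine | None = None,
) -> float:
    """How susceptible the network is to a ``kind`` mutation at ``node``.

    Node-based kinds: lambda({node}).  Edgetic kinds: max lambda({e}) over
    the edges incident to the node (incoming or outgoing).
    """
    network.index(node)  # existence check
    if engine is None:
        engine = SensitivityEngine(network, rules, initial_states, measure,
                                   max_steps)
    if kind in NODE_KINDS:
        spec = MutationSpec(kind, (node,), duration=tau,
                            seed=derive_seed(seed, STREAM_MUTATION, 0))
        return engine.lambda_for(spec)
    if kind not in EDGE_KINDS:
        raise MutationError(f"unknown mutation kind {kind!r}")
    incident = network.incident_edges(node)
    if not incident:
        raise MutationError(
            f"edgetic susceptibility undefined for isolated node {node!r}"
        )
    best = 0.0
    for j, edge in enumerate(incident):
        spec = MutationSpec(kind, (edge,), duration=tau,
                            seed=derive_seed(seed, STREAM_MUTATION, j))
        best = max(best, engine.lambda_for(spec))
    return best


def rank_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability a random positive outranks a random negative (ties 1/2).

    The Mann-Whitney formulation of the ROC AUC; raises on a degenerate
    label set (all-positive or all-negative).
    """
    from sklearn.metrics import roc_auc_score

    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("scores and labels must have equal length")
    if labels.min() == labels.max():
        raise ValueError("labels must contain at least one positive and one negative")
    return float(roc_auc_score(labels, scores))
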