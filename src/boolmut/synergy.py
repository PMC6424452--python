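"""Double-mutation synergy: deviation epsilon, expectations psi, labels.

Two simultaneously removed edges act synergistically when the double-mutant
sensitivity exceeds what the two single-mutant sensitivities predict:

    epsilon(e_i, e_j) = lambda({e_i, e_j}) - psi(lambda(e_i), lambda(e_j))

with three expectation functions psi — MAX: max(x, y); ROOT: sqrt(x^2 +
y^2) (kept exactly as defined, so it may exceed 1); ADD: min(x + y, 1) —
ordered psi_MAX <= psi_ROOT <= psi_ADD on [0, 1]^2.  A pair is labelled
"Synergy" iff epsilon > beta (strict).  ``scan_double_edge_removal`` runs
the full all-pairs workflow on one (network, rules, S) triple: singles are
computed once and cached, the same rule set and initial-state sample enter
the single and double lambdas so epsilon is not confounded by sampling
noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from itertools import combinations

from ._random import STREAM_MUTATION, derive_seed
from .dynamics import DEFAULT_MAX_STEPS, State
from .mutations import MutationSpec
from .network_io import RuleSet, SignedNetwork
from .sensitivity import SensitivityEngine

__all__ = [
    "PSI_KINDS",
    "SynergyRecord",
    "SynergySummary",
    "psi",
    "synergy_deviation",
    "classify",
    "scan_double_edge_removal",
]

PSI_KINDS = ("MAX", "ROOT", "ADD")

Edge = tuple[str, str]


def psi(x: float, y: float, kind: str) -> float:
    """Expected double-mutant sensitivity from two single lambdas."""
    if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
        raise ValueError(f"psi inputs must be in [0,1], got ({x}, {y})")
    kind = kind.upper()
    if kind == "MAX":
        return max(x, y)
    if kind == "ROOT":
        return math.sqrt(x * x + y * y)
    if kind == "ADD":
        return min(x + y, 1.0)
    raise ValueError(f"unknown psi kind {kind!r}; expected one of {PSI_KINDS}")


def synergy_deviation(lam_i: float, lam_j: float, lam_ij: float, kind: str) -> float:
    """epsilon = lambda_double - psi(lambda_i, lambda_j); may be negative."""
    if not 0.0 <= lam_ij <= 1.0:
        raise ValueError(f"lambda values must be in [0,1], got {lam_ij}")
    return lam_ij - psi(lam_i, lam_j, kind)


def classify(epsilon: float, beta: float) -> str:
    """"Synergy" iff epsilon exceeds the threshold beta (strictly)."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    return "Synergy" if epsilon > beta else "No synergy"


@dataclass(frozen=True)
class SynergyRecord:
    edge_i: Edge
    edge_j: Edge
    lam_i: float
    lam_j: float
    lam_ij: float
    psi_kind: str
    epsilon: float
    beta: float
    label: str
    both_singles_nonzero: bool


@dataclass(frozen=True)
class SynergySummary:
    """Table-style summary of one scan for one psi kind."""

    psi_kind: str
    beta: float
    measure: str
    n_pairs: int
    n_synergy: int
    n_no_synergy: int
    pct_synergy: float
    pct_no_synergy: float
    n_synergy_both_nonzero: int


def scan_double_edge_removal(
    network: SignedNetwork,
    rules: RuleSet,
    initial_states: Sequence[State],
    tau: int | str,
    measure: str = "identicalness",
    psi_kind: str = "MAX",
    beta: float = 0.1,
    max_steps: int = DEFAULT_MAX_STEPS,
    workers: int = 1,
    seed: int | None = None,
    engine: SensitivityEngine | None = None,
    _singles: dict[Edge, float] | None = None,
    _doubles: dict[tuple[Edge, Edge], float] | None = None,
) -> tuple[list[SynergyRecord], SynergySummary]:
    """All-pairs double edge-removal synergy scan.

    Computes lambda(e) once per edge, lambda({e_i, e_j}) for every one of
    the M(M-1)/2 unordered pairs, and classifies each pair at threshold
    ``beta``.  Returns the records and a summary with Synergy/No-synergy
    counts and percentages plus the subcount of synergy pairs whose two
    single lambdas are both nonzero.
    """
    if network.n_edges < 2:
        raise ValueError("need at least two edges for a double-mutation scan")
    psi_kind = psi_kind.upper()
    if psi_kind not in PSI_KINDS:
        raise ValueError(f"unknown psi kind {psi_kind!r}")
    if engine is None:
        engine = SensitivityEngine(network, rules, initial_states, measure,
                                   max_steps, workers)
    edge_ids: list[Edge] = [(s, t) for s, t, _ in network.edges]

    def spec_for(group: tuple[Edge, ...], idx: int) -> MutationSpec:
        return MutationSpec("edge-removal", group, duration=tau,
                            seed=derive_seed(seed, STREAM_MUTATION, idx))

    singles = _singles if _singles is not None else {}
    for k, e in enumerate(edge_ids):
        if e not in singles:
            singles[e] = engine.lambda_for(spec_for((e,), k))

    doubles = _doubles if _doubles is not None else {}
    records: list[SynergyRecord] = []
    n_syn = n_syn_nonzero = 0
    for k, (ei, ej) in enumerate(combinations(edge_ids, 2)):
        if (ei, ej) not in doubles:
            doubles[ei, ej] = engine.lambda_for(
                spec_for((ei, ej), network.n_edges + k)
            )
        lam_ij = doubles[ei, ej]
        eps = synergy_deviation(singles[ei], singles[ej], lam_ij, psi_kind)
        label = classify(eps, beta)
        nonzero = singles[ei] > 0 and singles[ej] > 0
        if label == "Synergy":
            n_syn += 1
            n_syn_nonzero += int(nonzero)
        records.append(SynergyRecord(ei, ej, singles[ei], singles[ej], lam_ij,
                                     psi_kind, eps, beta, label, nonzero))
    n_pairs = len(records)
    summary = SynergySummary(
        psi_kind=psi_kind,
        beta=beta,
        measure=measure,
        n_pairs=n_pairs,
        n_synergy=n_syn,
        n_no_synergy=n_pairs - n_syn,
        pct_synergy=100.0 * n_syn / n_pairs,
        pct_no_synergy=100.0 * (n_pairs - n_syn) / n_pairs,
        n_synergy_both_nonzero=n_syn_nonzero,
    )
    return records, summary
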