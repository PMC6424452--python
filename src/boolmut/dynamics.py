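"""Synchronous Boolean dynamics: rule evaluation, stepping, attractors.

A network state is a bit vector aligned to the network's node order.  All
nodes update simultaneously; a deterministic trajectory therefore ends in a
fixed point (period 1) or a limit cycle.  ``find_attractor`` records each
visited state with its first-visit time and returns, on the first revisit,
the minimal transient length, the period, and the cyclic state list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from ._random import STREAM_STATES, substream
from .network_io import ConstantRule, NCFRule, NegatedRule, Rule, RuleSet, SignedNetwork

__all__ = [
    "Attractor",
    "AttractorBudgetError",
    "evaluate_rule",
    "step",
    "find_attractor",
    "random_initial_states",
]

State = tuple[int, ...]

DEFAULT_MAX_STEPS = 10_000

# enumerating all 2**N states is only attempted below this node count
_EXHAUSTIVE_LIMIT = 24


class AttractorBudgetError(RuntimeError):
    """No state revisit occurred within the step budget."""

    def __init__(self, steps: int):
        super().__init__(f"no attractor found within {steps} steps")
        self.steps = steps


@dataclass(frozen=True)
class Attractor:
    """A trajectory's terminal cycle.

    ``transient`` is the number of steps before the cycle is entered (the
    smallest t with v(t) = v(t+p)); ``states`` holds the p pairwise-distinct
    cycle states in visit order, anchored at the first-visited cycle state.
    Distances between attractors are rotation-invariant, so the anchor is an
    internal convention only.
    """

    transient: int
    period: int
    states: tuple[State, ...]

    def __post_init__(self) -> None:
        if self.period != len(self.states) or self.period < 1:
            raise ValueError("period must equal the number of cycle states (>= 1)")

    @property
    def n_nodes(self) -> int:
        return len(self.states[0])


def evaluate_rule(rule: Rule, state: Sequence[int], network: SignedNetwork) -> int:
    """Next value of ``rule.target`` given the current network state.

    For an NCF rule this is the canalyzed value ``O_k`` of the first term
    whose input sits at its canalyzing value ``I_k``, else the default; a
    zero-term rule returns the node's own current value (zero in-degree
    nodes hold their state).
    """
    if isinstance(rule, ConstantRule):
        return rule.value
    if isinstance(rule, NegatedRule):
        return 1 - evaluate_rule(rule.base, state, network)
    if not rule.terms:
        return int(state[network.index(rule.target)])
    for u, i, o in rule.terms:
        if int(state[network.index(u)]) == i:
            return o
    return rule.default_output


def step(network: SignedNetwork, rules: RuleSet, state: Sequence[int]) -> State:
    """One synchronous update: every node evaluated on the pre-step state."""
    return tuple(evaluate_rule(r, state, network) for r in rules.rules)


def find_attractor(
    network: SignedNetwork,
    rules: RuleSet,
    initial_state: Sequence[int],
    max_steps: int = DEFAULT_MAX_STEPS,
) -> Attractor:
    """Iterate from ``initial_state`` until a state repeats.

    Raises :class:`AttractorBudgetError` if no revisit occurs within
    ``max_steps`` steps (the revisit is guaranteed within 2**N).
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    state = tuple(int(b) for b in initial_state)
    if len(state) != network.n_nodes or any(b not in (0, 1) for b in state):
        raise ValueError("initial_state must be a 0/1 vector of length N")
    first_seen: dict[State, int] = {state: 0}
    trajectory: list[State] = [state]
    for t in range(1, max_steps + 1):
        state = step(network, rules, state)
        t0 = first_seen.get(state)
        if t0 is not None:
            return Attractor(t0, t - t0, tuple(trajectory[t0:t]))
        first_seen[state] = t
        trajectory.append(state)
    raise AttractorBudgetError(max_steps)


def random_initial_states(
    n_nodes: int,
    count: int,
    seed: int | None = None,
) -> list[State]:
    """Sample ``count`` distinct states uniformly from {0,1}**N.

    If ``count >= 2**N`` (and N is small enough to enumerate) all states are
    returned exactly once, in ascending integer order, making small-network
    ensembles deterministic and fully averaged.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = substream(seed, STREAM_STATES)

    def unpack(code: int) -> State:
        return tuple((code >> i) & 1 for i in range(n_nodes))

    if n_nodes <= _EXHAUSTIVE_LIMIT and count >= 2**n_nodes:
        return [unpack(c) for c in range(2**n_nodes)]
    if n_nodes <= 62:
        chosen: list[int] = []
        seen: set[int] = set()
        while len(chosen) < count:
            draw = rng.integers(0, 2**n_nodes, size=count - len(chosen))
            for code in draw:
                code = int(code)
                if code not in seen:
                    seen.add(code)
                    chosen.append(code)
        return [unpack(c) for c in chosen]
    # wide networks: sample bit matrices, deduplicate byte-wise
    chosen_states: list[State] = []
    seen_keys: set[bytes] = set()
    while len(chosen_states) < count:
        block = rng.integers(0, 2, size=(count - len(chosen_states), n_nodes),
                             dtype="uint8")
        for row in block:
            key = row.tobytes()
            if key not in seen_keys:
                seen_keys.add(key)
                chosen_states.append(tuple(int(b) for b in row))
    return chosen_states
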