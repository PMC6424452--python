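"""Packed-bitmask simulation engine (internal).

States of networks with at most 62 nodes are packed into a single int64
(bit i = node i, in network node order) and stepped by numba-compiled
kernels.  The engine mirrors the object-level semantics of
:mod:`boolmut.dynamics` exactly — the equivalence is property-tested — and
exists purely for throughput in the ensemble drivers, which run millions of
trajectories.  Larger networks fall back to the object path automatically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .dynamics import Attractor, AttractorBudgetError
from .network_io import ConstantRule, NCFRule, NegatedRule, RuleSet, SignedNetwork

MAX_PACKED_NODES = 62

_MODE_NCF = 0
_MODE_CONST0 = 1
_MODE_CONST1 = 2
_MODE_NEGATED = 3


@dataclass(frozen=True)
class CompiledModel:
    """Array form of one (network, rules) model for the kernels."""

    n_nodes: int
    inputs: np.ndarray   # (N, Dmax) int64, input node index, -1 padding
    ivals: np.ndarray    # (N, Dmax) int64, canalyzing values
    ovals: np.ndarray    # (N, Dmax) int64, canalyzed values
    depth: np.ndarray    # (N,) int64
    default: np.ndarray  # (N,) int64
    mode: np.ndarray     # (N,) int64


def supports(network: SignedNetwork) -> bool:
    return network.n_nodes <= MAX_PACKED_NODES


def pack_state(state: Sequence[int]) -> int:
    code = 0
    for i, b in enumerate(state):
        code |= int(b) << i
    return code


def unpack_state(code: int, n_nodes: int) -> tuple[int, ...]:
    return tuple((code >> i) & 1 for i in range(n_nodes))


def compile_model(network: SignedNetwork, rules: RuleSet) -> CompiledModel:
    n = network.n_nodes
    if n > MAX_PACKED_NODES:
        raise ValueError(f"packed engine supports at most {MAX_PACKED_NODES} nodes")
    index = {node: i for i, node in enumerate(network.nodes)}
    depths = []
    for rule in rules.rules:
        base = rule.base if isinstance(rule, NegatedRule) else rule
        depths.append(base.depth if isinstance(base, NCFRule) else 0)
    dmax = max(1, max(depths, default=0))
    inputs = np.full((n, dmax), -1, dtype=np.int64)
    ivals = np.zeros((n, dmax), dtype=np.int64)
    ovals = np.zeros((n, dmax), dtype=np.int64)
    depth = np.zeros(n, dtype=np.int64)
    default = np.zeros(n, dtype=np.int64)
    mode = np.zeros(n, dtype=np.int64)
    for i, rule in enumerate(rules.rules):
        if isinstance(rule, ConstantRule):
            mode[i] = _MODE_CONST0 if rule.value == 0 else _MODE_CONST1
            continue
        if isinstance(rule, NegatedRule):
            mode[i] = _MODE_NEGATED
            rule = rule.base
        depth[i] = rule.depth
        default[i] = rule.default_output
        for k, (u, iv, ov) in enumerate(rule.terms):
            inputs[i, k] = index[u]
            ivals[i, k] = iv
            ovals[i, k] = ov
    return CompiledModel(n, inputs, ivals, ovals, depth, default, mode)


@njit(cache=False, nogil=True)
def _step_bits(state, n, inputs, ivals, ovals, depth, default, mode):
    new = np.int64(0)
    for i in range(n):
        m = mode[i]
        if m == 1:
            bit = np.int64(0)
        elif m == 2:
            bit = np.int64(1)
        else:
            d = depth[i]
            if d == 0:
                bit = (state >> i) & 1
            else:
                bit = default[i]
                for k in range(d):
                    if ((state >> inputs[i, k]) & 1) == ivals[i, k]:
                        bit = ovals[i, k]
                        break
            if m == 3:
                bit = 1 - bit
        new |= bit << i
    return new


@njit(cache=False, nogil=True)
def _run_trajectory(
    state0, tau, max_steps, n,
    m_inputs, m_ivals, m_ovals, m_depth, m_default, m_mode,
    w_inputs, w_ivals, w_ovals, w_depth, w_default, w_mode,
):
    """Step ``tau`` times under the mutant arrays, then iterate the wild-type
    arrays until a state revisit.  Returns (status, t0, p, cycle)."""
    s = state0
    for _ in range(tau):
        s = _step_bits(s, n, m_inputs, m_ivals, m_ovals, m_depth, m_default, m_mode)
    traj = np.empty(max_steps + 1, dtype=np.int64)
    traj[0] = s
    count = 1
    for _ in range(max_steps):
        s = _step_bits(s, n, w_inputs, w_ivals, w_ovals, w_depth, w_default, w_mode)
        for j in range(count):
            if traj[j] == s:
                return 1, j, count - j, traj[j:count].copy()
        traj[count] = s
        count += 1
    return 0, -1, -1, traj[:0].copy()


def run_attractor(
    model: CompiledModel,
    state0: int,
    max_steps: int,
    mutant: CompiledModel | None = None,
    tau: int = 0,
) -> tuple[int, int, list[int]]:
    """Attractor from packed ``state0``: (transient, period, packed cycle).

    With ``mutant`` and ``tau`` the first ``tau`` steps run under the mutant
    model before ``model`` takes over; the transient is counted from the
    reversion point (add ``tau`` for the composite timeline).
    """
    mut = mutant if mutant is not None else model
    status, t0, p, cycle = _run_trajectory(
        np.int64(state0), tau, max_steps, model.n_nodes,
        mut.inputs, mut.ivals, mut.ovals, mut.depth, mut.default, mut.mode,
        model.inputs, model.ivals, model.ovals, model.depth, model.default,
        model.mode,
    )
    if status == 0:
        raise AttractorBudgetError(max_steps)
    return int(t0), int(p), [int(c) for c in cycle]


def attractor_object(
    model: CompiledModel, state0: Sequence[int], max_steps: int
) -> Attractor:
    """Object-level Attractor via the packed engine (for cross-checks)."""
    t0, p, cycle = run_attractor(model, pack_state(state0), max_steps)
    return Attractor(t0, p, tuple(unpack_state(c, model.n_nodes) for c in cycle))
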