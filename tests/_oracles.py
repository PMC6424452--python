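"""Independent oracles used by the test suite.

Each oracle is implemented by a route deliberately different from the
package's own: the recursive Boolean-logic form of a nested canalyzing
function (vs the first-matching-term scan), Floyd tortoise-and-hare cycle
detection on the state-transition map (vs the visited-hash trajectory), and
an exhaustive time-lag scan for the similarity distance (vs the
gcd-restricted scan).
"""

from __future__ import annotations

from math import gcd, lcm

from boolmut import Attractor, step
from boolmut.dynamics import State


def recursive_ncf(terms: list[tuple[int, int]], values: list[int]) -> int:
    """Evaluate an NCF through its recursive and/or/literal form.

    ``terms`` is the ordered list of (canalyzing I_k, canalyzed O_k);
    ``values`` the input values in the same order.  Valid for depth >= 1
    with the default-output convention default = 1 - O_d, under which the
    rule collapses to nested conjunctions/disjunctions of literals.
    """
    d = len(terms)
    assert d >= 1

    def f(k: int) -> int:
        i_k, o_k = terms[k - 1]
        u = values[k - 1]
        literal = u if o_k == i_k else 1 - u
        if k == d:
            return literal
        rest = f(k + 1)
        return (literal & rest) if o_k == 0 else (literal | rest)

    return f(1)


def floyd_attractor(network, rules, initial: State):
    """(transient, period, cycle states) by tortoise-and-hare detection."""

    def nxt(s: State) -> State:
        return step(network, rules, s)

    tortoise, hare = nxt(initial), nxt(nxt(initial))
    while tortoise != hare:
        tortoise, hare = nxt(tortoise), nxt(nxt(hare))
    mu = 0
    tortoise = initial
    while tortoise != hare:
        tortoise, hare = nxt(tortoise), nxt(hare)
        mu += 1
    cycle = [tortoise]
    s = nxt(tortoise)
    while s != tortoise:
        cycle.append(s)
        s = nxt(s)
    return mu, len(cycle), cycle


def similarity_all_lags(a: Attractor, b: Attractor) -> float:
    """Similarity distance minimised over every lag in 0..lcm(p,p')-1."""
    p, q = a.period, b.period
    n = a.n_nodes
    c = lcm(p, q)
    best = None
    for m in range(c):
        total = 0
        for l in range(c):
            sa = a.states[(l + m) % p]
            sb = b.states[l % q]
            total += sum(x != y for x, y in zip(sa, sb))
        if best is None or total < best:
            best = total
    return best / (c * n)


def cycles_equal_up_to_rotation(cyc_a, cyc_b) -> bool:
    if len(cyc_a) != len(cyc_b):
        return False
    p = len(cyc_a)
    return any(
        all(cyc_a[(l + m) % p] == cyc_b[l] for l in range(p)) for m in range(p)
    )


def random_attractor(rng, n_nodes: int, period: int) -> Attractor:
    """A synthetic attractor: ``period`` pairwise-distinct random states.

    Distinct states make the period minimal by construction, matching the
    attractor invariant.
    """
    assert period <= 2**n_nodes
    codes: set[int] = set()
    while len(codes) < period:
        codes.add(int(rng.integers(0, 2**n_nodes)))
    ordered = list(codes)
    rng.shuffle(ordered)
    states = tuple(
        tuple((c >> i) & 1 for i in range(n_nodes)) for c in ordered
    )
    return Attractor(0, period, states)
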