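import pytest

from boolmut import NCFRule, RuleSet, SignedNetwork


@pytest.fixture
def copy_negate_net():
    """Two nodes: v1 copies v2, v2 negates v1 — a period-4 rotation."""
    net = SignedNetwork(
        ("v1", "v2"), (("v2", "v1", 1), ("v1", "v2", -1))
    )
    rules = RuleSet(net, (
        NCFRule("v1", (("v2", 1, 1),), 0),
        NCFRule("v2", (("v1", 1, 0),), 1),
    ))
    return net, rules


@pytest.fixture
def negation_loop():
    """One node negating itself: rule (v,1,0); default 1."""
    net = SignedNetwork(("v",), (("v", "v", -1),))
    rules = RuleSet(net, (NCFRule("v", (("v", 1, 0),), 1),))
    return net, rules


@pytest.fixture
def constant_zero_net():
    """Three independent nodes all driven to 0 (terms canalyze to 0 both ways)."""
    nodes = ("a", "b", "c")
    net = SignedNetwork(nodes, (("a", "b", 1), ("b", "c", 1), ("c", "a", 1)))
    sources = {"b": "a", "c": "b", "a": "c"}
    rules = RuleSet(net, tuple(
        NCFRule(n, ((sources[n], 1, 0),), 0) for n in nodes
    ))
    return net, rules
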