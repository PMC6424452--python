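import itertools

import numpy as np
import pytest

from boolmut import (
    ConstantRule,
    MutationError,
    MutationSpec,
    NCFRule,
    RuleFormatError,
    RuleSet,
    SignedNetwork,
    apply_mutation,
    evaluate_rule,
    find_attractor,
    generate_random_network,
    generate_random_rules,
    mutant_trajectory,
    register_plugin,
    step,
    unregister_plugin,
)
from boolmut.mutations import EDGE_KINDS, NODE_KINDS, PERMANENT


def _random_model(seed, n=6, m=14):
    net = generate_random_network(n, m, 0.5, seed=seed)
    return net, generate_random_rules(net, seed=seed + 1)


def _target_for(kind, net):
    if kind in NODE_KINDS:
        # pick a node with incoming edges so structural kinds have terms
        for n in net.nodes:
            if net.in_edges(n):
                return (n,)
        return (net.nodes[0],)
    s, t, _ = net.edges[0]
    return ((s, t),)


class TestNodeBasedKinds:
    def test_knockout_always_zero(self):
        net, rules = _random_model(1)
        node = net.nodes[0]
        model = apply_mutation(net, rules, MutationSpec("knockout", (node,)))
        rng = np.random.default_rng(0)
        for _ in range(16):
            s = tuple(int(b) for b in rng.integers(0, 2, net.n_nodes))
            assert evaluate_rule(model.rules.rule_for(node), s, model.network) == 0

    def test_overexpression_always_one(self):
        net, rules = _random_model(2)
        node = net.nodes[1]
        model = apply_mutation(net, rules, MutationSpec("overexpression", (node,)))
        assert model.rules.rule_for(node) == ConstantRule(node, 1)

    def test_state_flip_negates_output_everywhere(self):
        net, rules = _random_model(3)
        node = net.nodes[0]
        model = apply_mutation(net, rules, MutationSpec("state-flip", (node,)))
        rng = np.random.default_rng(1)
        for _ in range(16):
            s = tuple(int(b) for b in rng.integers(0, 2, net.n_nodes))
            assert (evaluate_rule(model.rules.rule_for(node), s, net)
                    == 1 - evaluate_rule(rules.rule_for(node), s, net))

    def test_rule_flip_example(self):
        net = SignedNetwork(("a", "b", "v"), (("a", "v", 1), ("b", "v", -1)))
        rules = RuleSet(net, (
            NCFRule("a", (), 0), NCFRule("b", (), 0),
            NCFRule("v", (("a", 1, 1), ("b", 0, 0)), 1),
        ))
        model = apply_mutation(net, rules, MutationSpec("rule-flip", ("v",)))
        flipped = model.rules.rule_for("v")
        assert flipped.terms == (("a", 0, 0), ("b", 1, 1))
        assert flipped.default_output == 0

    def test_outcome_shuffle_preserves_multiset(self):
        net, rules = _random_model(4, n=8, m=24)
        for node in net.nodes:
            if rules.rule_for(node).depth < 2:
                continue
            model = apply_mutation(
                net, rules, MutationSpec("outcome-shuffle", (node,), seed=3)
            )
            old = rules.rule_for(node)
            new = model.rules.rule_for(node)
            assert sorted(o for _, _, o in new.terms) == \
                sorted(o for _, _, o in old.terms)
            assert new.inputs == old.inputs
            assert [i for _, i, _ in new.terms] == [i for _, i, _ in old.terms]

    def test_outcome_shuffle_fixed_across_repeated_application(self):
        net, rules = _random_model(5)
        spec = MutationSpec("outcome-shuffle", (net.nodes[0],), seed=11)
        a = apply_mutation(net, rules, spec)
        b = apply_mutation(net, rules, spec)
        assert a.rules.rules == b.rules.rules


class TestEdgeticKinds:
    def _model_with_depth3(self):
        net = SignedNetwork(("a", "b", "c", "v"),
                            (("a", "v", 1), ("b", "v", 1), ("c", "v", -1)))
        rules = RuleSet(net, (
            NCFRule("a", (), 0), NCFRule("b", (), 0), NCFRule("c", (), 0),
            NCFRule("v", (("a", 1, 0), ("b", 0, 1), ("c", 1, 1)), 0),
        ))
        return net, rules

    def test_edge_removal_deletes_edge_and_term(self):
        net, rules = self._model_with_depth3()
        model = apply_mutation(net, rules,
                               MutationSpec("edge-removal", (("b", "v"),)))
        assert not model.network.has_edge("b", "v")
        assert model.rules.rule_for("v").terms == (("a", 1, 0), ("c", 1, 1))

    def test_edge_addition_prepends_term(self):
        net, rules = self._model_with_depth3()
        spec = MutationSpec("edge-addition", (("b", "a"),),
                            params={"io": (1, 0), "sign": 1})
        model = apply_mutation(net, rules, spec)
        assert model.network.has_edge("b", "a")
        assert model.rules.rule_for("a").terms == (("b", 1, 0),)

    def test_edge_addition_of_existing_edge_errors(self):
        net, rules = self._model_with_depth3()
        with pytest.raises(MutationError, match="already exists"):
            apply_mutation(net, rules,
                           MutationSpec("edge-addition", (("a", "v"),)))

    def test_edge_addition_sampled_io_follows_spec_seed(self):
        net, rules = self._model_with_depth3()
        spec = MutationSpec("edge-addition", (("b", "a"),), seed=21)
        a = apply_mutation(net, rules, spec)
        b = apply_mutation(net, rules, spec)
        assert a.rules.rules == b.rules.rules
        (u, i, o), = a.rules.rule_for("a").terms
        assert u == "b" and i in (0, 1) and o in (0, 1)
        # derived sign convention: positive iff I == O
        assert a.network.edge_sign("b", "a") == (1 if i == o else -1)

    def test_edge_attenuation_swaps_with_last(self):
        net, rules = self._model_with_depth3()
        model = apply_mutation(net, rules,
                               MutationSpec("edge-attenuation", (("a", "v"),)))
        assert model.rules.rule_for("v").terms == (
            ("c", 1, 1), ("b", 0, 1), ("a", 1, 0)
        )

    def test_edge_attenuation_of_last_term_is_noop(self):
        net, rules = self._model_with_depth3()
        model = apply_mutation(net, rules,
                               MutationSpec("edge-attenuation", (("c", "v"),)))
        assert model.rules.rule_for("v") == rules.rule_for("v")

    def test_edge_sign_switch_flips_canalyzing_value(self):
        net, rules = self._model_with_depth3()
        model = apply_mutation(net, rules,
                               MutationSpec("edge-sign-switch", (("b", "v"),)))
        assert model.rules.rule_for("v").terms == (
            ("a", 1, 0), ("b", 1, 1), ("c", 1, 1)
        )
        assert model.network.edge_sign("b", "v") == -1

    def test_edge_reverse_flips_canalyzed_value(self):
        net, rules = self._model_with_depth3()
        model = apply_mutation(net, rules,
                               MutationSpec("edge-reverse", (("b", "v"),)))
        assert model.rules.rule_for("v").terms == (
            ("a", 1, 0), ("b", 0, 0), ("c", 1, 1)
        )

    def test_edgetic_kind_rejects_node_target(self):
        net, rules = self._model_with_depth3()
        with pytest.raises(MutationError, match="given node"):
            apply_mutation(net, rules, MutationSpec("edge-removal", ("v",)))

    def test_node_kind_rejects_edge_target(self):
        net, rules = self._model_with_depth3()
        with pytest.raises(MutationError, match="given edge"):
            apply_mutation(net, rules, MutationSpec("knockout", (("a", "v"),)))

    def test_unknown_kind_errors(self):
        net, rules = self._model_with_depth3()
        with pytest.raises(MutationError, match="unknown mutation kind"):
            apply_mutation(net, rules, MutationSpec("frobnicate", ("v",)))


class TestInvolutionsAndPurity:
    @pytest.mark.parametrize("kind", ["rule-flip", "edge-sign-switch",
                                      "edge-reverse"])
    def test_applying_twice_is_identity(self, kind):
        for seed in range(5):
            net, rules = _random_model(seed * 10, n=7, m=18)
            target = _target_for(kind, net)
            spec = MutationSpec(kind, target)
            once = apply_mutation(net, rules, spec)
            twice = apply_mutation(once.network, once.rules, spec)
            assert twice.network == net
            assert twice.rules.rules == rules.rules

    def test_attenuation_twice_on_same_position_is_identity(self):
        """The swap is the transposition (j, d): repeating it at the same
        *position* j (whatever edge's term sits there) restores the rule."""
        for seed in range(5):
            net, rules = _random_model(seed * 10 + 1, n=7, m=18)
            node = max(net.nodes, key=lambda n: rules.rule_for(n).depth)
            rule = rules.rule_for(node)
            if rule.depth < 2:
                continue
            for j in range(rule.depth):
                e1 = (rule.terms[j][0], node)
                once = apply_mutation(
                    net, rules, MutationSpec("edge-attenuation", (e1,)))
                e2 = (once.rules.rule_for(node).terms[j][0], node)
                twice = apply_mutation(
                    once.network, once.rules,
                    MutationSpec("edge-attenuation", (e2,)))
                assert twice.rules.rules == rules.rules

    def test_attenuation_of_same_edge_twice_is_single_swap(self):
        """Re-targeting the same edge is a no-op the second time: its term
        already sits at the lowest-precedence position."""
        net, rules = _random_model(13, n=7, m=18)
        node = max(net.nodes, key=lambda n: rules.rule_for(n).depth)
        rule = rules.rule_for(node)
        assert rule.depth >= 2
        edge = (rule.terms[0][0], node)
        spec = MutationSpec("edge-attenuation", (edge,))
        once = apply_mutation(net, rules, spec)
        twice = apply_mutation(once.network, once.rules, spec)
        assert twice.rules.rules == once.rules.rules

    @pytest.mark.parametrize("kind", sorted(NODE_KINDS | EDGE_KINDS))
    def test_wild_type_pristine_after_mutant_run(self, kind):
        net, rules = _random_model(77, n=6, m=14)
        if kind == "edge-addition":
            missing = next(
                (u, v) for u in net.nodes for v in net.nodes
                if not net.has_edge(u, v)
            )
            target = (missing,)
        else:
            target = _target_for(kind, net)
        pristine_net = SignedNetwork(net.nodes, net.edges)
        pristine_rules = tuple(rules.rules)
        spec = MutationSpec(kind, target, duration=3, seed=5)
        mutant_trajectory(net, rules, spec, (0,) * net.n_nodes)
        assert net == pristine_net
        assert rules.rules == pristine_rules


class TestDurationSemantics:
    def test_knockout_clamps_node_during_tau(self):
        net, rules = _random_model(8)
        node = net.nodes[0]
        idx = net.index(node)
        spec = MutationSpec("knockout", (node,), duration=3)
        model = apply_mutation(net, rules, spec)
        state = (1,) * net.n_nodes
        for _ in range(3):
            state = step(model.network, model.rules, state)
            assert state[idx] == 0

    def test_overexpression_clamps_to_one(self):
        net, rules = _random_model(9)
        node = net.nodes[2]
        idx = net.index(node)
        model = apply_mutation(net, rules,
                               MutationSpec("overexpression", (node,)))
        state = (0,) * net.n_nodes
        for _ in range(4):
            state = step(model.network, model.rules, state)
            assert state[idx] == 1

    def test_negation_loop_knockout_reverts_to_same_cycle(self, negation_loop):
        net, rules = negation_loop
        spec = MutationSpec("knockout", ("v",), duration=1)
        attr = mutant_trajectory(net, rules, spec, (1,))
        wild = find_attractor(net, rules, (1,))
        assert attr.period == wild.period == 2
        assert set(attr.states) == set(wild.states) == {(0,), (1,)}

    def test_permanent_overexpression_fixed_point(self):
        net, rules = _random_model(10)
        node = net.nodes[0]
        idx = net.index(node)
        spec = MutationSpec("overexpression", (node,), duration=PERMANENT)
        attr = mutant_trajectory(net, rules, spec, (0,) * net.n_nodes)
        assert all(s[idx] == 1 for s in attr.states)

    def test_invalid_duration(self):
        with pytest.raises(MutationError):
            MutationSpec("knockout", ("v",), duration=0)


class TestComposition:
    def test_double_removal_equals_sequential_in_either_order(self):
        net, rules = _random_model(30, n=8, m=20)
        (s1, t1, _), (s2, t2, _) = net.edges[0], net.edges[1]
        e1, e2 = (s1, t1), (s2, t2)
        both = apply_mutation(net, rules,
                              MutationSpec("edge-removal", (e1, e2)))
        for order in ((e1, e2), (e2, e1)):
            m = apply_mutation(net, rules,
                               MutationSpec("edge-removal", (order[0],)))
            m = apply_mutation(m.network, m.rules,
                               MutationSpec("edge-removal", (order[1],)))
            assert set(m.network.edges) == set(both.network.edges)
            assert m.rules.rules == both.rules.rules


class TestPlugins:
    def test_plugin_rule_flip_matches_builtin(self):
        def my_rule_flip(rule, network, rng):
            terms = tuple((u, 1 - i, 1 - o) for u, i, o in rule.terms)
            return NCFRule(rule.target, terms, 1 - rule.default_output)

        register_plugin("myRuleFlip", node_transform=my_rule_flip)
        try:
            for seed in range(5):
                net, rules = _random_model(seed, n=6, m=15)
                node = net.nodes[0]
                via_plugin = apply_mutation(
                    net, rules, MutationSpec("myRuleFlip", (node,)))
                builtin = apply_mutation(
                    net, rules, MutationSpec("rule-flip", (node,)))
                assert via_plugin.rules.rules == builtin.rules.rules
        finally:
            unregister_plugin("myRuleFlip")

    def test_predefined_name_collision(self):
        with pytest.raises(MutationError, match="collides"):
            register_plugin("knockout", node_transform=lambda r, n, g: r)

    def test_plugin_returning_invalid_rule_fails_validation(self):
        def bad(rule, network, rng):
            return NCFRule(rule.target, (("nonexistent", 1, 1),), 0)

        register_plugin("badPlugin", node_transform=bad)
        try:
            net, rules = _random_model(40)
            node = next(n for n in net.nodes if net.in_edges(n))
            with pytest.raises(RuleFormatError, match="non-edge input"):
                apply_mutation(net, rules, MutationSpec("badPlugin", (node,)))
        finally:
            unregister_plugin("badPlugin")

    def test_plugin_needs_a_transform(self):
        with pytest.raises(MutationError):
            register_plugin("emptyPlugin")

    def test_load_plugin_file(self, tmp_path):
        script = tmp_path / "double_flip.py"
        script.write_text(
            "from boolmut import NCFRule\n"
            "MUTATION_NAME = 'fileFlip'\n"
            "def node_transform(rule, network, rng):\n"
            "    terms = tuple((u, 1-i, 1-o) for u, i, o in rule.terms)\n"
            "    return NCFRule(rule.target, terms, 1-rule.default_output)\n"
        )
        from boolmut import load_plugin_file

        name = load_plugin_file(script)
        try:
            assert name == "fileFlip"
            net, rules = _random_model(50)
            node = net.nodes[0]
            assert (apply_mutation(net, rules, MutationSpec(name, (node,)))
                    .rules.rules
                    == apply_mutation(net, rules,
                                      MutationSpec("rule-flip", (node,)))
                    .rules.rules)
        finally:
            unregister_plugin(name)
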