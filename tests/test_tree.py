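"""Decision-tree construction, rollback, and incremental analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxicea.parameters import ParameterTable
from oxicea.tree import (
    DecisionTree,
    Node,
    ProbExpr,
    TerminalPayoff,
    build_model,
    incremental,
    rollback,
)


def enumerate_paths(node):
    """Independent oracle: all complete root-to-leaf paths of a chance tree."""
    if node.kind == "terminal":
        return [([], node.payoff)]
    paths = []
    for expr, child in node.branches:
        for exprs, payoff in enumerate_paths(child):
            paths.append(([expr] + exprs, payoff))
    return paths


def oracle_expectation(node, assignment):
    """Probability-weighted payoff sum over complete paths."""
    cost = effect = 0.0
    for exprs, payoff in enumerate_paths(node):
        p = 1.0
        for e in exprs:
            v = assignment[e.param]
            p *= (1.0 - v) if e.complement else v
        cost += p * assignment[payoff.cost_param]
        effect += p * payoff.effect
    return cost, effect


class TestBuildModel:
    def test_two_strategies_four_terminals_each(self, model):
        assert model.strategy_names == ["intervention", "control"]
        for name in model.strategy_names:
            assert len(model.root(name).leaves()) == 4

    def test_missing_parameter_named(self, params):
        reduced = ParameterTable(s for s in params if s.name != "sens_control")
        with pytest.raises(KeyError, match="sens_control"):
            build_model(reduced)

    def test_unknown_effect_definition(self, params):
        with pytest.raises(ValueError):
            build_model(params, effect_definition="lives_saved")

    def test_serialization_round_trip(self, model, base_values):
        clone = DecisionTree.from_dict(model.to_dict())
        assert rollback(clone, base_values) == rollback(model, base_values)

    def test_non_complementary_chance_node_rejected(self):
        leaf = Node("terminal", "t", payoff=TerminalPayoff("c", 0))
        with pytest.raises(ValueError, match="complementary"):
            Node("chance", "bad", branches=((ProbExpr("p"), leaf), (ProbExpr("q"), leaf)))


class TestRollback:
    def test_base_case_expected_values(self, model, base_values):
        # hand expansion: E[C] = p*c_sev + (1-p)*c_non, E[E] = p*sens
        out = rollback(model, base_values)
        c_i, e_i = out["intervention"]
        c_c, e_c = out["control"]
        assert c_i == pytest.approx(0.16 * 25.74 + 0.84 * 3.58, abs=1e-12)  # 7.1256
        assert e_i == pytest.approx(0.16 * 0.85, abs=1e-12)  # 0.1360
        assert c_c == pytest.approx(0.04 * 17.98 + 0.96 * 2.14, abs=1e-12)  # 2.7736
        assert e_c == pytest.approx(0.04 * 0.56, abs=1e-12)  # 0.0224

    def test_rollback_matches_path_enumeration_oracle(self, model, base_values):
        for name in model.strategy_names:
            c, e = rollback(model, base_values)[name]
            oc, oe = oracle_expectation(model.root(name), base_values)
            assert c == pytest.approx(oc, abs=1e-12)
            assert e == pytest.approx(oe, abs=1e-12)

    def test_degenerate_probability_zero(self, model, base_values):
        vals = dict(base_values, p_severe_intervention=0.0)
        c, e = rollback(model, vals)["intervention"]
        assert c == pytest.approx(vals["cost_nonsevere_intervention"], abs=1e-12)
        assert e == 0.0

    def test_all_probabilities_extreme_selects_single_leaf(self, model, base_values):
        vals = dict(base_values, p_severe_intervention=1.0, sens_intervention=1.0)
        c, e = rollback(model, vals)["intervention"]
        assert c == pytest.approx(vals["cost_severe_intervention"], abs=1e-12)
        assert e == 1.0

    def test_probability_outside_unit_interval_errors(self, model, base_values):
        with pytest.raises(ValueError, match="outside"):
            rollback(model, dict(base_values, p_severe_intervention=1.5))

    def test_expected_values_within_leaf_bounds(self, model, base_values):
        out = rollback(model, base_values)
        for name in model.strategy_names:
            c, e = out[name]
            costs = [base_values[p.cost_param] for _, p in model.root(name).leaves()]
            assert min(costs) <= c <= max(costs)
            assert 0.0 <= e <= 1.0

    def test_vectorized_assignment_matches_scalar(self, model, base_values):
        vec = {k: np.array([v, v / 2 if k.startswith("cost") else v]) for k, v in base_values.items()}
        out = rollback(model, vec)
        scalar = rollback(model, base_values)
        for name in model.strategy_names:
            assert out[name][0][0] == pytest.approx(scalar[name][0], abs=1e-12)


@st.composite
def random_tree_and_assignment(draw, max_depth=6):
    """Random complementary-pair chance trees with a random assignment."""
    n_params = draw(st.integers(2, 6))
    prob_names = [f"p{i}" for i in range(n_params)]
    cost_names = [f"c{i}" for i in range(3)]
    assignment = {n: draw(st.floats(0.0, 1.0)) for n in prob_names}
    assignment |= {n: draw(st.floats(0.0, 50.0)) for n in cost_names}

    def make(depth):
        if depth == 0 or draw(st.booleans()) and depth < max_depth - 1:
            return Node(
                "terminal", f"leaf{depth}",
                payoff=TerminalPayoff(draw(st.sampled_from(cost_names)),
                                      draw(st.integers(0, 1))),
            )
        p = draw(st.sampled_from(prob_names))
        return Node(
            "chance", f"n{depth}",
            branches=((ProbExpr(p), make(depth - 1)),
                      (ProbExpr(p, complement=True), make(depth - 1))),
        )

    root = make(draw(st.integers(1, max_depth)))
    return root, assignment


class TestRollbackProperty:
    @given(random_tree_and_assignment())
    @settings(max_examples=150, deadline=None)
    def test_rollback_equals_enumeration_on_random_trees(self, tree_and_vals):
        root, vals = tree_and_vals
        tree = DecisionTree(strategies=(("s", root),))
        c, e = rollback(tree, vals)["s"]
        oc, oe = oracle_expectation(root, vals)
        assert c == pytest.approx(oc, abs=1e-12)
        assert e == pytest.approx(oe, abs=1e-12)


class TestIncremental:
    def test_base_case_icer_true_positive(self, model, base_values):
        out = rollback(model, base_values)
        res = incremental(out["control"], out["intervention"])
        assert res.status == "icer"
        assert res.delta_cost == pytest.approx(4.3520, abs=1e-10)
        assert res.delta_effect == pytest.approx(0.1136, abs=1e-12)
        assert res.icer == pytest.approx(4.3520 / 0.1136, abs=1e-8)  # ~38.31

    def test_base_case_icer_any_severe_diagnosis(self, params, base_values):
        tree = build_model(params, effect_definition="any_severe_diagnosis")
        out = rollback(tree, base_values)
        res = incremental(out["control"], out["intervention"])
        # effect is the diagnosed-severe proportion itself: delta = 0.12
        assert res.delta_effect == pytest.approx(0.12, abs=1e-12)
        assert res.icer == pytest.approx(4.3520 / 0.12, abs=1e-8)  # ~36.27

    def test_perfect_test_makes_effect_definitions_agree(self, params, base_values):
        vals = dict(base_values, sens_intervention=1.0, sens_control=1.0)
        icers = []
        for effect in ("true_positive", "any_severe_diagnosis"):
            out = rollback(build_model(params, effect), vals)
            icers.append(incremental(out["control"], out["intervention"]).icer)
        assert icers[0] == pytest.approx(icers[1], abs=1e-12)

    def test_dominance_statuses(self):
        assert incremental((10, 0.1), (5, 0.2)).status == "dominant"
        assert incremental((10, 0.1), (15, 0.05)).status == "dominated"
        assert incremental((10, 0.1), (15, 0.1)).status == "equal_effect"
        assert incremental((10, 0.1), (15, 0.1)).icer is None

    def test_order_swap_flips_sign(self, model, base_values):
        out = rollback(model, base_values)
        fwd = incremental(out["control"], out["intervention"])
        rev = incremental(out["intervention"], out["control"])
        assert rev.icer == pytest.approx(fwd.icer)  # both deltas negate
        assert rev.delta_cost == -fwd.delta_cost
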