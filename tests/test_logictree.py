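"""Boolean tree evaluation, scoring functions, moves, and the annealing search."""

import itertools
import math

import numpy as np
import pytest

from harmonizer.logictree import (
    AnnealingConfig,
    Internal,
    Leaf,
    LogicTree,
    Method,
    Move,
    Op,
    ScoreWeights,
    anneal,
    applicable_moves,
    evaluate_tree,
    evaluate_tree_matrix,
    parse_expression,
    propose_move,
    satisfied_leaf_fraction,
    score_classification,
    score_logistic,
    tree_to_expression,
)

from _oracles import all_trees, random_tree, truth_table, logistic_deviance_oracle

R1_OR_R2_AND_R3 = LogicTree(
    Internal(Op.AND, Internal(Op.OR, Leaf(0), Leaf(1)), Leaf(2))
)


class TestEvaluateTree:
    def test_example_expression(self):
        assert evaluate_tree(R1_OR_R2_AND_R3, [0, 1, 1]) is True
        assert evaluate_tree(R1_OR_R2_AND_R3, [1, 1, 0]) is False

    def test_complemented_leaf(self):
        assert evaluate_tree(LogicTree(Leaf(0, complement=True)), [1]) is False
        assert evaluate_tree(LogicTree(Leaf(0, complement=True)), [0]) is True

    def test_out_of_range_leaf_is_hard_error(self):
        with pytest.raises(IndexError):
            evaluate_tree(LogicTree(Leaf(3)), [1, 0])

    def test_exhaustive_truth_table_agreement_small(self):
        """Every tree with <=3 leaves over 3 rules against the eval() oracle."""
        for n_leaves in (1, 2, 3):
            for root in all_trees(n_leaves, 3):
                tree = LogicTree(root)
                expected = truth_table(tree, 3)
                for i, bits in enumerate(itertools.product([False, True], repeat=3)):
                    assert evaluate_tree(tree, bits) == expected[i]

    def test_sampled_truth_table_agreement_larger(self):
        """Seeded random 4- and 5-leaf trees over 5 rules against the oracle."""
        rng = np.random.default_rng(42)
        assignments = np.array(
            list(itertools.product([False, True], repeat=5)), dtype=bool
        )
        for _ in range(400):
            n_leaves = int(rng.integers(4, 6))
            tree = LogicTree(random_tree(rng, n_leaves, 5))
            expected = truth_table(tree, 5)
            got = evaluate_tree_matrix(tree, assignments)
            assert got.tolist() == expected


class TestScoreWeights:
    def test_must_sum_to_one(self):
        with pytest.raises(ValueError):
            ScoreWeights(0.9, 0.2)

    def test_false_negative_to_false_positive_ratio_is_1999(self):
        weights = ScoreWeights(0.9995, 0.0005)
        fn_cost = score_classification([0], [1], weights)
        fp_cost = score_classification([1], [0], weights)
        assert fn_cost / fp_cost == pytest.approx(1999.0, rel=1e-12)


class TestScoreClassification:
    def test_perfect_is_zero(self):
        y = [1, 0, 1, 0]
        assert score_classification(y, y, ScoreWeights()) == 0.0

    def test_single_false_negative_costs_w_pos(self):
        assert score_classification([0], [1], ScoreWeights(0.9995, 0.0005)) == 0.9995

    def test_mixed_errors_sum(self):
        score = score_classification([0, 1, 0], [1, 0, 0], ScoreWeights(0.9995, 0.0005))
        assert score == pytest.approx(1.0000)

    def test_monotone_in_each_error_type(self):
        weights = ScoreWeights(0.8, 0.2)
        base = score_classification([1, 0, 0, 0], [1, 1, 0, 0], weights)
        more_fn = score_classification([0, 0, 0, 0], [1, 1, 0, 0], weights)
        more_fp = score_classification([1, 0, 1, 0], [1, 1, 0, 0], weights)
        assert more_fn > base and more_fp > base

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            score_classification([1], [1, 0], ScoreWeights())


class TestScoreLogistic:
    def test_perfect_separation_is_bounded_but_tiny(self):
        x = [1, 1, 0, 0, 0, 0]
        y = [1, 1, 0, 0, 0, 0]
        weights = ScoreWeights(0.9995, 0.0005)
        separated = score_logistic(x, y, weights)
        intercept_only = score_logistic([0] * 6, y, weights)
        assert 0 < separated < 1e-3 * intercept_only

    def test_constant_covariate_equals_intercept_only_closed_form(self):
        y = [1, 1, 0, 0]
        weights = ScoreWeights(0.5, 0.5)
        expected = -2 * sum(0.5 * math.log(0.5) for _ in y)
        assert score_logistic([0, 0, 0, 0], y, weights) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "counts",  # (n11, n10, n01, n00): y=1/x=1, y=1/x=0, y=0/x=1, y=0/x=0
        [(3, 2, 4, 6), (5, 1, 1, 8), (2, 2, 2, 2), (1, 6, 3, 2)],
    )
    def test_two_by_two_matches_numeric_optimizer(self, counts):
        n11, n10, n01, n00 = counts
        x = [1] * n11 + [0] * n10 + [1] * n01 + [0] * n00
        y = [1] * (n11 + n10) + [0] * (n01 + n00)
        weights = ScoreWeights(0.9, 0.1)
        ours = score_logistic(x, y, weights)
        oracle = logistic_deviance_oracle(x, y, weights.w_pos, weights.w_neg)
        assert ours == pytest.approx(oracle, rel=1e-4, abs=1e-8)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            score_logistic([0, 1], [1, 1], ScoreWeights())


class TestProposeMove:
    def test_single_leaf_moves(self):
        tree = LogicTree(Leaf(0))
        assert set(applicable_moves(tree)) == {
            Move.ALTERNATE_LEAF, Move.GROW_BRANCH, Move.SPLIT_LEAF
        }
        rng = np.random.default_rng(0)
        for _ in range(200):
            new, move = propose_move(tree, 4, rng)
            assert new.n_leaves in (1, 2)
            assert tree.root == Leaf(0)  # input untouched

    def test_alternate_operator_flips(self):
        tree = LogicTree(Internal(Op.AND, Leaf(0), Leaf(1)))
        rng = np.random.default_rng(1)
        for _ in range(500):
            new, move = propose_move(tree, 2, rng)
            if move is Move.ALTERNATE_OPERATOR:
                assert new.root.op is Op.OR
                assert (new.root.left, new.root.right) == (Leaf(0), Leaf(1))
                break
        else:
            pytest.fail("alternate-operator never drawn in 500 proposals")

    def test_every_move_type_observed_from_three_leaf_tree(self):
        tree = LogicTree(
            Internal(Op.OR, Internal(Op.AND, Leaf(0), Leaf(1)), Leaf(2))
        )
        rng = np.random.default_rng(7)
        seen = set()
        for _ in range(10_000):
            _, move = propose_move(tree, 5, rng)
            seen.add(move)
        assert seen == set(Move)

    def test_moves_change_exactly_one_thing(self):
        tree = LogicTree(Internal(Op.AND, Leaf(0), Leaf(1)))
        rng = np.random.default_rng(3)
        for _ in range(300):
            new, move = propose_move(tree, 3, rng)
            if move in (Move.PRUNE_BRANCH, Move.DELETE_LEAF):
                assert new.n_leaves == 1
            elif move in (Move.GROW_BRANCH, Move.SPLIT_LEAF):
                assert new.n_leaves == 3
            else:
                assert new.n_leaves == 2


def _planted_and(n=200, n_rules=8, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.random((n, n_rules)) < 0.5
    y = X[:, 0] & X[:, 1]
    return X, y


class TestAnneal:
    def test_recovers_planted_conjunction(self):
        X, y = _planted_and(seed=2)
        # the exhaustive <=2-leaf oracle confirms a zero-score tree exists
        zero_exists = any(
            score_classification(evaluate_tree_matrix(LogicTree(r), X), y, ScoreWeights()) == 0
            for n in (1, 2)
            for r in all_trees(n, 8)
        )
        assert zero_exists
        config = AnnealingConfig(n_iterations=10_000, minmass=4, seed=1)
        fit = anneal(X, y, config)
        assert fit.best_score == 0.0
        assert fit.best_tree.n_leaves <= config.treesize
        preds = evaluate_tree_matrix(fit.best_tree, X)
        assert int(preds.sum()) >= config.minmass

    def test_same_seed_same_result(self):
        X, y = _planted_and(seed=3)
        config = AnnealingConfig(n_iterations=2000, minmass=1, seed=9)
        fit1 = anneal(X, y, config)
        fit2 = anneal(X, y, config)
        assert fit1.best_tree == fit2.best_tree
        assert fit1.score_trace == fit2.score_trace
        assert fit1.n_accepted_moves == fit2.n_accepted_moves

    def test_labels_independent_of_rules_cannot_beat_best_constant(self):
        """With all-zero rule columns every tree predicts a constant, so the
        best reachable score is exactly the better constant predictor's."""
        rng = np.random.default_rng(4)
        X = np.zeros((120, 3), dtype=bool)
        y = rng.random(120) < 0.3
        weights = ScoreWeights(0.9995, 0.0005)
        config = AnnealingConfig(n_iterations=2000, minmass=0, seed=5, weights=weights)
        fit = anneal(X, y, config)
        const0 = score_classification(np.zeros_like(y), y, weights)
        const1 = score_classification(np.ones_like(y), y, weights)
        assert fit.best_score == pytest.approx(min(const0, const1))

    def test_best_so_far_is_monotone_and_matches_trace(self):
        X, y = _planted_and(seed=6)
        config = AnnealingConfig(n_iterations=3000, minmass=1, seed=2)
        fit = anneal(X, y, config)
        running = np.minimum.accumulate(fit.score_trace)
        assert all(a >= b for a, b in zip(running, running[1:]))
        assert fit.best_score == min(fit.score_trace)

    def test_minmass_constrains_predictions(self):
        X, y = _planted_and(seed=8)
        config = AnnealingConfig(n_iterations=3000, minmass=30, seed=3)
        fit = anneal(X, y, config)
        preds = evaluate_tree_matrix(fit.best_tree, X)
        assert int(preds.sum()) >= 30

    def test_no_positives_rejected(self):
        X = np.ones((10, 2), dtype=bool)
        with pytest.raises(ValueError, match="positive"):
            anneal(X, np.zeros(10, dtype=bool), AnnealingConfig(n_iterations=10))

    def test_logistic_method_runs_and_separates(self):
        X, y = _planted_and(seed=10)
        config = AnnealingConfig(
            method=Method.LOGISTIC, n_iterations=4000, minmass=4, seed=4
        )
        fit = anneal(X, y, config)
        preds = evaluate_tree_matrix(fit.best_tree, X)
        # the planted conjunction is findable; logistic deviance near zero
        assert (preds == y).mean() > 0.95


class TestExpressions:
    def test_rendering_examples(self):
        assert tree_to_expression(R1_OR_R2_AND_R3, ["R1", "R2", "R3"]) == "((R1 OR R2) AND R3)"
        assert tree_to_expression(LogicTree(Leaf(0, True)), ["R1"]) == "(NOT R1)"

    def test_round_trip_equivalence_on_random_trees(self):
        rule_ids = [f"R{i}" for i in range(5)]
        rng = np.random.default_rng(11)
        assignments = list(itertools.product([0, 1], repeat=5))
        for _ in range(100):
            tree = LogicTree(random_tree(rng, int(rng.integers(1, 6)), 5))
            text = tree_to_expression(tree, rule_ids)
            parsed = parse_expression(text, rule_ids)
            for bits in assignments:
                assert evaluate_tree(parsed, bits) == evaluate_tree(tree, bits)

    def test_parse_rejects_garbage(self):
        with pytest.raises(ValueError):
            parse_expression("(R1 AND)", ["R1"])
        with pytest.raises(ValueError):
            parse_expression("(R9)", ["R1"])


def test_satisfied_leaf_fraction():
    tree = LogicTree(Internal(Op.AND, Leaf(0), Leaf(1)))
    assert satisfied_leaf_fraction(tree, [1, 0]) == 0.5
    assert satisfied_leaf_fraction(tree, [1, 1]) == 1.0
    negated = LogicTree(Internal(Op.AND, Leaf(0, True), Leaf(1)))
    assert satisfied_leaf_fraction(negated, [1, 0]) == 0.0
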