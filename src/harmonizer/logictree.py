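"""Logic regression by simulated annealing over Boolean trees.

A model for one target variable is a single Boolean tree: leaves reference
binary rule outputs (optionally complemented), internal nodes are AND/OR with
exactly two children. The fit minimizes a weighted least-squares score — for
0/1 outcomes a weighted misclassification count — where matching variables
(the rare positives) carry a much larger weight than the overwhelming mass of
non-matching ones.

The search perturbs the tree with six local moves (alternate leaf, alternate
operator, grow branch, prune branch, split leaf, delete leaf). Improving moves
are always accepted; worsening moves are accepted with a probability that
decays geometrically over the run (the annealing "temperature"), by default
from 0.1 down to 0.0001. Trees exceeding the leaf budget (``treesize``) or
predicting positive on fewer than ``minmass`` training instances are rejected
outright.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

logger = logging.getLogger("harmonizer")

__all__ = [
    "Leaf",
    "Internal",
    "LogicTree",
    "Op",
    "Move",
    "ScoreWeights",
    "AnnealingConfig",
    "FitResult",
    "evaluate_tree",
    "evaluate_tree_matrix",
    "score_classification",
    "score_logistic",
    "propose_move",
    "anneal",
    "tree_to_expression",
    "parse_expression",
    "satisfied_leaf_fraction",
]


class Op(str, enum.Enum):
    AND = "AND"
    OR = "OR"


@dataclass(frozen=True)
class Leaf:
    """A literal: rule ``rule_index``, negated when ``complement`` is set."""

    rule_index: int
    complement: bool = False

    def __post_init__(self) -> None:
        if self.rule_index < 0:
            raise ValueError("rule_index must be non-negative")


@dataclass(frozen=True)
class Internal:
    op: Op
    left: "Node"
    right: "Node"


Node = Union[Leaf, Internal]


@dataclass(frozen=True)
class LogicTree:
    """A Boolean combination of rule outputs; the fitted model for one target."""

    root: Node

    def leaves(self) -> list[Leaf]:
        return [node for _, node in _walk(self.root) if isinstance(node, Leaf)]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def max_rule_index(self) -> int:
        return max(leaf.rule_index for leaf in self.leaves())


def _walk(node: Node, path: tuple[int, ...] = ()):
    """Yield (path, node) pairs in prefix order; path items are 0=left, 1=right."""
    yield path, node
    if isinstance(node, Internal):
        yield from _walk(node.left, path + (0,))
        yield from _walk(node.right, path + (1,))


def _replace(node: Node, path: tuple[int, ...], new: Node) -> Node:
    if not path:
        return new
    assert isinstance(node, Internal)
    if path[0] == 0:
        return Internal(node.op, _replace(node.left, path[1:], new), node.right)
    return Internal(node.op, node.left, _replace(node.right, path[1:], new))


# ---------------------------------------------------------------------------
# evaluation


def _eval_node(node: Node, rule_values: np.ndarray) -> np.ndarray:
    if isinstance(node, Leaf):
        column = rule_values[..., node.rule_index]
        return ~column if node.complement else column
    left = _eval_node(node.left, rule_values)
    right = _eval_node(node.right, rule_values)
    return (left & right) if node.op is Op.AND else (left | right)


def evaluate_tree(tree: LogicTree, rule_values: Sequence[int]) -> bool:
    """Evaluate the tree on one binary rule vector."""
    values = np.asarray(rule_values, dtype=bool)
    if tree.max_rule_index() >= values.shape[-1]:
        raise IndexError(
            f"tree references rule {tree.max_rule_index()} but only "
            f"{values.shape[-1]} rule values were given"
        )
    return bool(_eval_node(tree.root, values))


def evaluate_tree_matrix(tree: LogicTree, rule_matrix: np.ndarray) -> np.ndarray:
    """Vectorized evaluation over an (instances x rules) binary matrix."""
    matrix = np.asarray(rule_matrix, dtype=bool)
    if tree.max_rule_index() >= matrix.shape[1]:
        raise IndexError("tree references a rule outside the matrix")
    return _eval_node(tree.root, matrix)


def satisfied_leaf_fraction(tree: LogicTree, rule_values: Sequence[int]) -> float:
    """Fraction of leaves whose literal is satisfied; the allocation rank key."""
    values = np.asarray(rule_values, dtype=bool)
    leaves = tree.leaves()
    hits = sum(
        (not values[leaf.rule_index]) if leaf.complement else bool(values[leaf.rule_index])
        for leaf in leaves
    )
    return hits / len(leaves)


# ---------------------------------------------------------------------------
# scoring


@dataclass(frozen=True)
class ScoreWeights:
    """Case/control weights of the evaluation function.

    The operating parameterization weights each matching variable (positive)
    by ``w_pos`` and each non-matching one by ``w_neg``, with
    ``w_pos + w_neg = 1``; the default 0.9995/0.0005 makes one false negative
    cost as much as 1999 false positives, compensating the extreme class
    imbalance of the allocation problem.
    """

    w_pos: float = 0.9995
    w_neg: float = 0.0005

    def __post_init__(self) -> None:
        if not (0 < self.w_pos < 1 and 0 < self.w_neg < 1):
            raise ValueError("weights must lie in (0, 1)")
        if abs(self.w_pos + self.w_neg - 1.0) > 1e-12:
            raise ValueError("w_pos + w_neg must equal 1")

    @classmethod
    def from_w_neg(cls, w_neg: float) -> "ScoreWeights":
        return cls(w_pos=1.0 - w_neg, w_neg=w_neg)

    def per_instance(self, labels: np.ndarray) -> np.ndarray:
        return np.where(labels, self.w_pos, self.w_neg)


def score_classification(
    predictions: Sequence[int], labels: Sequence[int], weights: ScoreWeights
) -> float:
    """Weighted misclassification count: sum of w_pos over false negatives
    plus w_neg over false positives (the 0/1 case of the weighted
    least-squares evaluation function)."""
    pred = np.asarray(predictions, dtype=bool)
    y = np.asarray(labels, dtype=bool)
    if pred.shape != y.shape:
        raise ValueError("predictions and labels must have equal length")
    fn = int((y & ~pred).sum())
    fp = int((~y & pred).sum())
    return fn * weights.w_pos + fp * weights.w_neg


_LOGIT_CAP = 15.0  # |a + b·x| cap; bounds the deviance under perfect separation


def score_logistic(
    tree_outputs: Sequence[int], labels: Sequence[int], weights: ScoreWeights
) -> float:
    """Weighted deviance of the one-covariate logistic model P(y=1) = expit(a + b·x).

    With a binary covariate the weighted MLE has closed form: the fitted
    probability in each covariate group is the weighted mean of the outcome.
    Fitted logits are capped at ±15, so perfect separation yields a small
    positive deviance instead of a failure; a constant covariate degrades to
    the intercept-only fit.
    """
    x = np.asarray(tree_outputs, dtype=bool)
    y = np.asarray(labels, dtype=float)
    if x.shape != y.shape:
        raise ValueError("tree_outputs and labels must have equal length")
    if not (0 < y.sum() < y.size):
        raise ValueError("both outcome classes must be present")
    w = weights.per_instance(y.astype(bool))

    p_min = 1.0 / (1.0 + math.exp(_LOGIT_CAP))
    p_hat = np.empty_like(y)
    groups = [x, ~x] if x.any() and (~x).any() else [np.ones_like(x, dtype=bool)]
    for mask in groups:
        p = float(np.sum(w[mask] * y[mask]) / np.sum(w[mask]))
        p_hat[mask] = min(max(p, p_min), 1.0 - p_min)
    return float(-2.0 * np.sum(w * (y * np.log(p_hat) + (1 - y) * np.log(1 - p_hat))))


# ---------------------------------------------------------------------------
# moves


class Move(str, enum.Enum):
    ALTERNATE_LEAF = "alternate_leaf"
    ALTERNATE_OPERATOR = "alternate_operator"
    GROW_BRANCH = "grow_branch"
    PRUNE_BRANCH = "prune_branch"
    SPLIT_LEAF = "split_leaf"
    DELETE_LEAF = "delete_leaf"


def _random_leaf(rng: np.random.Generator, n_rules: int) -> Leaf:
    return Leaf(int(rng.integers(n_rules)), bool(rng.integers(2)))


def applicable_moves(tree: LogicTree) -> list[Move]:
    """Moves that can act on the current tree (size limits are the caller's)."""
    moves = [Move.ALTERNATE_LEAF, Move.GROW_BRANCH, Move.SPLIT_LEAF]
    if isinstance(tree.root, Internal):
        moves += [Move.ALTERNATE_OPERATOR, Move.PRUNE_BRANCH, Move.DELETE_LEAF]
    return moves


def propose_move(
    tree: LogicTree, n_rules: int, rng: np.random.Generator
) -> tuple[LogicTree, Move]:
    """Return a new tree differing from ``tree`` by one uniformly drawn move.

    The move type is drawn uniformly from the applicable subset of the six
    move types, then a site (leaf or internal node) uniformly within the type.
    Grow and split both expand a leaf into a two-leaf branch; they attach the
    fresh leaf on opposite sides. The input tree is never mutated.
    """
    if n_rules < 1:
        raise ValueError("n_rules must be at least 1")
    nodes = list(_walk(tree.root))
    leaf_sites = [(p, n) for p, n in nodes if isinstance(n, Leaf)]
    internal_sites = [(p, n) for p, n in nodes if isinstance(n, Internal)]
    moves = applicable_moves(tree)
    move = moves[int(rng.integers(len(moves)))]

    if move is Move.ALTERNATE_LEAF:
        path, leaf = leaf_sites[int(rng.integers(len(leaf_sites)))]
        # uniform draw over: toggle complement, or each of the other rules
        choice = int(rng.integers(n_rules))
        others = [r for r in range(n_rules) if r != leaf.rule_index]
        if choice == 0 or not others:
            new: Node = Leaf(leaf.rule_index, not leaf.complement)
        else:
            new = Leaf(others[choice - 1], leaf.complement)
        return LogicTree(_replace(tree.root, path, new)), move

    if move is Move.ALTERNATE_OPERATOR:
        path, node = internal_sites[int(rng.integers(len(internal_sites)))]
        flipped = Internal(Op.OR if node.op is Op.AND else Op.AND, node.left, node.right)
        return LogicTree(_replace(tree.root, path, flipped)), move

    if move in (Move.GROW_BRANCH, Move.SPLIT_LEAF):
        path, leaf = leaf_sites[int(rng.integers(len(leaf_sites)))]
        op = Op.AND if rng.integers(2) else Op.OR
        fresh = _random_leaf(rng, n_rules)
        branch = Internal(op, leaf, fresh) if move is Move.GROW_BRANCH else Internal(op, fresh, leaf)
        return LogicTree(_replace(tree.root, path, branch)), move

    if move is Move.PRUNE_BRANCH:
        path, node = internal_sites[int(rng.integers(len(internal_sites)))]
        kept = node.left if rng.integers(2) == 0 else node.right
        return LogicTree(_replace(tree.root, path, kept)), move

    # DELETE_LEAF: remove one leaf, promoting its sibling
    deletable = [(p, n) for p, n in leaf_sites if p]
    path, _ = deletable[int(rng.integers(len(deletable)))]
    parent_path = path[:-1]
    parent = tree.root
    for step in parent_path:
        parent = parent.left if step == 0 else parent.right
    sibling = parent.right if path[-1] == 0 else parent.left
    return LogicTree(_replace(tree.root, parent_path, sibling)), move


# ---------------------------------------------------------------------------
# annealing


class Method(str, enum.Enum):
    CLASSIFICATION = "classification"
    LOGISTIC = "logistic"


@dataclass(frozen=True)
class AnnealingConfig:
    """Tuning parameters of one annealing run.

    ``treesize`` caps the number of leaves; ``minmass`` is the minimum number
    of training instances on which a candidate tree must evaluate true. The
    acceptance probability for score-worsening moves decays geometrically
    from ``p_start`` to ``p_end`` over ``n_iterations``.
    """

    method: Method = Method.CLASSIFICATION
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    treesize: int = 5
    minmass: int = 4
    p_start: float = 0.1
    p_end: float = 0.0001
    n_iterations: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.treesize < 1:
            raise ValueError("treesize must be at least 1")
        if self.minmass < 0:
            raise ValueError("minmass must be non-negative")
        if not (self.p_start > self.p_end > 0):
            raise ValueError("schedule requires p_start > p_end > 0")


@dataclass
class FitResult:
    """Outcome of one annealing run for one target."""

    best_tree: LogicTree
    best_score: float
    score_trace: list[float]
    n_accepted_moves: int
    config: AnnealingConfig


def _acceptance_probability(t: int, config: AnnealingConfig) -> float:
    if config.n_iterations <= 1:
        return config.p_end
    frac = t / (config.n_iterations - 1)
    return config.p_start * (config.p_end / config.p_start) ** frac


def anneal(
    rule_matrix: np.ndarray, labels: Sequence[int], config: AnnealingConfig
) -> FitResult:
    """Fit one logic tree to a binary rule matrix by simulated annealing.

    Starts from a uniformly random single (uncomplemented) leaf and iterates
    :func:`propose_move`. Proposals violating ``treesize`` or ``minmass`` are
    rejected; score-improving (or equal) proposals are always accepted;
    worsening ones with the scheduled probability. The best feasible tree
    seen anywhere in the run is returned (first encountered wins ties). The
    run terminates early once a perfect score of 0 is found, which no further
    move can improve. Fully reproducible from ``config.seed``.
    """
    matrix = np.asarray(rule_matrix, dtype=bool)
    y = np.asarray(labels, dtype=bool)
    if matrix.ndim != 2 or matrix.shape[0] != y.shape[0]:
        raise ValueError("rule_matrix must be (instances x rules), aligned with labels")
    if matrix.shape[1] < 1:
        raise ValueError("at least one rule is required")
    if not y.any():
        raise ValueError("target has no positive instances and cannot be learned")
    if config.n_iterations < 1:
        raise ValueError("n_iterations must be at least 1")
    if config.method is Method.LOGISTIC and y.all():
        raise ValueError("logistic scoring requires both classes")

    n_rules = matrix.shape[1]
    rng = np.random.default_rng(config.seed)

    def score_of(preds: np.ndarray) -> float:
        if config.method is Method.CLASSIFICATION:
            return score_classification(preds, y, config.weights)
        return score_logistic(preds, y, config.weights)

    def feasible(tree: LogicTree, preds: np.ndarray) -> bool:
        return tree.n_leaves <= config.treesize and int(preds.sum()) >= config.minmass

    current = LogicTree(Leaf(int(rng.integers(n_rules)), False))
    current_preds = evaluate_tree_matrix(current, matrix)
    current_score = score_of(current_preds)

    best_tree: Optional[LogicTree] = None
    best_score = math.inf
    if feasible(current, current_preds):
        best_tree, best_score = current, current_score

    trace: list[float] = []
    n_accepted = 0
    for t in range(config.n_iterations):
        candidate, _ = propose_move(current, n_rules, rng)
        accept = False
        if candidate.n_leaves <= config.treesize:
            preds = evaluate_tree_matrix(candidate, matrix)
            if int(preds.sum()) >= config.minmass:
                cand_score = score_of(preds)
                if cand_score <= current_score:
                    accept = True
                else:
                    accept = rng.random() < _acceptance_probability(t, config)
                if accept:
                    current, current_preds, current_score = candidate, preds, cand_score
                    n_accepted += 1
                    if cand_score < best_score:
                        best_tree, best_score = candidate, cand_score
        trace.append(current_score)
        if best_score == 0.0:
            break

    if best_tree is None:
        logger.warning(
            "no tree satisfied minmass=%d during the run; returning the final state",
            config.minmass,
        )
        best_tree, best_score = current, current_score
    return FitResult(
        best_tree=best_tree,
        best_score=best_score,
        score_trace=trace,
        n_accepted_moves=n_accepted,
        config=config,
    )


# ---------------------------------------------------------------------------
# expression rendering / parsing


def tree_to_expression(tree: LogicTree, rule_ids: Sequence[str]) -> str:
    """Render the tree as a fully parenthesized infix AND/OR/NOT expression."""

    def render(node: Node) -> str:
        if isinstance(node, Leaf):
            if node.rule_index >= len(rule_ids):
                raise IndexError(f"no rule id for leaf index {node.rule_index}")
            name = rule_ids[node.rule_index]
            return f"(NOT {name})" if node.complement else name
        return f"({render(node.left)} {node.op.value} {render(node.right)})"

    return render(tree.root)


def parse_expression(text: str, rule_ids: Sequence[str]) -> LogicTree:
    """Parse an expression produced by :func:`tree_to_expression` (round-trip)."""
    index = {rid: i for i, rid in enumerate(rule_ids)}
    tokens = text.replace("(", " ( ").replace(")", " ) ").split()
    pos = 0

    def peek() -> str:
        if pos >= len(tokens):
            raise ValueError("unexpected end of expression")
        return tokens[pos]

    def take(expected: Optional[str] = None) -> str:
        nonlocal pos
        token = peek()
        if expected is not None and token != expected:
            raise ValueError(f"expected {expected!r}, found {token!r}")
        pos += 1
        return token

    def leaf_from(token: str, complement: bool) -> Leaf:
        if token not in index:
            raise ValueError(f"unknown rule id {token!r}")
        return Leaf(index[token], complement)

    def parse_node() -> Node:
        if peek() != "(":
            return leaf_from(take(), False)
        take("(")
        if peek() == "NOT":
            take("NOT")
            leaf = leaf_from(take(), True)
            take(")")
            return leaf
        left = parse_node()
        op = Op(take())
        right = parse_node()
        take(")")
        return Internal(op, left, right)

    root = parse_node()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens after expression: {tokens[pos:]}")
    return LogicTree(root)
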