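"""Independent oracles used by the test suite.

Each oracle re-derives an expected value by a different route than the
implementation under test: truth tables evaluated through Python's own
boolean operators, plain-loop exhaustive scans, and general-purpose numeric
optimization.
"""

from __future__ import annotations

import itertools
import math

from harmonizer.logictree import Internal, Leaf, LogicTree, Op


def python_expression(node) -> str:
    """Render a tree as a Python boolean expression over names a0, a1, ..."""
    if isinstance(node, Leaf):
        name = f"a{node.rule_index}"
        return f"(not {name})" if node.complement else name
    lhs = python_expression(node.left)
    rhs = python_expression(node.right)
    joiner = "and" if node.op is Op.AND else "or"
    return f"({lhs} {joiner} {rhs})"


def truth_table(tree: LogicTree, n_rules: int) -> list[bool]:
    """Evaluate a tree on every assignment via eval() of a Python expression."""
    expression = python_expression(tree.root)
    code = compile(expression, "<oracle>", "eval")
    table = []
    for bits in itertools.product([False, True], repeat=n_rules):
        scope = {f"a{i}": bits[i] for i in range(n_rules)}
        table.append(bool(eval(code, {"__builtins__": {}}, scope)))
    return table


def all_trees(n_leaves: int, n_rules: int):
    """Every distinct tree with exactly ``n_leaves`` leaves over ``n_rules`` rules."""
    if n_leaves == 1:
        for rule in range(n_rules):
            for complement in (False, True):
                yield Leaf(rule, complement)
        return
    for k in range(1, n_leaves):
        for left in all_trees(k, n_rules):
            for right in all_trees(n_leaves - k, n_rules):
                for op in (Op.AND, Op.OR):
                    yield Internal(op, left, right)


def random_tree(rng, n_leaves: int, n_rules: int):
    """A uniformly-shaped random tree (for sampled oracle comparisons)."""
    if n_leaves == 1:
        return Leaf(int(rng.integers(n_rules)), bool(rng.integers(2)))
    k = int(rng.integers(1, n_leaves))
    op = Op.AND if rng.integers(2) else Op.OR
    return Internal(op, random_tree(rng, k, n_rules), random_tree(rng, n_leaves - k, n_rules))


def brute_cutoff(values, labels, direction):
    """Plain-loop exhaustive scan over midpoint candidates; returns
    (cutoff, sensitivity, specificity) maximizing sens+spec, smallest cutoff
    on ties."""
    from fractions import Fraction

    distinct = sorted(set(values))
    candidates = [-math.inf]
    candidates += [(a + b) / 2 for a, b in zip(distinct, distinct[1:])]
    candidates += [math.inf]
    best = None
    for cutoff in candidates:
        tp = fp = tn = fn = 0
        for value, label in zip(values, labels):
            predicted = value > cutoff if direction == "gt" else value < cutoff
            if predicted and label:
                tp += 1
            elif predicted:
                fp += 1
            elif label:
                fn += 1
            else:
                tn += 1
        sens = Fraction(tp, tp + fn)
        spec = Fraction(tn, tn + fp)
        if best is None or sens + spec > best[0]:
            best = (sens + spec, cutoff, float(sens), float(spec))
    return best[1], best[2], best[3]


def logistic_deviance_oracle(x, y, w_pos, w_neg, cap=15.0):
    """Minimum weighted deviance of P(y)=expit(a+b·x) by numeric optimization."""
    import numpy as np
    from scipy.optimize import minimize

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.where(y == 1, w_pos, w_neg)

    def deviance(params):
        eta = np.clip(params[0] + params[1] * x, -cap, cap)
        p = 1.0 / (1.0 + np.exp(-eta))
        p = np.clip(p, 1e-300, 1 - 1e-16)
        return -2.0 * np.sum(w * (y * np.log(p) + (1 - y) * np.log(1 - p)))

    starts = [(0.0, 0.0), (0.0, 2.0), (1.0, -2.0), (-1.0, 1.0)]
    results = [minimize(deviance, s, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12}) for s in starts]
    return min(r.fun for r in results)
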