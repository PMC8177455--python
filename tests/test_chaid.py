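import itertools
import json
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2 as chi2_dist

from transrisk.chaid import (
    NOMINAL,
    ORDINAL,
    ChaidConfig,
    ChaidTree,
    PredictorSpec,
    binary_predictors,
    bonferroni_multiplier,
    grow_tree,
    merge_categories,
    pearson_chi2,
    select_split,
)


# ---------------------------------------------------------------------------
# chi-square

def test_chi2_homogeneous_table_is_null():
    stat, dof, p = pearson_chi2([[10, 10], [10, 10]])
    assert stat == 0.0
    assert p == 1.0


def test_chi2_perfect_association_closed_form():
    # N(ad-bc)^2 / (row and column margins) = 40*(400)^2/(20*20*20*20)
    stat, dof, p = pearson_chi2([[20, 0], [0, 20]])
    assert stat == pytest.approx(40.0)
    assert dof == 1
    assert p == pytest.approx(float(chi2_dist.sf(40, 1)), rel=1e-12)
    assert p == pytest.approx(2.54e-10, rel=5e-3)


def test_chi2_zero_margin_dropped_with_warning():
    with pytest.warns(UserWarning):
        stat, dof, p = pearson_chi2([[5, 5], [0, 0], [7, 3]])
    assert dof == 1


def test_chi2_single_effective_row_sentinel():
    with pytest.warns(UserWarning):
        stat, dof, p = pearson_chi2([[5, 5], [0, 0]])
    assert (stat, dof, p) == (0.0, 0, 1.0)


# ---------------------------------------------------------------------------
# Bonferroni multipliers

def _enumerate_nominal(c, r):
    """Count set partitions of c labelled categories into exactly r blocks."""
    partitions = set()
    for assignment in itertools.product(range(r), repeat=c):
        if len(set(assignment)) != r:
            continue
        blocks = frozenset(
            frozenset(i for i, a in enumerate(assignment) if a == b) for b in range(r)
        )
        partitions.add(blocks)
    return len(partitions)


def _enumerate_ordinal(c, r):
    """Count contiguous partitions: choose r-1 cut points among c-1 gaps."""
    return sum(1 for _ in itertools.combinations(range(c - 1), r - 1))


@pytest.mark.parametrize("kind", [NOMINAL, ORDINAL])
def test_bonferroni_equals_exhaustive_enumeration(kind):
    for c in range(2, 7):
        for r in range(1, c + 1):
            expected = _enumerate_nominal(c, r) if kind == NOMINAL else _enumerate_ordinal(c, r)
            assert bonferroni_multiplier(c, r, kind) == expected, (c, r, kind)


def test_bonferroni_binary_is_one():
    assert bonferroni_multiplier(2, 2, NOMINAL) == 1
    assert bonferroni_multiplier(2, 2, ORDINAL) == 1


def test_bonferroni_derived_values():
    assert bonferroni_multiplier(3, 2, NOMINAL) == 3
    assert bonferroni_multiplier(4, 2, ORDINAL) == math.comb(3, 1) == 3


def test_bonferroni_r_above_c_rejected():
    with pytest.raises(ValueError):
        bonferroni_multiplier(3, 4, NOMINAL)


# ---------------------------------------------------------------------------
# merging

def test_binary_predictor_unchanged_when_informative():
    rng = np.random.default_rng(0)
    v = rng.integers(0, 2, 400)
    y = (rng.random(400) < 0.2 + 0.5 * v).astype(int)
    ev = merge_categories(v, y, PredictorSpec("x", NOMINAL, (0, 1)))
    assert ev.groups == ((0,), (1,))
    assert ev.bonferroni == 1
    assert ev.adjusted_p == pytest.approx(ev.raw_p)


def test_equal_rate_categories_merge_first():
    # categories a and c have identical outcome rates; b differs strongly
    v = np.array(["a"] * 100 + ["b"] * 100 + ["c"] * 100)
    y = np.concatenate([np.repeat([0, 1], [80, 20]),
                        np.repeat([0, 1], [20, 80]),
                        np.repeat([0, 1], [80, 20])])
    ev = merge_categories(v, y, PredictorSpec("x", NOMINAL, ("a", "b", "c")))
    groups = {frozenset(g) for g in ev.groups}
    assert frozenset({"a", "c"}) in groups
    assert ev.bonferroni == 3


def test_constant_predictor_is_unusable():
    v = np.zeros(50, dtype=int)
    y = np.tile([0, 1], 25)
    ev = merge_categories(v, y, PredictorSpec("x", NOMINAL, (0, 1)))
    assert len(ev.groups) == 1
    assert ev.adjusted_p == 1.0


def test_null_binary_predictor_collapses():
    """Under independence the two categories usually merge to one."""
    rng = np.random.default_rng(5)
    collapsed = 0
    for _ in range(50):
        v = rng.integers(0, 2, 300)
        y = rng.integers(0, 2, 300)
        ev = merge_categories(v, y, PredictorSpec("x", NOMINAL, (0, 1)))
        if len(ev.groups) == 1:
            collapsed += 1
    assert collapsed > 40  # ~95% expected at alpha_merge=0.05


def test_adjusted_p_rarely_small_under_null():
    rng = np.random.default_rng(6)
    small = 0
    for _ in range(200):
        v = rng.integers(0, 3, 1000)
        y = rng.integers(0, 2, 1000)
        ev = merge_categories(v, y, PredictorSpec("x", NOMINAL, (0, 1, 2)))
        if ev.adjusted_p < 0.01:
            small += 1
    assert small <= 6  # nominal expectation 2 of 200


# ---------------------------------------------------------------------------
# split selection and growth

def _frame(**cols):
    return pd.DataFrame(cols)


def test_perfect_separator_selected():
    y = np.repeat([0, 1], 40)
    X = _frame(x=np.repeat([0, 1], 40))
    config = ChaidConfig(min_parent=20, min_child=5)
    ev = select_split(X, y, binary_predictors(["x"]), config)
    assert ev is not None
    assert ev.predictor == "x"
    assert ev.adjusted_p < 0.01


def test_winner_with_undersized_child_rejected_for_next_best():
    rng = np.random.default_rng(2)
    n = 400
    # x1: extremely strong but only 8 positives -> child below min_child
    x1 = np.zeros(n, dtype=int)
    x1[:8] = 1
    x2 = rng.integers(0, 2, n)
    y = np.where(x1 == 1, 1, (rng.random(n) < 0.25 + 0.4 * x2).astype(int))
    X = _frame(x1=x1, x2=x2)
    config = ChaidConfig(min_parent=50, min_child=20)
    ev = select_split(X, y, binary_predictors(["x1", "x2"]), config)
    assert ev is not None
    assert ev.predictor == "x2"


def test_no_split_below_min_parent():
    y = np.repeat([0, 1], 20)
    X = _frame(x=np.repeat([0, 1], 20))
    assert select_split(X, y, binary_predictors(["x"]), ChaidConfig(min_parent=100)) is None


def test_pure_outcome_gives_single_node_tree():
    X = _frame(x=np.tile([0, 1], 100))
    tree = grow_tree(X, np.ones(200, int), binary_predictors(["x"]),
                     ChaidConfig(min_parent=20, min_child=5))
    assert len(tree.nodes) == 1
    assert tree.root.is_leaf


def test_max_depth_one_caps_tree():
    rng = np.random.default_rng(3)
    n = 1000
    x1 = rng.integers(0, 2, n)
    x2 = rng.integers(0, 2, n)
    y = (rng.random(n) < 0.1 + 0.4 * x1 + 0.3 * x2).astype(int)
    tree = grow_tree(_frame(x1=x1, x2=x2), y, binary_predictors(["x1", "x2"]),
                     ChaidConfig(min_parent=50, min_child=20, max_depth=1))
    assert tree.depth() <= 1


def test_children_counts_sum_to_parent_everywhere():
    rng = np.random.default_rng(4)
    n = 2000
    X = _frame(**{f"x{i}": rng.integers(0, 2, n) for i in range(4)})
    y = (rng.random(n) < 0.1 + 0.3 * X["x0"] + 0.2 * X["x1"] * X["x2"]).astype(int)
    tree = grow_tree(X, y, binary_predictors(list(X.columns)),
                     ChaidConfig(min_parent=100, min_child=30))
    assert len(tree.nodes) > 1
    for node in tree.nodes.values():
        if node.children:
            assert sum(tree.nodes[c].n for c in node.children) == node.n
            assert sum(tree.nodes[c].n_cases for c in node.children) == node.n_cases
            assert node.adjusted_p < tree.config.alpha_split


def test_routing_training_rows_reproduces_leaf_counts():
    rng = np.random.default_rng(7)
    n = 1200
    X = _frame(a=rng.integers(0, 2, n), b=rng.integers(0, 2, n))
    y = (rng.random(n) < 0.15 + 0.45 * X["a"]).astype(int)
    tree = grow_tree(X, y, binary_predictors(["a", "b"]), ChaidConfig(min_parent=80, min_child=30))
    routed = tree.predict(X)
    counts = routed["node_id"].value_counts()
    for leaf in tree.leaves():
        assert counts.get(leaf.node_id, 0) == leaf.n


def test_root_only_tree_predicts_base_rate():
    X = _frame(x=np.tile([0, 1], 30))
    y = np.tile([0, 0, 1], 20)
    tree = grow_tree(X, y, binary_predictors(["x"]), ChaidConfig(min_parent=1000))
    routed = tree.predict(X)
    assert np.allclose(routed["case_fraction"], y.mean())


def test_unseen_category_falls_back_to_largest_child():
    v = np.array(["a"] * 150 + ["b"] * 50)
    y = np.concatenate([np.repeat([0, 1], [120, 30]), np.repeat([0, 1], [5, 45])])
    spec = PredictorSpec("x", NOMINAL, ("a", "b", "z"))
    tree = grow_tree(_frame(x=v), y, [spec], ChaidConfig(min_parent=50, min_child=20))
    assert not tree.root.is_leaf
    node_id, frac, fallback = tree.route({"x": "z"})
    assert fallback
    assert tree.nodes[node_id].n == 150  # the larger child


def test_serialization_round_trip_and_determinism():
    rng = np.random.default_rng(9)
    n = 1500
    X = _frame(**{f"x{i}": rng.integers(0, 2, n) for i in range(5)})
    y = (rng.random(n) < 0.1 + 0.35 * X["x3"] + 0.2 * X["x1"]).astype(int)
    cfg = ChaidConfig(min_parent=100, min_child=40)
    preds = binary_predictors(list(X.columns))
    t1 = grow_tree(X, y, preds, cfg)
    t2 = grow_tree(X.copy(), y.copy(), preds, cfg)
    assert t1.to_json() == t2.to_json()  # byte-identical serialized tree
    back = ChaidTree.from_json(t1.to_json())
    assert back.to_json() == t1.to_json()
    assert json.loads(t1.to_json())["nodes"][0]["n"] == n


def test_dot_export_mentions_labels_and_nodes():
    X = _frame(x=np.repeat([0, 1], 100))
    y = np.concatenate([np.repeat([0, 1], [90, 10]), np.repeat([0, 1], [30, 70])])
    tree = grow_tree(X, y, binary_predictors(["x"]), ChaidConfig(min_parent=50, min_child=20))
    dot = tree.to_dot({"x": "sadness"})
    assert "digraph" in dot and "sadness" in dot and "n0 -> n1" in dot
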