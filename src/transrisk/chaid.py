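"""Chi-Square Automatic Interaction Detection (CHAID) for a binary outcome.

The classic recursive-partitioning recipe: within every node, each
candidate predictor first has its categories merged pairwise while the
most similar pair (adjacent pair, for ordinal predictors) is
statistically indistinguishable on the outcome; the resulting grouping
is scored with a Pearson chi-square test and Bonferroni-multiplied for
the number of ways the original categories can be partitioned.  The
predictor with the smallest adjusted p-value splits the node, subject to
a priori stopping rules (minimum node sizes, maximum depth, significance
threshold).  Splits are additionally Bonferroni-corrected across the
candidate predictors, so the tree-wide type-I error under a null cohort
stays near the nominal level.

The merge step is merge-only (no re-splitting of merged compounds),
which is exact for binary predictors - the dominant case here - and a
documented simplification of Kass's full algorithm otherwise.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

NOMINAL = "free-nominal"
ORDINAL = "monotonic-ordinal"


@dataclass(frozen=True)
class ChaidConfig:
    """Stopping and significance rules, set a priori.

    ``alpha_split`` gates Bonferroni-adjusted split p-values; ``alpha_merge``
    governs category merging; node-size floors and ``max_depth`` are the
    conventional CHAID defaults.  ``adjust_for_predictors`` additionally
    multiplies each split p-value by the number of candidate predictors,
    giving family-wise control across the predictor battery.
    """

    alpha_split: float = 0.01
    alpha_merge: float = 0.05
    min_parent: int = 100
    min_child: int = 50
    max_depth: int = 3
    bonferroni: bool = True
    adjust_for_predictors: bool = True

    def __post_init__(self):
        if not (0 < self.alpha_split < 1 and 0 < self.alpha_merge < 1):
            raise ValueError("alpha values must lie in (0, 1)")
        if self.min_child > self.min_parent:
            raise ValueError("min_child must not exceed min_parent")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass(frozen=True)
class PredictorSpec:
    """A candidate predictor: name, measurement type and ordered category list."""

    name: str
    kind: str = NOMINAL
    categories: tuple = (0, 1)

    def __post_init__(self):
        if self.kind not in (NOMINAL, ORDINAL):
            raise ValueError(f"unknown predictor kind {self.kind!r}")
        if len(self.categories) < 2:
            raise ValueError("a predictor needs at least 2 categories")


@dataclass
class SplitEvaluation:
    """A scored grouping of one predictor's categories inside a node."""

    predictor: str
    groups: tuple[tuple, ...]  # partition of the observed categories
    chi2: float
    df: int
    raw_p: float
    bonferroni: int
    adjusted_p: float


def pearson_chi2(table) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction on an r x c count table.

    Rows or columns with a zero margin are dropped (with a warning); a table
    left with fewer than two rows or columns carries no discriminating power
    and returns the sentinel (0, 0, 1).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    keep_r = t.sum(axis=1) > 0
    keep_c = t.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping zero-margin rows/columns from chi-square table", stacklevel=2)
        t = t[keep_r][:, keep_c]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return 0.0, 0, 1.0
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    stat = float(((t - expected) ** 2 / expected).sum())
    dof = (t.shape[0] - 1) * (t.shape[1] - 1)
    return stat, dof, float(chi2_dist.sf(stat, dof))


def bonferroni_multiplier(c: int, r: int, kind: str = NOMINAL) -> int:
    """Number of distinct ways to reduce c categories to r groups.

    Ordinal predictors allow only contiguous groupings: C(c-1, r-1).
    Nominal predictors allow any partition into r non-empty groups:
    the Stirling number of the second kind, evaluated by its alternating
    closed form sum_i (-1)^i (r-i)^c / (i! (r-i)!).
    """
    if r > c:
        raise ValueError("merged group count r cannot exceed category count c")
    if r < 1:
        raise ValueError("r must be >= 1")
    if kind == ORDINAL:
        return math.comb(c - 1, r - 1)
    total = Fraction(0)
    for i in range(r):
        total += Fraction((-1) ** i * (r - i) ** c, math.factorial(i) * math.factorial(r - i))
    return int(total)


def _group_counts(values: np.ndarray, outcome: np.ndarray, groups: list[list]) -> np.ndarray:
    out = np.zeros((len(groups), 2), dtype=float)
    for gi, grp in enumerate(groups):
        m = np.isin(values, grp)
        out[gi, 1] = outcome[m].sum()
        out[gi, 0] = m.sum() - out[gi, 1]
    return out


def merge_categories(
    values, outcome, spec: PredictorSpec, config: ChaidConfig = ChaidConfig()
) -> SplitEvaluation:
    """Merge a predictor's categories bottom-up and score the final grouping.

    Repeatedly finds the pair of groups (adjacent, for ordinal predictors)
    whose 2x2 outcome table has the largest p-value and merges it while that
    p exceeds ``alpha_merge``; two remaining indistinguishable groups collapse
    to one, marking the predictor unusable in this node (r=1, adjusted p=1).
    """
    v = np.asarray(values)
    y = np.asarray(outcome).astype(int)
    present = [c for c in spec.categories if c in set(v.tolist())]
    unknown = set(v.tolist()) - set(spec.categories)
    if unknown:
        raise ValueError(f"values outside declared categories for {spec.name!r}: {sorted(unknown)}")
    groups: list[list] = [[c] for c in present]
    c_present = len(present)
    if c_present < 2:
        return SplitEvaluation(spec.name, tuple(tuple(g) for g in groups), 0.0, 0, 1.0, 1, 1.0)

    while len(groups) >= 2:
        counts = _group_counts(v, y, groups)
        if spec.kind == ORDINAL:
            pairs = [(i, i + 1) for i in range(len(groups) - 1)]
        else:
            pairs = [(i, j) for i in range(len(groups)) for j in range(i + 1, len(groups))]
        best_pair, best_p = None, -1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i, j in pairs:
                _, _, p = pearson_chi2(counts[[i, j]])
                if p > best_p:
                    best_pair, best_p = (i, j), p
        if best_p <= config.alpha_merge:
            break
        i, j = best_pair
        groups[i] = groups[i] + groups[j]
        del groups[j]

    r = len(groups)
    grouping = tuple(tuple(g) for g in groups)
    if r == 1:
        return SplitEvaluation(spec.name, grouping, 0.0, 0, 1.0, 1, 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, dof, raw_p = pearson_chi2(_group_counts(v, y, groups))
    mult = bonferroni_multiplier(c_present, r, spec.kind) if config.bonferroni else 1
    return SplitEvaluation(spec.name, grouping, stat, dof, raw_p, mult, min(1.0, mult * raw_p))


def select_split(
    X: pd.DataFrame,
    outcome,
    predictors: list[PredictorSpec],
    config: ChaidConfig = ChaidConfig(),
) -> SplitEvaluation | None:
    """Best admissible split of a node, or None.

    Every predictor is merged and scored; candidates are ranked by adjusted
    p-value (after the optional across-predictor Bonferroni factor), ties
    broken by larger chi-square then predictor order.  The best candidate
    that is significant at ``alpha_split`` and leaves every child at least
    ``min_child`` rows wins; an oversized-looking winner that would create an
    undersized child is rejected and the next-best considered.
    """
    y = np.asarray(outcome).astype(int)
    if len(y) < config.min_parent:
        return None
    m = len(predictors)
    candidates: list[tuple[float, float, int, SplitEvaluation]] = []
    for order, spec in enumerate(predictors):
        ev = merge_categories(X[spec.name].to_numpy(), y, spec, config)
        if len(ev.groups) < 2:
            continue
        sel_p = min(1.0, ev.adjusted_p * m) if config.adjust_for_predictors else ev.adjusted_p
        candidates.append((sel_p, -ev.chi2, order, ev))
    for sel_p, _, _, ev in sorted(candidates, key=lambda t: (t[0], t[1], t[2])):
        if sel_p >= config.alpha_split:
            break  # sorted: everything after is no better
        sizes = [np.isin(X[ev.predictor].to_numpy(), grp).sum() for grp in ev.groups]
        if min(sizes) >= config.min_child:
            ev.adjusted_p = sel_p
            return ev
    return None


@dataclass
class ChaidNode:
    """One node of the fitted tree; terminal nodes have no split."""

    node_id: int
    depth: int
    n: int
    n_cases: int
    split_predictor: str | None = None
    split_groups: tuple[tuple, ...] | None = None
    adjusted_p: float | None = None
    children: list[int] = field(default_factory=list)
    parent: int | None = None

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n if self.n else float("nan")

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class ChaidTree:
    """A fitted bifurcating (more generally, multiway) classification tree."""

    nodes: dict[int, ChaidNode]
    predictors: list[PredictorSpec]
    config: ChaidConfig

    @property
    def root(self) -> ChaidNode:
        return self.nodes[0]

    def leaves(self) -> list[ChaidNode]:
        return [nd for nd in self.nodes.values() if nd.is_leaf]

    def depth(self) -> int:
        return max(nd.depth for nd in self.nodes.values())

    def route(self, record: dict) -> tuple[int, float, bool]:
        """Route one record; returns (leaf id, training case fraction, fallback_used)."""
        node = self.root
        fallback = False
        while not node.is_leaf:
            value = record[node.split_predictor]
            child_id = None
            for grp, cid in zip(node.split_groups, node.children):
                if value in grp:
                    child_id = cid
                    break
            if child_id is None:  # unseen category: follow the largest child
                child_id = max(node.children, key=lambda c: self.nodes[c].n)
                fallback = True
            node = self.nodes[child_id]
        return node.node_id, node.case_fraction, fallback

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-record terminal node id and training case fraction."""
        rows = []
        cols = {spec.name for spec in self.predictors}
        missing = cols - set(X.columns)
        needed = {nd.split_predictor for nd in self.nodes.values() if nd.split_predictor}
        if needed & missing:
            raise KeyError(f"missing predictor column(s): {sorted(needed & missing)}")
        records = X.to_dict("records")
        for rec in records:
            node_id, frac, fb = self.route(rec)
            rows.append((node_id, frac, fb))
        return pd.DataFrame(rows, columns=["node_id", "case_fraction", "fallback"], index=X.index)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "config": vars(self.config).copy(),
            "predictors": [
                {"name": p.name, "kind": p.kind, "categories": list(p.categories)}
                for p in self.predictors
            ],
            "nodes": [
                {
                    "node_id": nd.node_id,
                    "depth": nd.depth,
                    "n": nd.n,
                    "n_cases": nd.n_cases,
                    "split_predictor": nd.split_predictor,
                    "split_groups": [list(g) for g in nd.split_groups] if nd.split_groups else None,
                    "adjusted_p": nd.adjusted_p,
                    "children": nd.children,
                    "parent": nd.parent,
                }
                for nd in sorted(self.nodes.values(), key=lambda n: n.node_id)
            ],
        }

    def to_json(self, path=None, **kw) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, **kw)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "ChaidTree":
        config = ChaidConfig(**data["config"])
        predictors = [
            PredictorSpec(p["name"], p["kind"], tuple(p["categories"])) for p in data["predictors"]
        ]
        nodes = {}
        for nd in data["nodes"]:
            nodes[nd["node_id"]] = ChaidNode(
                node_id=nd["node_id"],
                depth=nd["depth"],
                n=nd["n"],
                n_cases=nd["n_cases"],
                split_predictor=nd["split_predictor"],
                split_groups=tuple(tuple(g) for g in nd["split_groups"]) if nd["split_groups"] else None,
                adjusted_p=nd["adjusted_p"],
                children=list(nd["children"]),
                parent=nd["parent"],
            )
        return cls(nodes, predictors, config)

    @classmethod
    def from_json(cls, source) -> "ChaidTree":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            try:
                data = json.loads(source)
            except (ValueError, TypeError):
                with open(source) as fh:
                    data = json.load(fh)
        return cls.from_dict(data)

    def to_dot(self, labels: dict[str, str] | None = None) -> str:
        """Graphviz DOT export with per-node n, case % and split annotations."""
        labels = labels or {}
        lines = ["digraph chaid {", "  node [shape=box, fontsize=10];"]
        for nd in sorted(self.nodes.values(), key=lambda n: n.node_id):
            pct = 100.0 * nd.case_fraction
            txt = f"Node {nd.node_id}\\nn={nd.n}\\ncases {pct:.1f}%"
            if nd.split_predictor is not None:
                name = labels.get(nd.split_predictor, nd.split_predictor)
                txt += f"\\nsplit: {name} (p={nd.adjusted_p:.3g})"
            lines.append(f'  n{nd.node_id} [label="{txt}"];')
        for nd in self.nodes.values():
            if nd.split_groups is None:
                continue
            for grp, cid in zip(nd.split_groups, nd.children):
                glabel = ",".join(str(g) for g in grp)
                lines.append(f'  n{nd.node_id} -> n{cid} [label="{glabel}"];')
        lines.append("}")
        return "\n".join(lines)


def grow_tree(
    X: pd.DataFrame,
    outcome,
    predictors: list[PredictorSpec],
    config: ChaidConfig = ChaidConfig(),
) -> ChaidTree:
    """Grow a CHAID tree breadth-first from the root.

    Recursion stops at ``max_depth``, at pure or undersized nodes, and when no
    predictor passes the adjusted significance threshold.  Node ids are
    assigned breadth-first, so the result is deterministic given data, the
    predictor order and the configuration.
    """
    y = np.asarray(outcome).astype(int)
    if len(X) == 0:
        raise ValueError("empty data")
    if len(X) != len(y):
        raise ValueError("X and outcome lengths differ")
    nodes: dict[int, ChaidNode] = {}
    root = ChaidNode(0, 0, len(y), int(y.sum()))
    nodes[0] = root
    queue: list[tuple[ChaidNode, np.ndarray]] = [(root, np.arange(len(y)))]
    next_id = 1
    while queue:
        node, idx = queue.pop(0)
        if node.depth >= config.max_depth or node.n < config.min_parent:
            continue
        if node.n_cases in (0, node.n):  # pure node
            continue
        ev = select_split(X.iloc[idx], y[idx], predictors, config)
        if ev is None:
            continue
        node.split_predictor = ev.predictor
        node.split_groups = ev.groups
        node.adjusted_p = ev.adjusted_p
        values = X[ev.predictor].to_numpy()[idx]
        for grp in ev.groups:
            sub = idx[np.isin(values, grp)]
            child = ChaidNode(next_id, node.depth + 1, len(sub), int(y[sub].sum()), parent=node.node_id)
            nodes[next_id] = child
            node.children.append(next_id)
            next_id += 1
            queue.append((child, sub))
    return ChaidTree(nodes, list(predictors), config)


def binary_predictors(names: list[str]) -> list[PredictorSpec]:
    """Convenience: free-nominal binary PredictorSpecs for 0/1 columns."""
    return [PredictorSpec(n, NOMINAL, (0, 1)) for n in names]
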