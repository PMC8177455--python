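"""Cross-validated tree evaluation on a held-out half of the cohort.

The train-test split assigns whole families to one fold (twin pairs
never straddle folds, preventing leakage through shared liability), the
fitted tree is applied to the test fold, and the report carries per-node
test counts and case percentages, PPV/NPV-style path summaries and the
model AUC (leaf case fractions as scores) with a family-cluster
bootstrap interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .accuracy import AccuracyEstimate, mann_whitney_auc
from .chaid import ChaidTree
from .cohort import Cohort


@dataclass
class SplitPlan:
    """Randomized assignment of families (or records) to train/test folds."""

    seed: int = 0
    train_fraction: float = 0.5
    family_aware: bool = True
    assignment: dict[str, str] = field(default_factory=dict)  # family_id -> "train"|"test"


def train_test_split(cohort: Cohort, plan: SplitPlan) -> tuple[Cohort, Cohort]:
    """Split the cohort by family according to the plan's seed.

    Families are visited in a seeded random order and assigned to the training
    fold until it holds at least ``train_fraction`` of the records; the plan's
    ``assignment`` is filled in for reproducibility.  With ``family_aware``
    off, each record is its own unit.
    """
    df = cohort.df
    units = df["family_id"].to_numpy() if plan.family_aware else df["participant_id"].to_numpy()
    unique_units = pd.unique(units)
    if plan.family_aware and len(unique_units) < 2:
        raise ValueError("need at least two families to split")
    rng = np.random.default_rng(plan.seed)
    order = rng.permutation(len(unique_units))
    sizes = pd.Series(units).value_counts()
    target = plan.train_fraction * len(df)
    train_units = set()
    got = 0
    for i in order:
        if got >= target:
            break
        u = unique_units[i]
        train_units.add(u)
        got += int(sizes[u])
    plan.assignment = {str(u): ("train" if u in train_units else "test") for u in unique_units}
    mask = np.array([u in train_units for u in units])
    return cohort.subset(mask), cohort.subset(~mask)


@dataclass
class PathSummary:
    node_id: int
    n: int
    case_pct: float
    kind: str  # "PPV" | "NPV"
    value: float  # PPV = case %, NPV = 100 - case %
    rule: str


@dataclass
class TreeReport:
    """Test-set performance of a fitted tree."""

    node_table: pd.DataFrame  # per terminal node: n, cases, case_pct, rule
    paths: list[PathSummary]
    auc: AccuracyEstimate
    n_test: int
    fallback_count: int = 0

    def render(self, max_rule: int = 60) -> str:
        lines = [f"Tree evaluation on test fold (n = {self.n_test})", str(self.auc), ""]
        lines.append(f"{'node':>4s} {'n':>6s} {'case %':>7s} {'type':>5s}  rule")
        for p in self.paths:
            rule = p.rule if len(p.rule) <= max_rule else p.rule[: max_rule - 3] + "..."
            lines.append(f"{p.node_id:4d} {p.n:6d} {p.case_pct:7.1f} {p.kind:>5s}  {rule}")
        return "\n".join(lines)


def describe_path(tree: ChaidTree, node_id: int, labels: dict[str, str] | None = None) -> str:
    """Human-readable conjunction of split conditions from root to node."""
    if node_id not in tree.nodes:
        raise KeyError(f"unknown node id {node_id}")
    labels = labels or {}
    clauses: list[str] = []
    node = tree.nodes[node_id]
    while node.parent is not None:
        parent = tree.nodes[node.parent]
        pos = parent.children.index(node.node_id)
        grp = parent.split_groups[pos]
        name = labels.get(parent.split_predictor, parent.split_predictor)
        if set(grp) == {1}:
            clauses.append(f"{name} endorsed")
        elif set(grp) == {0}:
            clauses.append(f"{name} not endorsed")
        else:
            clauses.append(f"{name} in {{{', '.join(str(g) for g in grp)}}}")
        node = parent
    if not clauses:
        return "(all participants)"
    return " AND ".join(reversed(clauses))


def _cluster_bootstrap_auc(scores, y, families, n_boot, rng) -> tuple[float, float]:
    fam_ids, fam_index = np.unique(np.asarray(families), return_inverse=True)
    members = [np.flatnonzero(fam_index == i) for i in range(len(fam_ids))]
    stats = []
    for _ in range(n_boot):
        pick = rng.integers(0, len(members), size=len(members))
        idx = np.concatenate([members[i] for i in pick])
        yb = y[idx]
        if yb.min() == yb.max():
            continue
        stats.append(mann_whitney_auc(scores[idx], yb))
    if not stats:
        return float("nan"), float("nan")
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(lo), float(hi)


def evaluate_tree(
    tree: ChaidTree,
    test: Cohort,
    outcome,
    extra_columns: pd.DataFrame | None = None,
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> TreeReport:
    """Route the test fold through a trained tree and report node statistics.

    Scores are the training case fractions at the routed terminal node; the
    AUC interval uses a family-cluster bootstrap.  Case-enriched terminal
    paths (test case % above the fold's base rate) are summarised as PPVs,
    case-depleted ones as NPVs (100 - case %).
    """
    if len(test) == 0:
        raise ValueError("empty test fold")
    rng = np.random.default_rng(rng)
    y = np.asarray(outcome).astype(int)
    X = test.df[[c for c in test.item_codes if c in test.df.columns]].copy()
    if extra_columns is not None:
        for col in extra_columns.columns:
            X[col] = extra_columns[col].to_numpy()
    routed = tree.predict(X)
    labels = {it.code: it.label for it in test.registry}

    base_rate = y.mean()
    rows, paths = [], []
    for leaf in sorted(tree.leaves(), key=lambda nd: nd.node_id):
        m = (routed["node_id"] == leaf.node_id).to_numpy()
        n = int(m.sum())
        cases = int(y[m].sum())
        pct = 100.0 * cases / n if n else float("nan")
        rule = describe_path(tree, leaf.node_id, labels)
        rows.append({"node_id": leaf.node_id, "n": n, "cases": cases, "case_pct": pct, "rule": rule})
        if n:
            if pct / 100.0 >= base_rate:
                paths.append(PathSummary(leaf.node_id, n, pct, "PPV", pct, rule))
            else:
                paths.append(PathSummary(leaf.node_id, n, pct, "NPV", 100.0 - pct, rule))

    scores = routed["case_fraction"].to_numpy()
    if np.unique(scores).size < 2 or y.min() == y.max():
        auc = AccuracyEstimate("AUC", 50.0, float("nan"), float("nan"))
    else:
        point = mann_whitney_auc(scores, y)
        lo, hi = _cluster_bootstrap_auc(scores, y, test.df["family_id"].to_numpy(), n_boot, rng)
        auc = AccuracyEstimate("AUC", 100 * point, 100 * lo, 100 * hi)
    return TreeReport(
        node_table=pd.DataFrame(rows),
        paths=paths,
        auc=auc,
        n_test=len(test),
        fallback_count=int(routed["fallback"].sum()),
    )
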