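"""Diagnostic accuracy of binary risk exposures against caseness.

PPV and NPV are computed through Bayes' theorem from sensitivity,
specificity and prevalence (algebraically identical to the direct count
ratios on the same 2x2 table), with standard-logit 95% confidence
intervals.  AUC is the Mann-Whitney probability of concordance (ties
counted 1/2); for a single binary exposure it equals (Se+Sp)/2.
Covariate-adjusted AUCs come from an IRLS-fitted logistic model with a
family-cluster bootstrap interval, so twin/sibling clustering is
honoured in interval estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .cohort import Cohort


class UndefinedMetricError(ValueError):
    """A margin of the 2x2 table is empty, so the metric has no estimate."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """TP/FP/FN/TN counts of a binary classifier against binary caseness."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class AccuracyEstimate:
    """A metric on the percentage scale with its confidence interval."""

    metric: str
    estimate: float
    lo: float
    hi: float
    level: float = 0.95

    def __str__(self) -> str:
        return f"{self.metric} {self.estimate:.2f} (95% CI {self.lo:.2f}, {self.hi:.2f})"


def build_2x2(exposure, outcome) -> ContingencyTable2x2:
    """Cross-tabulate aligned binary vectors into TP/FP/FN/TN counts."""
    e = np.asarray(exposure).astype(int)
    o = np.asarray(outcome).astype(int)
    if e.shape != o.shape:
        raise ValueError("exposure and outcome must have equal length")
    return ContingencyTable2x2(
        tp=int(((e == 1) & (o == 1)).sum()),
        fp=int(((e == 1) & (o == 0)).sum()),
        fn=int(((e == 0) & (o == 1)).sum()),
        tn=int(((e == 0) & (o == 0)).sum()),
    )


def proportion_ci(successes: int, total: int, level: float = 0.95) -> tuple[float, float]:
    """Standard-logit interval for a binomial proportion, on the [0, 1] scale.

    logit(p) +/- z * sqrt(1/successes + 1/failures), back-transformed.
    Degenerate proportions (0 or all successes) get a +0.5 adjustment to
    both cells for the interval only; the boundary side is pinned at 0/1.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= successes <= total:
        raise ValueError("successes must lie in [0, total]")
    z = norm.ppf(0.5 + level / 2)
    s, f = float(successes), float(total - successes)
    degenerate = s == 0 or f == 0
    if degenerate:
        s, f = s + 0.5, f + 0.5
    p = s / (s + f)
    half = z * np.sqrt(1.0 / s + 1.0 / f)
    lg = np.log(p / (1 - p))
    lo = 1.0 / (1.0 + np.exp(-(lg - half)))
    hi = 1.0 / (1.0 + np.exp(-(lg + half)))
    if successes == 0:
        lo = 0.0
    if successes == total:
        hi = 1.0
    return float(lo), float(hi)


def _estimate(metric: str, successes: int, total: int, level: float) -> AccuracyEstimate:
    lo, hi = proportion_ci(successes, total, level)
    return AccuracyEstimate(metric, 100.0 * successes / total, 100.0 * lo, 100.0 * hi, level)


def predictive_values(table: ContingencyTable2x2, level: float = 0.95) -> dict[str, AccuracyEstimate]:
    """PPV, NPV (via Bayes' theorem), sensitivity and specificity with logit CIs.

    PPV = Se*p / (Se*p + (1-Sp)(1-p)) and NPV = Sp(1-p) / (Sp(1-p) + (1-Se)p)
    where p is prevalence; both reduce exactly to tp/(tp+fp) and tn/(tn+fn).
    """
    t = table
    if t.n == 0:
        raise UndefinedMetricError("empty table")
    if t.tp + t.fn == 0 or t.tn + t.fp == 0:
        raise UndefinedMetricError("single-class outcome: Se/Sp undefined")
    if t.tp + t.fp == 0:
        raise UndefinedMetricError("no positive classifications: PPV undefined")
    if t.tn + t.fn == 0:
        raise UndefinedMetricError("no negative classifications: NPV undefined")
    se = t.tp / (t.tp + t.fn)
    sp = t.tn / (t.tn + t.fp)
    p = (t.tp + t.fn) / t.n
    ppv = se * p / (se * p + (1 - sp) * (1 - p))
    npv = sp * (1 - p) / (sp * (1 - p) + (1 - se) * p)
    out = {
        "PPV": _estimate("PPV", t.tp, t.tp + t.fp, level),
        "NPV": _estimate("NPV", t.tn, t.tn + t.fn, level),
        "Se": _estimate("Se", t.tp, t.tp + t.fn, level),
        "Sp": _estimate("Sp", t.tn, t.tn + t.fp, level),
    }
    # Bayes form is the published definition; keep it as the point estimate
    # (it agrees with the count ratio to floating tolerance by construction).
    out["PPV"] = AccuracyEstimate("PPV", 100 * ppv, out["PPV"].lo, out["PPV"].hi, level)
    out["NPV"] = AccuracyEstimate("NPV", 100 * npv, out["NPV"].lo, out["NPV"].hi, level)
    return out


def mann_whitney_auc(scores, outcome) -> float:
    """AUC as the probability a random case outscores a random non-case (ties 1/2)."""
    s = np.asarray(scores, dtype=float)
    o = np.asarray(outcome).astype(int)
    n1 = int(o.sum())
    n0 = len(o) - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("AUC needs at least one case and one non-case")
    ranks = rankdata(s)  # midranks handle ties
    return float((ranks[o == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _hanley_mcneil_se(auc: float, n1: int, n0: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    return float(np.sqrt(max(var, 0.0)))


def auc_scores(scores, outcome, level: float = 0.95) -> AccuracyEstimate:
    """Mann-Whitney AUC with a Hanley-McNeil confidence interval (percentages)."""
    o = np.asarray(outcome).astype(int)
    auc = mann_whitney_auc(scores, o)
    n1 = int(o.sum())
    se = _hanley_mcneil_se(auc, n1, len(o) - n1)
    z = norm.ppf(0.5 + level / 2)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return AccuracyEstimate("AUC", 100 * auc, 100 * lo, 100 * hi, level)


def _fit_logit_probs(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """IRLS logistic fit (statsmodels GLM/Binomial); returns fitted probabilities."""
    import statsmodels.api as sm

    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=100)
    except Exception as exc:  # pragma: no cover - separation is data dependent
        raise RuntimeError(f"logistic fit did not converge: {exc}") from exc
    if not res.converged:
        raise RuntimeError("logistic fit did not converge (possible separation)")
    return np.asarray(res.fittedvalues)


def _design(exposures: np.ndarray, influence: np.ndarray | None) -> np.ndarray:
    expo = np.asarray(exposures, float)
    if expo.ndim == 1:
        expo = expo[:, None]
    cols = [np.ones(expo.shape[0])]
    cols.extend(expo.T)
    if influence is not None:
        cats = np.unique(influence)
        for c in cats[1:]:  # first category is the reference
            cols.append((np.asarray(influence) == c).astype(float))
    return np.column_stack(cols)


def adjusted_auc(
    exposures,
    outcome,
    families,
    influence=None,
    n_boot: int = 2000,
    level: float = 0.95,
    rng: np.random.Generator | int | None = None,
) -> AccuracyEstimate:
    """AUC of a logistic model (exposures + influence-category indicators).

    The point estimate applies Mann-Whitney concordance to the fitted
    probabilities.  The interval resamples whole families with replacement
    (percentile cluster bootstrap), honouring twin/sibling clustering.
    """
    rng = np.random.default_rng(rng)
    y = np.asarray(outcome).astype(int)
    X = _design(exposures, influence)
    fam = np.asarray(families)
    probs = _fit_logit_probs(X, y)
    point = mann_whitney_auc(probs, y)

    fam_ids, fam_index = np.unique(fam, return_inverse=True)
    members = [np.flatnonzero(fam_index == i) for i in range(len(fam_ids))]
    stats = []
    for _ in range(n_boot):
        pick = rng.integers(0, len(members), size=len(members))
        idx = np.concatenate([members[i] for i in pick])
        yb = y[idx]
        if yb.min() == yb.max():
            continue
        try:
            pb = _fit_logit_probs(X[idx], yb)
            stats.append(mann_whitney_auc(pb, yb))
        except RuntimeError:
            continue
    alpha = 1 - level
    if stats:
        lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    else:  # pragma: no cover - only with n_boot=0
        lo = hi = point
    return AccuracyEstimate("AUC", 100 * point, 100 * float(lo), 100 * float(hi), level)


_UNDEFINED = AccuracyEstimate("undefined", float("nan"), float("nan"), float("nan"))


def _metrics_row(exposure, outcome, level=0.95) -> dict[str, AccuracyEstimate]:
    try:
        table = build_2x2(exposure, outcome)
        vals = predictive_values(table, level)
        auc = auc_scores(np.asarray(exposure, float), outcome, level)
        return {"PPV": vals["PPV"], "NPV": vals["NPV"], "AUC": auc}
    except UndefinedMetricError:
        return {"PPV": _UNDEFINED, "NPV": _UNDEFINED, "AUC": _UNDEFINED}


def risk_table(cohort: Cohort, profiles: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Predictive-value table: FH, high symptom load and SubT against caseness,
    then load and SubT stratified by family-history status."""
    y = profiles["case"].to_numpy()
    rows: list[tuple[str, dict]] = [
        ("Family History", _metrics_row(profiles["fh"], y, level)),
        ("Symptom Load", _metrics_row(profiles["high_load"], y, level)),
        ("Subthreshold Syndrome", _metrics_row(profiles["subt_any"], y, level)),
    ]
    for label, col in (("Symptom Load", "high_load"), ("Subthreshold Syndrome", "subt_any")):
        for fh_val, tag in ((0, "FH-"), (1, "FH+")):
            m = (profiles["fh"] == fh_val).to_numpy()
            if m.sum() == 0:
                rows.append((f"{label} {tag}", {"PPV": _UNDEFINED, "NPV": _UNDEFINED, "AUC": _UNDEFINED}))
            else:
                rows.append((f"{label} {tag}", _metrics_row(profiles.loc[m, col], y[m], level)))
    records = []
    for name, mets in rows:
        rec = {"risk_group": name}
        for key, est in mets.items():
            rec[key] = est.estimate
            rec[f"{key}_lo"] = est.lo
            rec[f"{key}_hi"] = est.hi
        records.append(rec)
    return pd.DataFrame(records)


def render_risk_table(table: pd.DataFrame) -> str:
    """Aligned-text report mirroring the metrics-table layout (2-decimal percents)."""
    lines = [f"{'Risk group':28s} {'PPV (95% CI)':>24s} {'NPV (95% CI)':>24s} {'AUC (95% CI)':>24s}"]
    for _, r in table.iterrows():
        cells = []
        for key in ("PPV", "NPV", "AUC"):
            if np.isnan(r[key]):
                cells.append(f"{'undefined':>24s}")
            else:
                cells.append(f"{r[key]:6.2f} ({r[f'{key}_lo']:6.2f}, {r[f'{key}_hi']:6.2f})")
        lines.append(f"{r['risk_group']:28s} " + " ".join(cells))
    return "\n".join(lines)
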