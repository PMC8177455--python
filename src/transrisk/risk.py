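"""Early-expression risk exposures derived from the symptom battery.

Derives, per participant: total symptom load (0-23), the high-load flag
(strictly above the in-sample median), per-syndrome subthreshold flags,
trans-diagnostic caseness (OR of the three CIDI flags), the composite
risk strata used for predictive-value tables, and the 8-category
"variable of influence" (age x sex x MZ-vs-other) used to adjust tree
growth for demographics and familial clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cohort import CIDI_COLUMNS, Cohort, SymptomItem, registry_codes


@dataclass(frozen=True)
class SubthresholdRule:
    """One syndrome rule: required items plus a minimum endorsed count on one scale."""

    syndrome: str
    scale: str  # DLE | HMLE | PLE
    required: tuple[str, ...]
    min_count: int

    def __post_init__(self):
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.scale not in ("DLE", "HMLE", "PLE"):
            raise ValueError(f"unknown scale {self.scale!r}")


@dataclass
class SubthresholdRuleSet:
    """A named collection of syndrome rules, validated against a registry."""

    rules: list[SubthresholdRule] = field(default_factory=list)

    def validate(self, registry: list[SymptomItem]) -> None:
        codes = set(registry_codes(registry))
        for rule in self.rules:
            unknown = [c for c in rule.required if c not in codes]
            if unknown:
                raise ValueError(
                    f"rule {rule.syndrome!r} references unknown item code(s): {unknown}"
                )

    @classmethod
    def from_yaml(cls, path) -> "SubthresholdRuleSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        rules = [
            SubthresholdRule(
                syndrome=name,
                scale=spec["scale"],
                required=tuple(spec.get("required", [])),
                min_count=int(spec["min_count"]),
            )
            for name, spec in raw.items()
        ]
        return cls(rules)

    def to_yaml(self, path) -> None:
        raw = {
            r.syndrome: {"scale": r.scale, "required": list(r.required), "min_count": r.min_count}
            for r in self.rules
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def default_rule_set() -> SubthresholdRuleSet:
    """Default subthreshold definitions (the study's exact rules are not public).

    Depressive: sadness plus >=4 depressive-scale items; hypomanic: elation
    plus >=3 hypomanic-scale items; psychotic: >=2 psychotic-scale items.
    The whole rule set is configuration and can be replaced from YAML.
    """
    return SubthresholdRuleSet(
        [
            SubthresholdRule("depressive", "DLE", ("DLE2",), 4),
            SubthresholdRule("hypomanic", "HMLE", ("HMLE1",), 3),
            SubthresholdRule("psychotic", "PLE", (), 2),
        ]
    )


def symptom_load(cohort: Cohort) -> np.ndarray:
    """Total endorsed items per participant, in [0, 23]."""
    return cohort.symptoms.to_numpy().sum(axis=1).astype(int)


def load_median(load: np.ndarray) -> float:
    """Lower-median convention: element at position ceil(n/2) of the sorted loads."""
    srt = np.sort(np.asarray(load))
    return float(srt[(len(srt) + 1) // 2 - 1])


def high_load_flags(cohort: Cohort) -> np.ndarray:
    """1 where symptom load is strictly greater than the in-sample median."""
    load = symptom_load(cohort)
    return (load > load_median(load)).astype(np.int8)


def subthreshold_flags(
    cohort: Cohort, rules: SubthresholdRuleSet | None = None
) -> pd.DataFrame:
    """Per-syndrome flags plus ``subt_any``; a syndrome flag requires every
    listed item endorsed and at least ``min_count`` endorsed on its scale."""
    rules = rules if rules is not None else default_rule_set()
    rules.validate(cohort.registry)
    sx = cohort.symptoms
    out = pd.DataFrame(index=sx.index)
    for rule in rules.rules:
        scale_cols = [it.code for it in cohort.registry if it.scale == rule.scale]
        ok = sx[scale_cols].sum(axis=1) >= rule.min_count
        for code in rule.required:
            ok &= sx[code] == 1
        out[rule.syndrome] = ok.astype(np.int8)
    out["subt_any"] = (
        out.any(axis=1).astype(np.int8) if len(rules.rules) else np.zeros(len(sx), np.int8)
    )
    return out


def caseness(cohort: Cohort) -> np.ndarray:
    """Trans-diagnostic caseness: OR of depressive, hypo/manic and psychotic flags."""
    return cohort.df[CIDI_COLUMNS].to_numpy().any(axis=1).astype(np.int8)


#: Fixed encoding of the influence variable.  Bit 0: age_rating > median age;
#: bit 1: sex F; bit 2: zygosity MZ.  Category = 1 + bits, hence
#: (age<=median, M, non-MZ) -> 1 and (age>median, F, MZ) -> 8.
def influence_variable(cohort: Cohort, median_age: float | None = None) -> np.ndarray:
    df = cohort.df
    age = pd.to_numeric(df["age_rating"], errors="coerce").to_numpy(float)
    if median_age is None:
        median_age = float(np.median(age[~np.isnan(age)]))
    older = (age > median_age).astype(int)
    female = (df["sex"] == "F").to_numpy().astype(int)
    mz = (df["zygosity"] == "MZ").to_numpy().astype(int)
    return 1 + older + 2 * female + 4 * mz


LOW_RISK_TRIO = "low-risk trio"
HIGH_RISK_TRIO = "high-risk trio"


def composite_risk(profiles: pd.DataFrame) -> pd.DataFrame:
    """FH x load and FH x SubT strata plus the low/high-risk trio labels.

    Expects columns ``fh``, ``high_load``, ``subt_any`` and returns the same
    frame with ``stratum_fh_load``, ``stratum_fh_subt`` and ``trio`` columns.
    """
    out = profiles.copy()
    fh = out["fh"].map({0: "FH-", 1: "FH+"})
    out["stratum_fh_load"] = fh + "/" + out["high_load"].map({0: "LowLoad", 1: "HighLoad"})
    out["stratum_fh_subt"] = fh + "/" + out["subt_any"].map({0: "SubT-", 1: "SubT+"})
    trio = pd.Series("intermediate", index=out.index)
    trio[(out.fh == 1) & (out.subt_any == 1) & (out.high_load == 1)] = HIGH_RISK_TRIO
    trio[(out.fh == 0) & (out.subt_any == 0) & (out.high_load == 0)] = LOW_RISK_TRIO
    out["trio"] = trio
    return out


def derive_profiles(cohort: Cohort, rules: SubthresholdRuleSet | None = None) -> pd.DataFrame:
    """All per-participant risk exposures as one DataFrame (aligned to the cohort)."""
    prof = pd.DataFrame(
        {
            "participant_id": cohort.df["participant_id"].to_numpy(),
            "family_id": cohort.df["family_id"].to_numpy(),
            "sx_load": symptom_load(cohort),
            "high_load": high_load_flags(cohort),
            "fh": cohort.df["fh"].to_numpy(),
            "case": caseness(cohort),
            "influence": influence_variable(cohort),
        }
    )
    subt = subthreshold_flags(cohort, rules)
    for col in subt.columns:
        prof[col] = subt[col].to_numpy()
    return composite_risk(prof)
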