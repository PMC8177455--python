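"""Participant-level cohort table: domain types, CSV I/O, eligibility, summaries.

The cohort is a table of twins and non-twin siblings, one row per
participant, carrying 23 binary self-rated symptom endorsements (three
scales: depressive-, hypomanic- and psychotic-like experiences), a
family-history flag, three CIDI caseness flags and the ages needed to
order symptom self-rating, syndrome onset and diagnostic interview.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A required column is missing from the cohort CSV."""


class ParseError(ValueError):
    """A cell could not be parsed (reported with its 1-based data row)."""


class ValidationError(ValueError):
    """The table violates a cohort invariant (e.g. duplicate ids)."""


ZYGOSITIES = ("MZ", "DZ", "SIB")
SEXES = ("F", "M")

ID_COLUMNS = ["participant_id", "family_id", "zygosity", "sex"]
AGE_COLUMNS = ["age_rating", "age_cidi"]
FLAG_COLUMNS = ["fh", "cidi_depressive", "cidi_hypomanic", "cidi_psychotic"]
ONSET_COLUMNS = ["onset_age_subt", "onset_age_case"]
CIDI_COLUMNS = ["cidi_depressive", "cidi_hypomanic", "cidi_psychotic"]


@dataclass(frozen=True)
class SymptomItem:
    """One self-rated symptom: a scale-tagged code (e.g. ``DLE2``) and a label."""

    code: str
    label: str

    @property
    def scale(self) -> str:
        for tag in ("HMLE", "DLE", "PLE"):
            if self.code.startswith(tag):
                return tag
        raise ValueError(f"unrecognised scale in item code {self.code!r}")


#: Pinned item labels.  The remaining labels are placeholders: the source
#: instrument's full item list is not public, and only these codes are
#: referenced by rules, figures or pinned orderings.
_PINNED_LABELS = {
    "DLE2": "sadness / depressed mood",
    "DLE4": "feeling overwhelmed",
    "DLE8": "hypersomnia",
    "DLE10": "impaired sleep quality",
    "DLE11": "impaired concentration",
    "HMLE1": "feelings of elation",
    "HMLE3": "reduced need for sleep",
    "HMLE5": "increased physical activity",
    "PLE2": "third-party auditory hallucinations",
    "PLE3": "hearing voices when alone",
    "PLE5": "paranoia",
    "PLE6": "thought withdrawal",
}


def default_registry() -> list[SymptomItem]:
    """The default 23-item registry: DLE1-11, HMLE1-6, PLE1-6."""
    items: list[SymptomItem] = []
    for tag, count in (("DLE", 11), ("HMLE", 6), ("PLE", 6)):
        for i in range(1, count + 1):
            code = f"{tag}{i}"
            items.append(SymptomItem(code, _PINNED_LABELS.get(code, f"{tag} item {i}")))
    return items


def registry_codes(registry: list[SymptomItem]) -> list[str]:
    codes = [it.code for it in registry]
    if len(set(codes)) != len(codes):
        raise ValidationError("duplicate item codes in registry")
    return codes


def item_label(registry: list[SymptomItem], code: str) -> str:
    for it in registry:
        if it.code == code:
            return it.label
    return code


@dataclass
class Cohort:
    """A validated participant table plus its symptom-item registry.

    ``df`` holds one row per participant with the CSV schema's columns;
    row order is preserved by every operation that does not filter.
    """

    df: pd.DataFrame
    registry: list[SymptomItem] = field(default_factory=default_registry)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        _validate(self.df, registry_codes(self.registry))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def item_codes(self) -> list[str]:
        return [it.code for it in self.registry]

    @property
    def symptoms(self) -> pd.DataFrame:
        """The n x 23 binary endorsement block, columns in registry order."""
        return self.df[self.item_codes]

    def families(self) -> pd.core.groupby.DataFrameGroupBy:
        return self.df.groupby("family_id", sort=False)

    def subset(self, mask: np.ndarray | pd.Series) -> "Cohort":
        return Cohort(self.df.loc[np.asarray(mask)].copy(), self.registry)


def required_columns(codes: list[str]) -> list[str]:
    return ID_COLUMNS + AGE_COLUMNS + codes + FLAG_COLUMNS + ONSET_COLUMNS


def _validate(df: pd.DataFrame, codes: list[str]) -> None:
    missing = [c for c in required_columns(codes) if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    if df["participant_id"].duplicated().any():
        dup = df.loc[df["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise ValidationError(f"duplicate participant_id {dup!r}")
    bad_zyg = ~df["zygosity"].isin(ZYGOSITIES)
    if bad_zyg.any():
        raise ValidationError(f"invalid zygosity at row {int(np.flatnonzero(bad_zyg)[0]) + 1}")
    bad_sex = ~df["sex"].isin(SEXES)
    if bad_sex.any():
        raise ValidationError(f"invalid sex at row {int(np.flatnonzero(bad_sex)[0]) + 1}")
    for col in codes + FLAG_COLUMNS:
        vals = df[col]
        bad = ~vals.isin([0, 1])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ParseError(f"non-binary value in column {col!r} at row {row}")
    for col in AGE_COLUMNS + ONSET_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.notna() & (vals <= 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValidationError(f"non-positive age in column {col!r} at row {row}")
    # onset of caseness may only be recorded for participants flagged as cases
    any_case = df[CIDI_COLUMNS].any(axis=1)
    orphan = df["onset_age_case"].notna() & ~any_case
    if orphan.any():
        row = int(np.flatnonzero(orphan.to_numpy())[0]) + 1
        raise ValidationError(f"onset_age_case without any CIDI flag at row {row}")


def read_cohort(path, registry: list[SymptomItem] | None = None) -> Cohort:
    """Read and validate a cohort CSV (schema errors name the offending column)."""
    registry = registry if registry is not None else default_registry()
    codes = registry_codes(registry)
    df = pd.read_csv(path, dtype={"participant_id": str, "family_id": str})
    missing = [c for c in required_columns(codes) if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    for col in codes + FLAG_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~vals.isin([0, 1])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ParseError(f"non-binary value in column {col!r} at row {row}")
        df[col] = vals.astype(np.int8)
    return Cohort(df, registry)


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort CSV (round-trips bit-identically through read_cohort)."""
    df = cohort.df[required_columns(cohort.item_codes)]
    df.to_csv(path, index=False)


@dataclass
class ExclusionLog:
    """Excluded participant ids with machine-readable reason codes."""

    entries: pd.DataFrame  # columns: participant_id, reason

    def __len__(self) -> int:
        return len(self.entries)

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)


def apply_eligibility_filter(cohort: Cohort) -> tuple[Cohort, ExclusionLog]:
    """Keep only records where symptom self-rating antecedes interview and onset.

    A record is excluded when the CIDI interview age or onset of full-threshold
    caseness does not strictly follow the self-rating age (equal ages cannot
    establish antecedence), or when a required age is missing.  Filtering is
    idempotent and |included| + |excluded| equals the input size.
    """
    df = cohort.df
    age_rating = pd.to_numeric(df["age_rating"], errors="coerce")
    age_cidi = pd.to_numeric(df["age_cidi"], errors="coerce")
    onset_case = pd.to_numeric(df["onset_age_case"], errors="coerce")
    is_case = df[CIDI_COLUMNS].any(axis=1)

    missing = age_rating.isna() | age_cidi.isna() | (is_case & onset_case.isna())
    cidi_precedes = ~missing & (age_cidi < age_rating)
    onset_precedes = ~missing & ~cidi_precedes & onset_case.notna() & (onset_case <= age_rating)

    reason = pd.Series(pd.NA, index=df.index, dtype="string")
    reason[onset_precedes] = "onset_precedes_rating"
    reason[cidi_precedes] = "cidi_precedes_rating"
    reason[missing] = "missing_age"

    excluded = reason.notna()
    log = ExclusionLog(
        pd.DataFrame(
            {
                "participant_id": df.loc[excluded, "participant_id"].to_numpy(),
                "reason": reason[excluded].to_numpy(),
            }
        )
    )
    return cohort.subset(~excluded.to_numpy()), log


@dataclass
class SummaryReport:
    """Cohort descriptives in the layout of the study's characteristics table."""

    n: int
    sex_counts: dict[str, int]
    zygosity_counts: dict[str, int]
    load_mean: float
    load_sd: float
    load_median: float
    load_iqr: tuple[float, float]
    n_fh: int
    n_case: int
    n_multi_disorder: int
    onset_subt_median: float | None
    onset_subt_iqr: tuple[float, float] | None
    onset_case_median: float | None
    onset_case_iqr: tuple[float, float] | None
    n_subt: int | None = None

    def render(self) -> str:
        def pct(k: int) -> str:
            return f"{k} ({round(100.0 * k / self.n):.0f}%)"

        lines = [f"Cohort summary (N = {self.n})", ""]
        for s in SEXES:
            lines.append(f"  Sex {s}: {pct(self.sex_counts.get(s, 0))}")
        for z in ZYGOSITIES:
            lines.append(f"  Zygosity {z}: {pct(self.zygosity_counts.get(z, 0))}")
        lines.append(
            f"  Symptom load: mean {self.load_mean:.2f} (SD {self.load_sd:.2f}), "
            f"median {self.load_median:g} (IQR {self.load_iqr[0]:g}-{self.load_iqr[1]:g})"
        )
        lines.append(f"  Family history: {pct(self.n_fh)}")
        if self.n_subt is not None:
            lines.append(f"  >=1 subthreshold syndrome: {pct(self.n_subt)}")
        lines.append(f"  Mood/psychotic caseness: {pct(self.n_case)}")
        lines.append(f"  >=2 CIDI disorders: {pct(self.n_multi_disorder)}")
        if self.onset_subt_median is not None:
            lo, hi = self.onset_subt_iqr
            lines.append(f"  Onset of first SubT: median {self.onset_subt_median:g} (IQR {lo:g}-{hi:g})")
        if self.onset_case_median is not None:
            lo, hi = self.onset_case_iqr
            lines.append(f"  Onset of caseness: median {self.onset_case_median:g} (IQR {lo:g}-{hi:g})")
        return "\n".join(lines)


def summarize_cohort(cohort: Cohort, subt_any: np.ndarray | None = None) -> SummaryReport:
    """Descriptive summary; ``subt_any`` (per-record flags) is optional."""
    if len(cohort) == 0:
        raise ValidationError("cannot summarise an empty cohort")
    df = cohort.df
    load = cohort.symptoms.to_numpy().sum(axis=1)
    q1, q3 = np.percentile(load, [25, 75])
    cases = df[CIDI_COLUMNS].to_numpy()
    onset_subt = pd.to_numeric(df["onset_age_subt"], errors="coerce").dropna()
    onset_case = pd.to_numeric(df["onset_age_case"], errors="coerce").dropna()

    def med_iqr(s: pd.Series):
        if len(s) == 0:
            return None, None
        a, b = np.percentile(s, [25, 75])
        return float(np.median(s)), (float(a), float(b))

    om_s, oi_s = med_iqr(onset_subt)
    om_c, oi_c = med_iqr(onset_case)
    return SummaryReport(
        n=len(df),
        sex_counts=df["sex"].value_counts().to_dict(),
        zygosity_counts=df["zygosity"].value_counts().to_dict(),
        load_mean=float(load.mean()),
        load_sd=float(load.std(ddof=1)) if len(load) > 1 else 0.0,
        load_median=float(np.median(load)),
        load_iqr=(float(q1), float(q3)),
        n_fh=int(df["fh"].sum()),
        n_case=int(cases.any(axis=1).sum()),
        n_multi_disorder=int((cases.sum(axis=1) >= 2).sum()),
        onset_subt_median=om_s,
        onset_subt_iqr=oi_s,
        onset_case_median=om_c,
        onset_case_iqr=oi_c,
        n_subt=int(np.asarray(subt_any).sum()) if subt_any is not None else None,
    )
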