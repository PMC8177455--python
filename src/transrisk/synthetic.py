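"""Liability-threshold twin-cohort simulator with marginal calibration.

Families (twin or sibling pairs) share a standard-normal family factor
``a_f``; individual liability is ``L = sqrt(rho) a_f + sqrt(1-rho) e``
with ``rho`` set by zygosity (MZ above DZ = siblings).  Item ``j`` is
endorsed iff ``lambda_j L + sqrt(1-lambda_j^2) u > tau_j``, so the
marginal prevalence is exactly ``Phi(-tau_j)``.  Family history is a
family-level threshold on ``a_f``; caseness is a threshold on liability
(shifted by family history) or, when a ground-truth tree is planted, a
Bernoulli draw from the tree's leaf probability.

``calibrate_thresholds`` tunes the free parameters by staged bisection
on simulated cohorts until the generator reproduces a set of target
marginals (family history, subthreshold prevalence, their joint rate,
mean and median symptom load, the high-load share, caseness and onset
ages).  Matching a cohort whose printed load distribution has median 5
yet only ~22% strictly above it requires a large probability atom at the
median; the default configuration therefore uses a block of five
near-comonotone high-prevalence "core" items plus eighteen items that
fire mainly at high liability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .cohort import Cohort, default_registry, registry_codes
from .risk import default_rule_set, load_median, subthreshold_flags, symptom_load


class CalibrationError(RuntimeError):
    """Bisection failed to reach a target within its tolerance budget."""


# ---------------------------------------------------------------------------
# configuration

#: Items forming the comonotone high-prevalence core (three depressive-scale
#: items, two hypomanic).  Chosen so the core alone never satisfies a default
#: subthreshold rule: sadness (DLE2) and >=1 further hypomanic item gate the
#: depressive / hypomanic syndromes, psychotic needs two PLE items.  The
#: first three core items carry the largest prevalences, matching the
#: emulated cohort's most-endorsed ordering.
CORE_ITEMS = ("DLE8", "HMLE1", "DLE10", "DLE3", "HMLE2")
_CORE_STAGGER = (0.010, 0.005, 0.000, -0.005, -0.010)

#: Non-core items form two weight-tied families.  The "neutral" family (led
#: by DLE4) never satisfies a subthreshold rule on its own and its level
#: controls the high-load share; the "trigger" family (led by sadness, DLE2)
#: completes the depressive / hypomanic / psychotic rules and its level
#: controls the subthreshold rate.  Within a family, prevalences keep fixed
#: ratios so each knob is scalar and monotone.  The three rarest codes are
#: pinned to the psychotic-scale items the emulated cohort reports as least
#: endorsed (PLE2 < PLE6 < PLE3).
NEUTRAL_WEIGHTS = {
    "DLE4": 1.00,
    "DLE1": 0.85,
    "DLE11": 0.80,
    "DLE5": 0.76,
    "DLE6": 0.72,
    "DLE7": 0.68,
    "DLE9": 0.64,
}
TRIGGER_WEIGHTS = {
    "DLE2": 1.00,
    "HMLE3": 0.85,
    "HMLE4": 0.72,
    "HMLE5": 0.67,
    "HMLE6": 0.62,
    "PLE1": 0.54,
    "PLE5": 0.40,
    "PLE4": 0.27,
    "PLE3": 0.068,
    "PLE6": 0.054,
    "PLE2": 0.045,
}


def knob_prevalences(
    p_trigger: float = 0.205, p_neutral: float = 0.235, mean_load: float = 5.21
) -> dict[str, float]:
    """Full 23-item prevalence profile from the two family levels.

    The core level is derived so all prevalences sum to the target mean
    symptom load (marginal prevalence is exact under the threshold model).
    """
    prev = {c: w * p_neutral for c, w in NEUTRAL_WEIGHTS.items()}
    prev.update({c: w * p_trigger for c, w in TRIGGER_WEIGHTS.items()})
    p_core = (mean_load - sum(prev.values())) / len(CORE_ITEMS)
    if not 0.40 < p_core < 0.80:
        raise CalibrationError(f"derived core prevalence {p_core:.3f} out of range")
    for c, st in zip(CORE_ITEMS, _CORE_STAGGER):
        prev[c] = p_core + st
    return prev


@dataclass
class PlantedTree:
    """Ground-truth decision tree over item codes with leaf case probabilities.

    ``root`` is a nested mapping ``{"item": code, "absent": ..., "present": ...}``
    whose branch values are either a float leaf probability or another mapping.
    """

    root: dict

    def __post_init__(self):
        for _, prob in self.leaves():
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"leaf probability {prob} outside [0, 1]")

    def items(self) -> set[str]:
        out: set[str] = set()

        def walk(node):
            if isinstance(node, dict):
                out.add(node["item"])
                walk(node["absent"])
                walk(node["present"])

        walk(self.root)
        return out

    def leaves(self) -> list[tuple[tuple[tuple[str, int], ...], float]]:
        """(path, probability) pairs; a path is ((item, value), ...)."""
        out = []

        def walk(node, path):
            if isinstance(node, dict):
                walk(node["absent"], path + ((node["item"], 0),))
                walk(node["present"], path + ((node["item"], 1),))
            else:
                out.append((path, float(node)))

        walk(self.root, ())
        return out

    def leaf_probabilities(self, symptoms: pd.DataFrame) -> np.ndarray:
        """Route each record's symptom vector to its leaf probability."""
        out = np.empty(len(symptoms))

        def walk(node, mask):
            if isinstance(node, dict):
                col = symptoms[node["item"]].to_numpy().astype(bool)
                walk(node["absent"], mask & ~col)
                walk(node["present"], mask & col)
            else:
                out[mask] = float(node)

        walk(self.root, np.ones(len(symptoms), dtype=bool))
        return out


@dataclass
class SyntheticConfig:
    """All generator parameters; defaults mirror the emulated study cohort."""

    n: int = 1815
    # family structure: pair probabilities by zygosity (individual shares match)
    p_mz: float = 0.28
    p_dz: float = 0.38
    p_sib: float = 0.34
    rho_mz: float = 0.8
    rho_dz: float = 0.4  # non-twin siblings share this too
    p_female: float = 0.58
    # symptom model
    item_prevalence: dict[str, float] = field(default_factory=dict)
    item_loading: dict[str, float] = field(default_factory=dict)
    # family history and caseness
    z_fh: float = float(norm.ppf(1 - 346 / 1815))
    fh_effect: float = 0.5
    z_case: float = 0.95
    p_subtype: tuple[float, float, float] = (0.75, 0.25, 0.12)
    # ages (years); ratings at 15-19, interview later, onsets truncated normal
    age_rating_range: tuple[int, int] = (15, 19)
    age_cidi_mean: float = 26.4
    age_cidi_sd: float = 4.2
    age_cidi_range: tuple[float, float] = (19.0, 40.0)
    onset_subt_loc: float = 17.0
    onset_subt_scale: float = 3.0
    onset_subt_range: tuple[float, float] = (12.0, 25.0)
    onset_case_loc: float = 20.5
    onset_case_scale: float = 3.5
    onset_case_range: tuple[float, float] = (14.0, 30.0)
    planted: PlantedTree | None = None
    theoretical_auc: float | None = None

    def __post_init__(self):
        if not self.item_prevalence:
            self.item_prevalence = knob_prevalences()
        if not self.item_loading:
            self.item_loading = {
                code: (0.999 if code in CORE_ITEMS else 0.998) for code in self.item_prevalence
            }
        self.validate()

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        if not 0 <= self.rho_dz < self.rho_mz < 1:
            raise ValueError("need 0 <= rho_dz < rho_mz < 1")
        for code, p in self.item_prevalence.items():
            if not 0 < p < 1:
                raise ValueError(f"prevalence for {code} outside (0, 1)")
            lam = self.item_loading[code]
            if not 0 <= lam < 1:
                raise ValueError(f"loading for {code} outside [0, 1)")

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["planted"] = self.planted.root if self.planted is not None else None
        raw["p_subtype"] = list(self.p_subtype)
        for key in ("age_rating_range", "age_cidi_range", "onset_subt_range", "onset_case_range"):
            raw[key] = list(raw[key])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        planted = raw.pop("planted", None)
        raw["planted"] = PlantedTree(planted) if planted is not None else None
        raw["p_subtype"] = tuple(raw.get("p_subtype", (0.75, 0.25, 0.12)))
        for key in ("age_rating_range", "age_cidi_range", "onset_subt_range", "onset_case_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# simulation internals

def _draw_structure(config: SyntheticConfig, rng: np.random.Generator):
    """Zygosity, family ids, family factor and liability for n individuals."""
    n = config.n
    n_fam = (n + 1) // 2
    ftype = rng.choice(3, size=n_fam, p=[config.p_mz, config.p_dz, config.p_sib])
    a_f = rng.standard_normal(n_fam)
    sizes = np.full(n_fam, 2)
    if n % 2 == 1:
        sizes[-1] = 1
    fam_index = np.repeat(np.arange(n_fam), sizes)
    zyg = np.array(["MZ", "DZ", "SIB"])[ftype][fam_index]
    rho = np.where(ftype[fam_index] == 0, config.rho_mz, config.rho_dz)
    e = rng.standard_normal(n)
    liability = np.sqrt(rho) * a_f[fam_index] + np.sqrt(1 - rho) * e
    return fam_index, zyg, a_f, liability


def _draw_items(
    config: SyntheticConfig, rng: np.random.Generator, liability: np.ndarray, codes: list[str]
) -> pd.DataFrame:
    n = len(liability)
    out = {}
    for code in codes:
        lam = config.item_loading[code]
        tau = norm.ppf(1 - config.item_prevalence[code])
        u = rng.standard_normal(n)
        out[code] = (lam * liability + np.sqrt(1 - lam * lam) * u > tau).astype(np.int8)
    return pd.DataFrame(out)


def _draw_truncnorm_int(
    rng: np.random.Generator, loc, scale, lo, hi, lower_open=None, size=None
) -> np.ndarray:
    """Rounded truncated-normal draws, optionally conditioned > lower_open."""
    loc = np.broadcast_to(np.asarray(loc, float), (size,)).copy()
    out = np.full(size, np.nan)
    todo = np.ones(size, dtype=bool)
    floor = np.full(size, lo, float) if lower_open is None else np.maximum(lo, np.asarray(lower_open, float) + 0.5)
    for _ in range(200):
        if not todo.any():
            break
        draw = np.round(rng.normal(loc[todo], scale))
        ok = (draw >= np.maximum(lo, floor[todo])) & (draw <= hi)
        idx = np.flatnonzero(todo)
        out[idx[ok]] = draw[ok]
        todo[idx[ok]] = False
    if todo.any():  # pathological config: clamp the stragglers
        out[todo] = np.ceil(np.maximum(lo, floor[todo]))
    return out


def generate_cohort(config: SyntheticConfig, seed: int) -> Cohort:
    """Generate one fully valid cohort; identical seed and config give an
    identical table (hence byte-identical CSV)."""
    config.validate()
    rng = np.random.default_rng(seed)
    registry = default_registry()
    codes = registry_codes(registry)
    missing = [c for c in codes if c not in config.item_prevalence]
    if missing:
        raise ValueError(f"config lacks prevalence for item(s): {missing}")

    fam_index, zyg, a_f, liability = _draw_structure(config, rng)
    n = config.n
    items = _draw_items(config, rng, liability, codes)

    fh = (a_f > config.z_fh).astype(np.int8)[fam_index]

    if config.planted is not None:
        p_case = config.planted.leaf_probabilities(items)
        case = (rng.random(n) < p_case).astype(np.int8)
    else:
        case = (liability + config.fh_effect * fh > config.z_case).astype(np.int8)

    # CIDI subtype flags: independent thinning among cases, forced non-empty
    pd_, ph, pp = config.p_subtype
    dep = (rng.random(n) < pd_) & (case == 1)
    hyp = (rng.random(n) < ph) & (case == 1)
    psy = (rng.random(n) < pp) & (case == 1)
    none = (case == 1) & ~(dep | hyp | psy)
    dep |= none

    sex = np.where(rng.random(n) < config.p_female, "F", "M")
    lo_r, hi_r = config.age_rating_range
    age_rating = rng.integers(lo_r, hi_r + 1, size=n).astype(float)

    df = pd.DataFrame(
        {
            "participant_id": [f"P{i:05d}" for i in range(n)],
            "family_id": [f"F{i:05d}" for i in fam_index],
            "zygosity": zyg,
            "sex": sex,
            "age_rating": age_rating,
            "age_cidi": np.nan,
            **{c: items[c] for c in codes},
            "fh": fh,
            "cidi_depressive": dep.astype(np.int8),
            "cidi_hypomanic": hyp.astype(np.int8),
            "cidi_psychotic": psy.astype(np.int8),
            "onset_age_subt": np.nan,
            "onset_age_case": np.nan,
        }
    )

    # onset of the first subthreshold syndrome: observed in the self-ratings,
    # so it is drawn at or before the rating age
    subt = subthreshold_flags(Cohort(df.copy(), registry), default_rule_set())["subt_any"].to_numpy()
    has_subt = subt == 1
    if has_subt.any():
        lo, hi = config.onset_subt_range
        upper = np.minimum(hi, age_rating[has_subt])
        draw = _draw_truncnorm_int(
            rng, config.onset_subt_loc, config.onset_subt_scale, lo, hi, size=int(has_subt.sum())
        )
        df.loc[has_subt, "onset_age_subt"] = np.minimum(draw, upper)

    is_case = case == 1
    if is_case.any():
        lo, hi = config.onset_case_range
        draw = _draw_truncnorm_int(
            rng,
            config.onset_case_loc,
            config.onset_case_scale,
            lo,
            hi,
            lower_open=age_rating[is_case],
            size=int(is_case.sum()),
        )
        df.loc[is_case, "onset_age_case"] = draw

    age_cidi = _draw_truncnorm_int(
        rng,
        config.age_cidi_mean,
        config.age_cidi_sd,
        config.age_cidi_range[0],
        config.age_cidi_range[1],
        size=n,
    )
    onset_case = df["onset_age_case"].to_numpy(float)
    age_cidi = np.maximum(age_cidi, age_rating)
    age_cidi = np.where(np.isnan(onset_case), age_cidi, np.maximum(age_cidi, onset_case))
    df["age_cidi"] = age_cidi

    return Cohort(df, registry)


# ---------------------------------------------------------------------------
# calibration

#: Target marginals of the emulated cohort (counts out of 1815 where printed).
STUDY_MARGINALS = {
    "fh": 346 / 1815,
    "subt_any": 383 / 1815,
    "fh_and_subt": 198 / 1815,
    "mean_load": 5.21,
    "median_load": 5.0,
    "high_load": 405 / 1815,
    "caseness": 439 / 1815,
    "onset_case_median": 20.0,
}

_DEFAULT_TOL = {
    "fh": 0.0075,
    "subt_any": 0.0075,
    "fh_and_subt": 0.0075,
    "mean_load": 0.075,
    "median_load": 0.0,
    "high_load": 0.0075,
    "caseness": 0.0075,
    "onset_case_median": 0.5,
}


def simulated_marginals(config: SyntheticConfig, seed: int, n: int | None = None) -> dict[str, float]:
    """One large simulated evaluation of every calibration target."""
    cfg = _with(config, n=n or config.n)
    cohort = generate_cohort(cfg, seed)
    load = symptom_load(cohort)
    med = load_median(load)
    subt = subthreshold_flags(cohort)["subt_any"].to_numpy()
    fh = cohort.df["fh"].to_numpy()
    case = cohort.df[["cidi_depressive", "cidi_hypomanic", "cidi_psychotic"]].to_numpy().any(axis=1)
    onset = cohort.df["onset_age_case"].dropna()
    return {
        "fh": float(fh.mean()),
        "subt_any": float(subt.mean()),
        "fh_and_subt": float((fh & subt).mean()),
        "mean_load": float(load.mean()),
        "median_load": float(med),
        "high_load": float((load > med).mean()),
        "caseness": float(case.mean()),
        "onset_case_median": float(np.median(onset)) if len(onset) else float("nan"),
    }


def _with(config: SyntheticConfig, **overrides) -> SyntheticConfig:
    raw = asdict(config)
    raw["planted"] = config.planted
    raw["p_subtype"] = config.p_subtype
    for key in ("age_rating_range", "age_cidi_range", "onset_subt_range", "onset_case_range"):
        raw[key] = getattr(config, key)
    raw["item_prevalence"] = dict(config.item_prevalence)
    raw["item_loading"] = dict(config.item_loading)
    raw.update(overrides)
    return SyntheticConfig(**raw)


def _bisect(update, measure, target, lo, hi, seed, tol, iters=14, increasing=True):
    """Bisection on a scalar knob against a simulated, monotone response."""
    for it in range(iters):
        mid = 0.5 * (lo + hi)
        val = measure(update(mid), seed + it)
        if abs(val - target) <= tol:
            return mid
        high = val > target
        if high == increasing:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def calibrate_thresholds(
    targets: dict[str, float] | None = None,
    config: SyntheticConfig | None = None,
    seed: int = 0,
    n_sim: int = 120_000,
    tol: dict[str, float] | None = None,
    rounds: int = 3,
    verify_n: int = 400_000,
) -> SyntheticConfig:
    """Tune the generator to reproduce target marginals; raise on failure.

    Item thresholds follow in closed form from prevalences (tau = Phi^-1(1-p));
    the remaining knobs are tuned by staged bisection on simulated cohorts:
    the top non-core item's prevalence for the high-load share, sadness (DLE2)
    prevalence for the subthreshold rate, filler rescaling for the mean load,
    the familial correlations for the joint FH-and-SubT rate, the caseness
    threshold for caseness, and the onset-age location for the onset median.
    """
    targets = {**STUDY_MARGINALS, **(targets or {})}
    tol = {**_DEFAULT_TOL, **(tol or {})}
    cfg = _with(config or SyntheticConfig(), n=n_sim)

    def measured(c: SyntheticConfig, s: int) -> dict[str, float]:
        return simulated_marginals(c, s)

    # family history is exact in closed form: P(a_f > z) = Phi(-z)
    cfg = _with(cfg, z_fh=float(norm.ppf(1 - targets["fh"])))

    p_trigger, p_neutral = 0.205, 0.235
    for rnd in range(rounds):
        base = seed + 1000 * rnd

        def set_trigger(x):
            return _with(
                cfg, item_prevalence=knob_prevalences(x, p_neutral, targets["mean_load"])
            )

        p_trigger = _bisect(
            set_trigger,
            lambda c, s: measured(c, s)["subt_any"],
            targets["subt_any"],
            0.10, 0.30, base, tol["subt_any"] / 2,
        )
        cfg = set_trigger(p_trigger)

        def set_neutral(x):
            return _with(
                cfg, item_prevalence=knob_prevalences(p_trigger, x, targets["mean_load"])
            )

        p_neutral = _bisect(
            set_neutral,
            lambda c, s: measured(c, s)["high_load"],
            targets["high_load"],
            max(0.12, p_trigger), 0.34, base + 100, tol["high_load"] / 2,
        )
        cfg = set_neutral(p_neutral)

        def set_rho(s):
            return _with(cfg, rho_dz=0.4 * s, rho_mz=min(0.97, 0.8 * s))

        x = _bisect(
            set_rho,
            lambda c, s: measured(c, s)["fh_and_subt"],
            targets["fh_and_subt"],
            0.5, 2.2, base + 200, tol["fh_and_subt"] / 2,
        )
        cfg = set_rho(x)

    def set_zcase(z):
        return _with(cfg, z_case=z)

    x = _bisect(
        set_zcase,
        lambda c, s: measured(c, s)["caseness"],
        targets["caseness"],
        0.2, 2.0, seed + 300, tol["caseness"] / 2, increasing=False,
    )
    cfg = set_zcase(x)

    def set_onset(loc):
        return _with(cfg, onset_case_loc=loc)

    x = _bisect(
        set_onset,
        lambda c, s: measured(c, s)["onset_case_median"],
        targets["onset_case_median"],
        16.0, 24.0, seed + 400, 0.25,
    )
    cfg = set_onset(x)

    achieved = simulated_marginals(cfg, seed + 999, n=verify_n)
    for key, want in targets.items():
        if key == "median_load":
            if achieved[key] != want:
                raise CalibrationError(f"median_load {achieved[key]} != {want}")
            continue
        if abs(achieved[key] - want) > tol[key]:
            raise CalibrationError(
                f"target {key}: achieved {achieved[key]:.4f}, wanted {want:.4f} "
                f"(tolerance {tol[key]})"
            )
    return _with(cfg, n=config.n if config is not None else 1815)


# ---------------------------------------------------------------------------
# planted trees

def planted_theoretical_auc(tree: PlantedTree, config: SyntheticConfig, n_mc: int = 200_000) -> float:
    """AUC of the oracle score (leaf probability) under the generator.

    Leaf masses come from a closed form when every referenced item has zero
    loading (independent items), else from one large fixed-seed simulation;
    concordance over leaf pairs is then exact (ties count one half).
    """
    leaves = tree.leaves()
    if all(config.item_loading.get(code, 0.0) == 0.0 for code in tree.items()):
        masses = []
        for path, _ in leaves:
            m = 1.0
            for code, val in path:
                p = config.item_prevalence[code]
                m *= p if val == 1 else (1 - p)
            masses.append(m)
    else:
        rng = np.random.default_rng(12345)
        cfg = _with(config, n=n_mc)
        _, _, _, liab = _draw_structure(cfg, rng)
        items = _draw_items(cfg, rng, liab, sorted(tree.items()))
        masses = []
        for path, _ in leaves:
            mask = np.ones(len(items), dtype=bool)
            for code, val in path:
                mask &= items[code].to_numpy() == val
            masses.append(float(mask.mean()))
    qs = np.array([q for _, q in leaves])
    ms = np.array(masses)
    p_case = float((ms * qs).sum())
    p_non = float((ms * (1 - qs)).sum())
    if p_case == 0 or p_non == 0:
        raise ValueError("planted tree yields a single-class cohort")
    gt = 0.0
    eq = 0.0
    for k in range(len(qs)):
        for l in range(len(qs)):
            w = ms[k] * qs[k] * ms[l] * (1 - qs[l])
            if qs[k] > qs[l]:
                gt += w
            elif qs[k] == qs[l]:
                eq += w
    return (gt + 0.5 * eq) / (p_case * p_non)


def plant_tree(tree: PlantedTree, config: SyntheticConfig | None = None) -> SyntheticConfig:
    """Return a config whose caseness mechanism is the planted tree; the
    theoretical AUC of the oracle score is recorded on the config."""
    cfg = _with(config or SyntheticConfig(), planted=tree)
    unknown = tree.items() - set(cfg.item_prevalence)
    if unknown:
        raise ValueError(f"planted tree references unknown item(s): {sorted(unknown)}")
    return _with(cfg, theoretical_auc=float(planted_theoretical_auc(tree, cfg)))
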