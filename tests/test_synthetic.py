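import io

import numpy as np
import pytest

from transrisk.accuracy import mann_whitney_auc
from transrisk.cohort import write_cohort
from transrisk.risk import caseness, symptom_load
from transrisk.synthetic import (
    CalibrationError,
    PlantedTree,
    SyntheticConfig,
    _draw_structure,
    calibrate_thresholds,
    generate_cohort,
    knob_prevalences,
    plant_tree,
    planted_theoretical_auc,
    simulated_marginals,
)


def _flat_config(n=100_000, lam=0.5, prev=0.30, **kw):
    """Config with uniform loadings/prevalences for distribution checks."""
    cfg = SyntheticConfig(n=n, **kw)
    cfg.item_prevalence = {c: prev for c in cfg.item_prevalence}
    cfg.item_loading = {c: lam for c in cfg.item_loading}
    return cfg


def test_marginal_prevalence_matches_threshold_closed_form():
    """Item prevalence equals Phi(-tau) within 3 Monte-Carlo SEs at n=100000."""
    cfg = _flat_config(prev=0.30)
    cohort = generate_cohort(cfg, seed=11)
    se = 3 * np.sqrt(0.3 * 0.7 / cfg.n) * 2  # conservative for family clustering
    props = cohort.symptoms.mean(axis=0)
    assert (np.abs(props - 0.30) < 3 * 0.007).all()
    assert props.mean() == pytest.approx(0.30, abs=0.01)


def test_zero_loading_decouples_cotwins():
    cfg = _flat_config(n=60_000, lam=0.0)
    cohort = generate_cohort(cfg, seed=2)
    sx = cohort.symptoms.to_numpy()
    fam = cohort.df["family_id"].to_numpy()
    first = sx[0::2][: len(sx) // 2 - 1]
    second = sx[1::2][: len(sx) // 2 - 1]
    same = fam[0::2][: len(sx) // 2 - 1] == fam[1::2][: len(sx) // 2 - 1]
    r = np.corrcoef(first[same].sum(1), second[same].sum(1))[0, 1]
    assert abs(r) < 0.03


def test_mz_liability_correlation_exceeds_dz():
    cfg = SyntheticConfig(n=120_000)
    rng = np.random.default_rng(5)
    fam_index, zyg, a_f, L = _draw_structure(cfg, rng)
    pairs = {}
    for z in ("MZ", "DZ"):
        m = zyg == z
        Lz = L[m]
        fz = fam_index[m]
        keep = len(Lz) - (len(Lz) % 2)
        a, b = Lz[0:keep:2], Lz[1:keep:2]
        ok = fz[0:keep:2] == fz[1:keep:2]
        pairs[z] = np.corrcoef(a[ok], b[ok])[0, 1]
    assert pairs["MZ"] > pairs["DZ"] + 0.1
    assert pairs["MZ"] == pytest.approx(cfg.rho_mz, abs=0.03)
    assert pairs["DZ"] == pytest.approx(cfg.rho_dz, abs=0.03)


def test_same_seed_byte_identical_csv():
    cfg = SyntheticConfig(n=500)
    bufs = []
    for _ in range(2):
        cohort = generate_cohort(cfg, seed=9)
        buf = io.StringIO()
        write_cohort(cohort, buf)
        bufs.append(buf.getvalue())
    assert bufs[0] == bufs[1]


def test_generated_cohort_is_already_eligible():
    from transrisk.cohort import apply_eligibility_filter

    cohort = generate_cohort(SyntheticConfig(n=2000), seed=4)
    kept, log = apply_eligibility_filter(cohort)
    assert len(log) == 0
    assert len(kept) == 2000


def test_zygosity_mix_and_family_sizes():
    cohort = generate_cohort(SyntheticConfig(n=4001), seed=10)
    shares = cohort.df["zygosity"].value_counts(normalize=True)
    assert shares["MZ"] == pytest.approx(0.28, abs=0.03)
    assert shares["DZ"] == pytest.approx(0.38, abs=0.03)
    sizes = cohort.df.groupby("family_id").size()
    assert set(sizes.unique()) == {1, 2}
    assert (sizes == 1).sum() == 1  # odd cohort leaves one singleton


def test_infeasible_config_rejected():
    with pytest.raises(ValueError):
        SyntheticConfig(rho_mz=1.2)
    with pytest.raises(ValueError):
        SyntheticConfig(n=0)
    with pytest.raises(CalibrationError):
        knob_prevalences(0.5, 0.5, 5.21)  # leaves no room for the core block


def test_config_yaml_round_trip(tmp_path):
    cfg = SyntheticConfig(n=321)
    path = tmp_path / "config.yaml"
    cfg.to_yaml(path)
    back = SyntheticConfig.from_yaml(path)
    assert back.n == 321
    assert back.item_prevalence == cfg.item_prevalence
    assert back.rho_mz == cfg.rho_mz


# ---------------------------------------------------------------------------
# planted trees

def test_single_leaf_tree_gives_bernoulli_caseness_independent_of_symptoms():
    cfg = plant_tree(PlantedTree({"item": "DLE2", "absent": 0.24, "present": 0.24}),
                     _flat_config(n=60_000, lam=0.0))
    cohort = generate_cohort(cfg, seed=3)
    y = caseness(cohort)
    assert y.mean() == pytest.approx(0.24, abs=0.01)
    r = np.corrcoef(symptom_load(cohort), y)[0, 1]
    assert abs(r) < 0.02


def test_two_leaf_tree_mixture_rate_and_theoretical_auc():
    tree = PlantedTree({"item": "DLE2", "absent": 0.1, "present": 0.6})
    cfg = _flat_config(n=150_000, lam=0.0, prev=0.30)
    cfg = plant_tree(tree, cfg)
    # closed form: masses (0.7, 0.3); P(case) = 0.7*0.1 + 0.3*0.6 = 0.25
    # AUC = (0.3*0.6*0.7*0.9 + 0.5*(0.7*0.1*0.7*0.9 + 0.3*0.6*0.3*0.4)) / (0.25*0.75)
    expected_auc = (0.1134 + 0.5 * (0.0441 + 0.0216)) / (0.25 * 0.75)
    assert cfg.theoretical_auc == pytest.approx(expected_auc, abs=1e-12)
    cohort = generate_cohort(cfg, seed=6)
    y = caseness(cohort)
    assert y.mean() == pytest.approx(0.25, abs=0.01)
    # the oracle score reproduces the theoretical AUC empirically
    score = cfg.planted.leaf_probabilities(cohort.symptoms)
    assert mann_whitney_auc(score, y) == pytest.approx(expected_auc, abs=0.01)


def test_planted_leaf_probability_validation():
    with pytest.raises(ValueError):
        PlantedTree({"item": "DLE2", "absent": -0.1, "present": 0.5})
    with pytest.raises(ValueError):
        plant_tree(PlantedTree({"item": "NOPE", "absent": 0.1, "present": 0.5}))


def test_theoretical_auc_with_correlated_items_uses_simulated_masses():
    tree = PlantedTree({"item": "DLE2", "absent": 0.1, "present": 0.7})
    cfg = _flat_config(n=1000, lam=0.6, prev=0.25)
    auc = planted_theoretical_auc(tree, cfg)
    assert 0.5 < auc < 1.0


# ---------------------------------------------------------------------------
# calibration

def test_calibration_near_fixed_point():
    """Calibrating to a configuration's own marginals changes little."""
    cfg = SyntheticConfig()
    own = simulated_marginals(cfg, seed=77, n=150_000)
    own["median_load"] = 5.0
    got = calibrate_thresholds(targets=own, config=cfg, seed=1, n_sim=60_000,
                               rounds=1, verify_n=120_000,
                               tol={k: 0.02 for k in own} | {"mean_load": 0.2,
                                                             "median_load": 0.0,
                                                             "onset_case_median": 1.0})
    after = simulated_marginals(got, seed=78, n=150_000)
    for key in ("fh", "subt_any", "high_load", "caseness"):
        assert after[key] == pytest.approx(own[key], abs=0.025)


def test_joint_target_above_independence_needs_family_coupling():
    """The calibrated joint FH-and-SubT rate exceeds the independence product,
    so the shared family factor must be doing real work."""
    cfg = SyntheticConfig()
    m = simulated_marginals(cfg, seed=13, n=150_000)
    assert m["fh_and_subt"] > 1.5 * m["fh"] * m["subt_any"]
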