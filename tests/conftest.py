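import numpy as np
import pandas as pd
import pytest

from transrisk.cohort import Cohort, default_registry, registry_codes
from transrisk.synthetic import SyntheticConfig, generate_cohort


def make_cohort_df(rows: list[dict]) -> pd.DataFrame:
    """Build a schema-complete cohort frame from sparse row dicts."""
    codes = registry_codes(default_registry())
    records = []
    for i, row in enumerate(rows):
        row = dict(row)  # never mutate the caller's dicts
        rec = {
            "participant_id": f"P{i}",
            "family_id": f"F{i}",
            "zygosity": "DZ",
            "sex": "F",
            "age_rating": 16.0,
            "age_cidi": 25.0,
            **{c: 0 for c in codes},
            "fh": 0,
            "cidi_depressive": 0,
            "cidi_hypomanic": 0,
            "cidi_psychotic": 0,
            "onset_age_subt": np.nan,
            "onset_age_case": np.nan,
        }
        for code in row.pop("endorse", []):
            rec[code] = 1
        rec.update(row)
        records.append(rec)
    return pd.DataFrame(records)


@pytest.fixture
def registry():
    return default_registry()


@pytest.fixture
def cohort_factory():
    def make(rows):
        return Cohort(make_cohort_df(rows))

    return make


@pytest.fixture(scope="session")
def sim_cohort():
    """A mid-sized synthetic cohort shared across integration-style tests."""
    return generate_cohort(SyntheticConfig(n=900), seed=5)
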