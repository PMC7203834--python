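import numpy as np
import pandas as pd
import pytest

from geoaft import graphs, simulate


@pytest.fixture(scope="session")
def grid16():
    return graphs.make_county_graph(16, "grid", seed=1)


@pytest.fixture(scope="session")
def pa_graph():
    return graphs.make_county_graph(layout="pa_fixture")


@pytest.fixture(scope="session")
def sim_cohort(grid16):
    """A moderate synthetic registry cohort shared across tests."""
    truth = simulate.default_truth(seed=42)
    cases, echo = simulate.simulate_registry(grid16, truth, 4000)
    return cases, echo


def toy_cases(rows: list[dict]) -> pd.DataFrame:
    """Build a minimal cases frame from per-row overrides of sane defaults."""
    base = {
        "case_id": None, "age_at_dx": 65, "race": "white",
        "ethnicity": "non_hispanic", "insurance": "insured", "psa": 6.5,
        "gleason_path_primary": np.nan, "gleason_path_secondary": np.nan,
        "gleason_clin_primary": 3.0, "gleason_clin_secondary": 4.0,
        "stage_path": "unknown", "stage_clin": "T2", "metastasis": "no",
        "ln_positive": "no", "treatment": "neither", "county_fips": "g00000",
        "followup_months": 60.0, "event": "censored",
    }
    out = []
    for i, r in enumerate(rows):
        row = dict(base, **r)
        if row["case_id"] is None:
            row["case_id"] = f"t{i:03d}"
        out.append(row)
    return pd.DataFrame(out)
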