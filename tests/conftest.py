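import numpy as np
import pandas as pd
import pytest

from dynapred import (
    LandmarkGrid,
    apply_eligibility_filters,
    build_landmark_stack,
    default_truth,
    generate_cohort,
)
from dynapred.supermodel import fit_supermodel


def make_cohort(rows: list[dict]) -> pd.DataFrame:
    """Hand-built cohort table; unspecified fields get reference values."""
    defaults = {
        "age_years": 14.0,
        "sex": "female",
        "tumor_location": "other",
        "volume_cm3": 100.0,
        "excision": "wide/radical",
        "lung_mets": "no",
        "other_mets": "no",
        "histology": "good",
        "t_lr": np.nan,
        "t_nm": np.nan,
        "t_os": 6.0,
        "os_status": 0.0,
    }
    out = []
    for i, row in enumerate(rows):
        rec = {"id": i, **defaults, **row}
        out.append(rec)
    return pd.DataFrame(out)


@pytest.fixture(scope="session")
def medium_cohort():
    """Complete synthetic cohort reused across read-only tests."""
    cohort = generate_cohort(600, seed=42)
    eligible, _ = apply_eligibility_filters(cohort)
    return eligible


@pytest.fixture(scope="session")
def medium_stack(medium_cohort):
    return build_landmark_stack(medium_cohort, LandmarkGrid())


@pytest.fixture(scope="session")
def medium_fit(medium_stack):
    return fit_supermodel(medium_stack)


@pytest.fixture(scope="session")
def truth():
    return default_truth()
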