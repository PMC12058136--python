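import numpy as np
import pandas as pd
import pytest

from morbnet.catalog import DiseaseCatalog
from morbnet.cohort import Cohort
from morbnet.simulate import build_planted_ising, default_design


def make_cohort(X, codes=None, gender="M", age="50-64", income="Q1", edu="Primary"):
    """Wrap a binary matrix into a Cohort with constant demographics."""
    X = np.asarray(X)
    n, p = X.shape
    if codes is None:
        codes = tuple(f"D{i+1}" for i in range(p))
    df = pd.DataFrame(X, columns=list(codes))
    df.insert(0, "id", [f"P{i}" for i in range(n)])
    if isinstance(gender, str):
        gender = [gender] * n
    df.insert(1, "gender", gender)
    df.insert(2, "age_group", age)
    df.insert(3, "income_q", income)
    df.insert(4, "education", edu)
    return Cohort(df, DiseaseCatalog.from_codes(codes))


@pytest.fixture
def cohort_factory():
    return make_cohort


@pytest.fixture(scope="session")
def planted():
    """Default 32-node design with its calibrated Ising parameters.

    Calibration is deterministic and costs a few seconds, so it is shared
    across the whole session.
    """
    design = default_design()
    params = build_planted_ising(design)
    return design, params
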