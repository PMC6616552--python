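import numpy as np
import pandas as pd
import pytest

from astrobiome import CohortSpec, OtuTable, generate_cohort, validate_metadata


@pytest.fixture(scope="session")
def small_cohort():
    """A small deterministic cohort shared by read-only tests."""
    spec = CohortSpec(n_subjects=4, stool_subjects=3, n_taxa=30,
                      library_size_median=3000, seed=42)
    return spec, generate_cohort(spec)


@pytest.fixture
def toy_table():
    counts = pd.DataFrame(
        {"s1": [5, 1, 0], "s2": [0, 2, 7]},
        index=["t1", "t2", "t3"],
    )
    return OtuTable(counts)


@pytest.fixture
def toy_metadata():
    meta = pd.DataFrame(
        {
            "subject_id": ["AstA", "AstA"],
            "site": ["stool", "stool"],
            "timepoint": ["L-60", "FD7"],
        },
        index=["s1", "s2"],
    )
    return validate_metadata(meta)


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
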