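import numpy as np
import pandas as pd
import pytest

from ovoscore.synthetic_data import CohortConfig, generate_cohort


def merge_embryo_oocyte(cohort):
    """Analysis table for the embryo-level GEE models."""
    merged = cohort.embryos.merge(
        cohort.oocytes, on=["patient_id", "oocyte_id"], suffixes=("", "_ooc"))
    merged["eight_cell"] = merged["eight_cell_flag"].astype(int)
    return merged.merge(cohort.cycles[["patient_id", "age"]], on="patient_id")


@pytest.fixture(scope="session")
def default_cohort():
    """One moderate default-config cohort shared across read-only tests."""
    return generate_cohort(CohortConfig(n_patients=200, seed=11))


@pytest.fixture(scope="session")
def default_merged(default_cohort):
    return merge_embryo_oocyte(default_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
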