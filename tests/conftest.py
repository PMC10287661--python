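import logging

import numpy as np
import pytest

from subgrowth.cohort import CohortConfig, generate_cohort, generate_mullen
from subgrowth.gamm import fit_gamm

logging.getLogger("subgrowth").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def cohort_small():
    """A modest cohort shared across tests: 80 subjects, default truth."""
    cfg = CohortConfig(n_subjects=80, seed=42)
    records, truth = generate_cohort(cfg)
    records = generate_mullen(records, truth, seed=7)
    return records, truth, cfg


@pytest.fixture(scope="session")
def thalamus_model(cohort_small):
    records, _, _ = cohort_small
    return fit_gamm(records, ("thalamus", "L"), with_sex=True, span=(0, 810))


@pytest.fixture(scope="session")
def month_grid():
    return np.arange(0, 721, 30.0)
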