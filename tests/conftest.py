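import numpy as np
import pandas as pd
import pytest

from prscohort import CohortTable, SimConfig
from prscohort.simulate import (
    scoring_file_from_weights,
    sim_common_genotypes,
    sim_phenotypes,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort: 1:7 case:control at reduced size, 100 common variants."""
    return SimConfig(n_cases=60, n_controls=360, n_common_variants=100, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """(genotypes, cohort, true standardized PRS, true weights, ancestry)."""
    geno, _freqs, ancestry = sim_common_genotypes(small_config)
    cohort, true_prs, w = sim_phenotypes(geno, small_config, ancestry=ancestry)
    return geno, cohort, true_prs, w, ancestry


@pytest.fixture(scope="session")
def true_scoring(small_cohort):
    geno, _, _, w, _ = small_cohort
    return scoring_file_from_weights(geno, w, "PGS_TRUE")


def minimal_cohort(status, **extra) -> CohortTable:
    """Cohort table with constant demographics, for tests that only need status."""
    n = len(status)
    df = pd.DataFrame(
        {
            "sample_id": [f"S{i:05d}" for i in range(n)],
            "status": np.asarray(status, dtype=int),
            "age": 50.0,
            "sex": "male",
            **extra,
        }
    )
    return CohortTable(df)
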