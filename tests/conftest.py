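import numpy as np
import pytest

from gutpredict import (
    AbundanceTable,
    CohortSpec,
    generate_cohort,
    reduce_to_top,
)


@pytest.fixture
def toy_table():
    """5-taxon toy with column sums 10, 5, 3, 1, 1 across two samples."""
    values = np.array(
        [
            [5.0, 2.5, 1.5, 0.5, 0.5],
            [5.0, 2.5, 1.5, 0.5, 0.5],
        ]
    )
    return AbundanceTable(
        sample_ids=["s1", "s2"],
        taxon_ids=["a", "b", "c", "d", "e"],
        values=values,
        level="genus",
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Small planted cohort shared by screening/selection tests."""
    spec = CohortSpec(
        n_taxa_raw=150,
        n_planted=3,
        target_abs_corr=(0.6, 0.6, 0.6),
        log_sigma=0.9,
        outcome_mode="from_planted",
        seed=7,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_pm(small_cohort):
    return reduce_to_top(small_cohort.abundance, 102)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
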