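import numpy as np
import pandas as pd
import pytest

from microstage.synthetic_data import CohortConfig, generate_cohort
from microstage.tables_io import AsvTable, SampleMetadata


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (9 subjects/group, modest depth) shared across tests."""
    config = CohortConfig(
        n_per_group=9, n_asvs_feces=40, n_asvs_saliva=50, depth=3000, seed=11
    )
    feces, saliva, meta, truth = generate_cohort(config)
    return {"config": config, "feces": feces, "saliva": saliva,
            "metadata": meta, "truth": truth}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_table():
    counts = pd.DataFrame(
        [[5, 0, 3, 2], [1, 4, 0, 5], [2, 2, 2, 2]],
        index=["s1", "s2", "s3"],
        columns=["a1", "a2", "a3", "a4"],
    )
    return AsvTable(counts, site="feces")


@pytest.fixture
def toy_metadata():
    frame = pd.DataFrame({
        "sample_id": ["s1", "s2", "s3"],
        "subject_id": ["p1", "p2", "p3"],
        "group": ["NC", "NM", "M"],
        "site": ["feces", "feces", "feces"],
    })
    return SampleMetadata(frame)
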