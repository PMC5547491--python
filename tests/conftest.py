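import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import dmscan

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def ref():
    """Short coding reference: ATG AAA TGC GAA (Met-Lys-Cys-Glu)."""
    return dmscan.ReferenceSequence("ATGAAATGCGAA", is_coding=True)


@pytest.fixture
def small_table():
    """Hand-built 3-timepoint count table with a wild-type row."""
    counts = pd.DataFrame(
        {
            "t0": [100, 100, 50, 0],
            "t1": [100, 50, 60, 5],
            "t2": [100, 20, 80, 10],
        },
        index=pd.Index(["_wt", "varA", "varB", "varC"], name="variant"),
    )
    return dmscan.VariantCountTable(
        counts, dmscan.TimepointSchedule((0.0, 1.0, 2.0))
    )


@pytest.fixture(scope="session")
def tiny_simulation():
    """Small binding simulation shared across tests (fast, deterministic)."""
    config = dmscan.SimulationConfig(
        assay="binding",
        n_variants=300,
        population_size=300_000,
        rounds=5,
        replicates=3,
        seed=11,
    )
    return dmscan.simulate_dataset(config)
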