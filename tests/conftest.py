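import numpy as np
import pandas as pd
import pytest

from cosig.io import CountMatrix
from cosig.simulate import CohortSpec, SynthConfig, generate_cohorts


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def small_config():
    """A fast three-cohort configuration with the same structure as the
    reference conditions (one cohort lacks normals)."""
    return SynthConfig(
        n_genes=300,
        cohorts=(
            CohortSpec("alpha", 30, 8),
            CohortSpec("beta", 20, 0),
            CohortSpec("gamma", 25, 6),
        ),
        n_planted_up=15,
        n_planted_down=15,
        seed=11,
    )


@pytest.fixture
def small_dataset(small_config):
    return generate_cohorts(small_config)


@pytest.fixture
def tiny_counts():
    """A 4-gene x 4-sample matrix with lengths, two tumors and two normals."""
    counts = pd.DataFrame(
        [[10, 20, 5, 8], [100, 80, 120, 90], [0, 1, 0, 0], [40, 30, 35, 45]],
        index=["gA", "gB", "gC", "gD"],
        columns=["s1", "s2", "s3", "s4"],
    )
    lengths = pd.Series([1000.0, 2000.0, 500.0, 1500.0], index=counts.index)
    meta = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "patient_id": ["p1", "p2", "p3", "p4"],
            "cohort": ["x", "x", "y", "y"],
            "sample_type": ["tumor", "tumor", "normal", "normal"],
            "sex": ["female"] * 4,
        }
    )
    return CountMatrix(counts, lengths), meta
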