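import numpy as np
import pandas as pd
import pytest

from remsig import CohortDesign, ExpressionMatrix, PlantedSet, generate_cohort
from remsig.gsea import DIRECTION_REM_UP


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples with fixed values."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [10.0, 10.0, 10.0, 10.0], [5.0, 1.0, 8.0, 2.0]],
        index=["GA", "GB", "GC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(values)


@pytest.fixture(scope="session")
def small_cohort():
    """Three-arm cohort with one planted set per arm, small enough for fast tests."""
    design = CohortDesign(
        n_genes=400,
        n_per_arm=(60, 40, 40),
        planted_sets=(
            PlantedSet("INFLAMMASOME_LIKE", 25, "IFX", delta=1.0),
            PlantedSet("CD19_LIKE", 25, "TCZ", direction=DIRECTION_REM_UP, delta=1.0),
            PlantedSet("CD56_LIKE", 25, "ABT", delta=1.0),
        ),
        n_decoy_sets=3,
        insufficient_effect_per_arm=(1, 2, 1),
        adverse_event_per_arm=(0, 1, 0),
        seed=3,
    )
    return design, generate_cohort(design)
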