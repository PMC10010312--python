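import numpy as np
import pandas as pd
import pytest

from immunocentroid import (
    ExpressionMatrix,
    SimConfig,
    filter_min_expression,
    normalize,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def cohort():
    """A default 35-sample synthetic cohort with a planted immune program."""
    return simulate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def recovery_cohort():
    """Cohort with 20 up- and 20 down-regulated response genes, the planted
    structure the balanced classifier is designed to recover."""
    cfg = SimConfig(
        seed=0,
        program_specs=[("response_up", 20, 1.0), ("response_down", 20, -1.0)],
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def norm_cohort(cohort):
    counts, clinical, truth = cohort
    filtered, _ = filter_min_expression(counts)
    return normalize(filtered), clinical, truth


@pytest.fixture
def toy_counts():
    """6 genes x 6 samples with hand-chosen patterns for filter tests."""
    values = np.array(
        [
            [10, 10, 10, 10, 10, 0],   # exactly 5 samples at threshold -> kept
            [0, 0, 0, 0, 0, 0],        # all zero -> removed
            [9, 9, 9, 9, 9, 9],        # never reaches min_count -> removed
            [100, 0, 0, 0, 0, 0],      # only 1 sample -> removed
            [12, 15, 30, 11, 10, 10],  # 6 samples -> kept
            [10, 10, 10, 10, 0, 0],    # only 4 samples -> removed
        ],
        dtype=float,
    )
    return ExpressionMatrix(
        [f"g{i}" for i in range(6)], [f"s{j}" for j in range(6)], values
    )


@pytest.fixture
def small_norm():
    """5 genes x 4 samples log-normalized toy matrix."""
    rng = np.random.default_rng(3)
    counts = rng.integers(1, 200, size=(5, 4)).astype(float)
    m = ExpressionMatrix(
        [f"g{i}" for i in range(5)], [f"s{j}" for j in range(4)], counts
    )
    return normalize(m)
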