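import numpy as np
import pytest

from pathrisk.io import ExpressionMatrix, GeneSetCollection, SurvivalData


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_expr(rng):
    """10 genes x 12 samples with heterogeneous means/scales."""
    genes = [f"G{i}" for i in range(10)]
    samples = [f"S{j}" for j in range(12)]
    values = rng.normal(0, 1, (10, 12)) * rng.uniform(0.5, 3.0, (10, 1)) + rng.normal(
        2, 1, (10, 1)
    )
    return ExpressionMatrix(genes, samples, values)


@pytest.fixture
def small_surv(rng, small_expr):
    time = rng.exponential(10.0, small_expr.n_samples) + 0.1
    event = np.ones(small_expr.n_samples, dtype=int)
    event[[2, 7]] = 0
    return SurvivalData(list(small_expr.sample_ids), time, event)


@pytest.fixture
def small_collection():
    return GeneSetCollection(
        "toy",
        {
            "SET_A": frozenset(["G0", "G1", "G2"]),
            "SET_B": frozenset(["G3", "G4", "G5", "G6"]),
            "SET_C": frozenset(["G7", "G8", "G9", "MISSING_GENE"]),
        },
    )
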