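import numpy as np
import pandas as pd
import pytest

from anchorsig import ExpressionMatrix, SyntheticCohortConfig, generate_cohort


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """Deterministic 10-gene x 8-sample matrix, all unique patients."""
    rng = np.random.default_rng(42)
    genes = [f"G{i}" for i in range(10)]
    samples = [f"S{i}" for i in range(8)]
    values = pd.DataFrame(
        rng.normal(8.0, 1.0, (10, 8)), index=genes, columns=samples
    )
    return ExpressionMatrix(values=values)


@pytest.fixture
def default_cohort():
    """One synthetic cohort at study-condition defaults (seed 7)."""
    return generate_cohort(SyntheticCohortConfig(seed=7))


@pytest.fixture
def fast_config() -> SyntheticCohortConfig:
    """Reduced gene counts for unit tests that only need structure."""
    return SyntheticCohortConfig(
        n_signature_genes=60, n_background_genes=200, seed=11
    )
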