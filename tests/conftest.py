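import numpy as np
import pytest

from slidefactors.expression import normalize_expression
from slidefactors.synthetic import (
    SynthExpressionConfig,
    SynthSlideConfig,
    generate_cohort,
    generate_expression,
)


@pytest.fixture(scope="session")
def planted_expression():
    """Block-structured expression with 3 planted factors (module-test scale)."""
    cfg = SynthExpressionConfig(
        n_samples=300, n_factors=3, genes_per_factor=30, n_background_genes=60,
        overlap_fraction=0.0, seed=0,
    )
    return generate_expression(cfg)


@pytest.fixture(scope="session")
def planted_matrix(planted_expression):
    return normalize_expression(
        planted_expression.matrix.to_frame(), already_log2=True
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny coupled cohort for cross-module tests (fast on one CPU)."""
    return generate_cohort(
        SynthExpressionConfig(n_samples=40, n_factors=2, genes_per_factor=10,
                              n_background_genes=20, seed=1),
        SynthSlideConfig(grid=(8, 8), feature_dim=16, seed=1),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
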