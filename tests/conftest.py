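import numpy as np
import pandas as pd
import pytest

from regulon_coupler.io import CohortAnnotation, ExpressionMatrix


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples, no missing values."""
    return ExpressionMatrix(
        pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [1.0, 3.0, 2.0, 4.0]],
            index=["TF1", "GENEA", "GENEB"],
            columns=["s1", "s2", "s3", "s4"],
        )
    )


@pytest.fixture
def two_cohort_data():
    """Deterministic two-cohort matrix: GENEA tracks TF1 in cohort A only."""
    rng = np.random.default_rng(42)
    n_a, n_b = 30, 40
    samples = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    tf = rng.normal(0, 1, n_a + n_b)
    coupled = np.concatenate(
        [tf[:n_a] + rng.normal(0, 0.2, n_a), rng.normal(0, 1, n_b)]
    )
    noise = rng.normal(0, 1, n_a + n_b)
    mat = ExpressionMatrix(
        pd.DataFrame(
            [tf, coupled, noise],
            index=["TF1", "GENEA", "GENEB"],
            columns=samples,
        )
    )
    ann = CohortAnnotation(
        pd.Series(["A"] * n_a + ["B"] * n_b, index=samples)
    )
    return mat, ann
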