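from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from clrnorm.io import ExpressionMatrix

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def assessment_fixture_path() -> Path:
    """TSV transcription of the 16-candidate assessment summary."""
    return DATA_DIR / "candidate_assessments.tsv"


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x 2 samples, strictly positive."""
    return ExpressionMatrix(
        pd.DataFrame(
            [[1.0, 3.0], [10.0, 30.0], [100.0, 3.0]],
            index=["g1", "g2", "g3"],
            columns=["s1", "s2"],
        )
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_positive_matrix(
    rng: np.random.Generator, n_genes: int, n_samples: int
) -> ExpressionMatrix:
    values = rng.lognormal(mean=3.0, sigma=1.0, size=(n_genes, n_samples))
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
    )
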