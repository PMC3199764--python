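"""Shared fixtures: small generated matrices used across the suite."""

import numpy as np
import pytest

from periodsig.matrix_io import ExpressionMatrix
from periodsig.preprocess import RowStandardizer
from periodsig.synthetic import figure1_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng) -> ExpressionMatrix:
    """8 x 10 random matrix with distinct values (generic input)."""
    values = rng.standard_normal((8, 10))
    return ExpressionMatrix(
        [f"g{i}" for i in range(1, 9)],
        [f"t{j}" for j in range(1, 11)],
        values,
    )


@pytest.fixture
def standardized_matrix(rng) -> ExpressionMatrix:
    """50 x 24 standardized Gaussian noise matrix."""
    values = RowStandardizer().fit_transform(rng.standard_normal((50, 24)))
    return ExpressionMatrix(
        [f"g{i}" for i in range(1, 51)],
        [f"t{j}" for j in range(1, 25)],
        values,
    )


@pytest.fixture
def figure1() -> ExpressionMatrix:
    return figure1_fixture(seed=0)
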