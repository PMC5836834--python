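import numpy as np
import pytest

from circaphase import TimeDesign, generate_expression


@pytest.fixture
def design4() -> TimeDesign:
    """4-h sampling of a 24-h period over two cycles (12 samples, 6 phases)."""
    return TimeDesign(period_h=24.0, interval_h=4.0, n_cycles=2)


@pytest.fixture
def design3() -> TimeDesign:
    """3-h sampling of a 24-h period over two cycles (16 samples, 8 phases)."""
    return TimeDesign(period_h=24.0, interval_h=3.0, n_cycles=2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240301)


@pytest.fixture
def small_matrix(design4):
    matrix, truth = generate_expression(
        design=design4, n_genes=60, frac_oscillating=0.5, seed=11
    )
    return matrix, truth


def zscore_rows(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
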