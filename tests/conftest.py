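import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from spatialpca import kernels
from spatialpca.io import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def standardized_expr(values: np.ndarray) -> ExpressionMatrix:
    """Row-standardize a matrix and wrap it as an ExpressionMatrix."""
    values = np.asarray(values, float)
    values = (values - values.mean(axis=1, keepdims=True)) / values.std(
        axis=1, ddof=1, keepdims=True
    )
    m, n = values.shape
    return ExpressionMatrix(
        values,
        gene_ids=[f"g{i}" for i in range(m)],
        location_ids=[f"s{i}" for i in range(n)],
        state="standardized",
    )


def random_kernel(rng, n, gamma=1.0, variance_threshold=1.0):
    """Full-rank Gaussian kernel on random scaled 2-D coordinates."""
    coords = kernels.scale_coordinates(
        kernels.SpatialCoordinates(rng.normal(size=(n, 2)))
    )
    return kernels.lowrank_eigen(
        kernels.build_kernel(coords, gamma), variance_threshold
    )
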