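import numpy as np
import pytest

from copclust import DistanceMatrix, TimeSeries


@pytest.fixture
def micro_pair():
    """The hand-checkable three-point pair used throughout the distance tests."""
    return TimeSeries("X", [1.0, 2.0, 3.0]), TimeSeries("Y", [3.0, 1.0, 2.0])


@pytest.fixture
def three_point_matrix():
    """d(1,2)=0.1, d(1,3)=d(2,3)=1: one tight pair plus an outlier."""
    return DistanceMatrix(
        ids=("S1", "S2", "S3"),
        values=np.array([[0.0, 0.1, 1.0], [0.1, 0.0, 1.0], [1.0, 1.0, 0.0]]),
    )


def random_distance_matrix(rng, n):
    A = rng.random((n, n))
    A = 0.5 * (A + A.T)
    np.fill_diagonal(A, 0.0)
    return DistanceMatrix(ids=tuple(f"s{i}" for i in range(n)), values=A)
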