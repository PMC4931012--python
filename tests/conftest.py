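import numpy as np
import pandas as pd
import pytest

from infantgut.community import DistanceMatrix
from infantgut.profiles import AbundanceTable, EnvironmentTable, SampleMetadata


@pytest.fixture
def tiny_table() -> AbundanceTable:
    """Four samples over three families with clear dominance structure."""
    df = pd.DataFrame(
        [
            [0.8, 0.1, 0.1],
            [0.7, 0.2, 0.1],
            [0.1, 0.8, 0.1],
            [0.2, 0.7, 0.1],
        ],
        index=["a1", "a2", "b1", "b2"],
        columns=["Bifidobacteriaceae", "Enterobacteriaceae", "Staphylococcaceae"],
    )
    return AbundanceTable(df)


@pytest.fixture
def tiny_meta() -> SampleMetadata:
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "b1", "b2"],
                "subject_id": ["A", "A", "B", "B"],
                "day": [1, 3, 1, 3],
                "cohort": ["infant_longitudinal"] * 4,
            }
        )
    )


@pytest.fixture
def tiny_env() -> EnvironmentTable:
    return EnvironmentTable(
        pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "b1", "b2"],
                "pH": [5.2, 5.4, 6.8, np.nan],
                "acetate": [70.0, 65.0, 20.0, 25.0],
            }
        )
    )


def euclidean_distance_matrix(points: np.ndarray, ids=None) -> DistanceMatrix:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    ids = ids or [f"s{i}" for i in range(len(pts))]
    return DistanceMatrix(ids, d)
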