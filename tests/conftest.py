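import numpy as np
import pytest

from dismap.data_model import AdjacencyStructure, IncidenceDataset


def make_dataset(counts, at_risk, edges, std_weights=None, adi=None, x2=None,
                 races=None):
    """Build a small validated dataset from raw arrays.

    counts: (I, R, A); at_risk: (I, R); edges: undirected (i, j) pairs.
    """
    counts = np.asarray(counts)
    I, R, A = counts.shape
    counties = tuple(f"c{i}" for i in range(I))
    adj = AdjacencyStructure(counties, tuple(tuple(e) for e in edges))
    if std_weights is None:
        std_weights = np.full(A, 1.0 / A)
    if adi is None:
        adi = np.arange(I, dtype=float) + 1.0
    if x2 is None:
        x2 = np.zeros(I, dtype=int)
    return IncidenceDataset(
        counties=counties,
        races=tuple(races) if races is not None else tuple(range(R)),
        age_labels=tuple(f"a{k}" for k in range(A)),
        counts=counts,
        at_risk=np.asarray(at_risk),
        std_weights=np.asarray(std_weights, dtype=float),
        adi_score=np.asarray(adi, dtype=float),
        x2=np.asarray(x2, dtype=int),
        adjacency=adj,
    )


@pytest.fixture
def toy_dataset():
    """3 counties on a path, 2 races, 1 age group."""
    counts = np.array([[[20], [5]], [[15], [3]], [[25], [8]]])
    at_risk = np.array([[500, 200], [400, 150], [600, 250]])
    return make_dataset(counts, at_risk, [(0, 1), (1, 2)])


@pytest.fixture
def single_cell_dataset():
    """One county, one race, one age group: y* = 50, n = 1000."""
    return make_dataset(
        np.array([[[50]]]), np.array([[1000]]), [], races=(0,)
    )
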