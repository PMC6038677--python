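import numpy as np
import pytest

from tlhnmda.datasets_io import BipartiteAssociations, DiseaseDAG
from tlhnmda.synthetic import SyntheticSpec, generate


@pytest.fixture
def toy_dag():
    """Three-node tree: D2 and D3 are siblings under the root D1."""
    return DiseaseDAG(("D1", "D2", "D3"), frozenset({("D2", "D1"), ("D3", "D1")}))


@pytest.fixture
def chain_dag():
    """Chain D3 -> D2 -> D1."""
    return DiseaseDAG(("D1", "D2", "D3"), frozenset({("D3", "D2"), ("D2", "D1")}))


@pytest.fixture
def diamond_dag():
    """Diamond: D4 has parents D2 and D3, both children of D1."""
    return DiseaseDAG(
        ("D1", "D2", "D3", "D4"),
        frozenset({("D4", "D2"), ("D4", "D3"), ("D2", "D1"), ("D3", "D1")}),
    )


@pytest.fixture(scope="session")
def default_dataset():
    """Default-scale synthetic dataset with planted clusters (seed 0)."""
    return generate(SyntheticSpec())


@pytest.fixture(scope="session")
def small_dataset():
    """Small, strongly clustered dataset for fast end-to-end runs."""
    return generate(SyntheticSpec(nd=10, nm=12, nl=8, n_clusters=2,
                                  p_in=0.8, p_out=0.05, seed=3))


def random_connected_layers(rng, nd=3, nm=4, nl=5, p=0.5):
    """Random binary A (nd x nm) and B (nm x nl) without zero rows/columns.

    Zero-degree entities (cold-start nodes) are outside the model's scope;
    resample until every row and column has at least one positive.
    """
    while True:
        A = (rng.random((nd, nm)) < p).astype(float)
        B = (rng.random((nm, nl)) < p).astype(float)
        if (A.sum(0).min() > 0 and A.sum(1).min() > 0
                and B.sum(0).min() > 0 and B.sum(1).min() > 0):
            return A, B


def random_similarity(rng, n):
    """Random symmetric similarity-like matrix with unit diagonal."""
    M = rng.random((n, n))
    M = (M + M.T) / 2
    np.fill_diagonal(M, 1.0)
    return M


def as_assoc(A, row_prefix="r", col_prefix="c"):
    rows = tuple(f"{row_prefix}{i:02d}" for i in range(A.shape[0]))
    cols = tuple(f"{col_prefix}{j:02d}" for j in range(A.shape[1]))
    return BipartiteAssociations(rows, cols, A)
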