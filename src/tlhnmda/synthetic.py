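"""Synthetic triple-layer datasets with planted cluster structure.

Real inputs to the model are curated databases (disease-miRNA associations,
miRNA-lncRNA interactions, a MeSH-derived disease DAG).  The generator
stands in for them with a controllable planted-signal design: diseases,
miRNAs and lncRNAs are partitioned into matched clusters; a pair whose
entities share a cluster is associated with probability ``p_in``, otherwise
``p_out``; and the disease DAG is a rooted tree whose subtrees follow the
disease clusters, so cluster-mates share ancestors and are semantically
similar.  With ``p_in > p_out`` every stage of the pipeline has signal to
recover; with ``p_in == p_out`` the data carry no signal and
cross-validation should sit at chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .datasets_io import BipartiteAssociations, DataError, DiseaseDAG

logger = logging.getLogger(__name__)

__all__ = ["SyntheticSpec", "generate", "perturb"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Design of a synthetic triple-layer dataset.

    nd, nm, nl: numbers of diseases, miRNAs and lncRNAs.
    n_clusters: number of matched clusters spanning the three layers.
    p_in / p_out: association probability for pairs inside / outside
        matched clusters (both bipartite layers).
    dag_branching: branching factor of the per-cluster disease subtrees.
    seed: RNG seed; the output is fully reproducible from it.
    """

    nd: int = 30
    nm: int = 40
    nl: int = 25
    n_clusters: int = 4
    p_in: float = 0.3
    p_out: float = 0.02
    dag_branching: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.nd, self.nm, self.nl) < 1 or self.n_clusters < 1:
            raise ValueError("entity counts and n_clusters must be positive")
        if self.n_clusters > min(self.nd, self.nm, self.nl):
            raise ValueError("n_clusters may not exceed the smallest layer")
        if not (0.0 <= self.p_out <= self.p_in <= 1.0):
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if self.dag_branching < 1:
            raise ValueError("dag_branching must be positive")


def _labels(prefix: str, n: int) -> tuple[str, ...]:
    width = len(str(n))
    return tuple(f"{prefix}{i + 1:0{width}d}" for i in range(n))


def _clusters(n: int, k: int) -> np.ndarray:
    """Round-robin cluster assignment: entity i -> cluster i mod k."""
    return np.arange(n) % k


def _sample_layer(
    rng: np.random.Generator,
    row_clusters: np.ndarray,
    col_clusters: np.ndarray,
    p_in: float,
    p_out: float,
) -> np.ndarray:
    """Bernoulli block matrix with >= 1 positive per row and column.

    Deficient rows/columns are resampled from the same block probabilities
    (up to 1000 rounds) so no entity is completely isolated — isolated
    entities would make their kernel profile empty and their held-out
    ranking meaningless.
    """
    probs = np.where(row_clusters[:, None] == col_clusters[None, :], p_in, p_out)
    mat = (rng.random(probs.shape) < probs).astype(np.int8)
    resamples = 0
    for _ in range(1000):
        zero_rows = np.flatnonzero(mat.sum(axis=1) == 0)
        for r in zero_rows:
            mat[r] = rng.random(probs.shape[1]) < probs[r]
            resamples += 1
        zero_cols = np.flatnonzero(mat.sum(axis=0) == 0)
        for c in zero_cols:
            mat[:, c] = rng.random(probs.shape[0]) < probs[:, c]
            resamples += 1
        if mat.sum(axis=1).min() > 0 and mat.sum(axis=0).min() > 0:
            if resamples:
                logger.info("resampled %d deficient rows/columns", resamples)
            return mat
    raise DataError(
        "could not guarantee >= 1 positive per row/column after 1000 resampling rounds; "
        "association probabilities are too small"
    )


def _cluster_tree(
    labels: tuple[str, ...], clusters: np.ndarray, branching: int
) -> DiseaseDAG:
    """Rooted tree whose subtrees are the disease clusters.

    The first disease of cluster 0 is the global root; the first member of
    every other cluster attaches to it.  Within each cluster the members
    form a ``branching``-ary tree, so cluster-mates share deep ancestors
    while members of different clusters share only the root.
    """
    members: dict[int, list[str]] = {}
    for lab, c in zip(labels, clusters):
        members.setdefault(int(c), []).append(lab)
    root = members[0][0]
    edges: set[tuple[str, str]] = set()
    for c, labs in sorted(members.items()):
        if c != 0:
            edges.add((labs[0], root))
        for j in range(1, len(labs)):
            parent = labs[(j - 1) // branching]
            edges.add((labs[j], parent))
    return DiseaseDAG(labels, frozenset(edges))


def generate(
    spec: SyntheticSpec,
) -> tuple[
    DiseaseDAG,
    BipartiteAssociations,
    BipartiteAssociations,
    dict[str, set[str]],
    dict[str, np.ndarray],
]:
    """Generate a full synthetic dataset.

    Returns (dag, A, B, disease_sets, truth) where ``A`` is disease x miRNA,
    ``B`` is miRNA x lncRNA, ``disease_sets[m]`` lists the diseases
    associated with miRNA m in A, and ``truth`` maps each layer name to its
    planted cluster labels (in label order).
    """
    rng = np.random.default_rng(spec.seed)
    d_labels = _labels("d", spec.nd)
    m_labels = _labels("m", spec.nm)
    l_labels = _labels("l", spec.nl)
    d_clust = _clusters(spec.nd, spec.n_clusters)
    m_clust = _clusters(spec.nm, spec.n_clusters)
    l_clust = _clusters(spec.nl, spec.n_clusters)

    dag = _cluster_tree(d_labels, d_clust, spec.dag_branching)
    a_mat = _sample_layer(rng, d_clust, m_clust, spec.p_in, spec.p_out)
    b_mat = _sample_layer(rng, m_clust, l_clust, spec.p_in, spec.p_out)
    A = BipartiteAssociations(d_labels, m_labels, a_mat)
    B = BipartiteAssociations(m_labels, l_labels, b_mat)
    disease_sets = {
        m: {d_labels[i] for i in np.flatnonzero(a_mat[:, j])}
        for j, m in enumerate(m_labels)
    }
    truth = {"disease": d_clust.copy(), "mirna": m_clust.copy(), "lncrna": l_clust.copy()}
    return dag, A, B, disease_sets, truth


def perturb(
    A: BipartiteAssociations, flip_rate: float, seed: int
) -> BipartiteAssociations:
    """Flip each entry independently with probability ``flip_rate``."""
    if not (0.0 <= flip_rate <= 1.0):
        raise ValueError("flip_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    flips = rng.random(A.matrix.shape) < flip_rate
    return BipartiteAssociations(
        A.row_labels, A.col_labels, np.where(flips, 1 - A.matrix, A.matrix)
    )
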