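"""Similarity matrices feeding the triple-layer propagation model.

Five families of similarity are constructed here:

* **Disease semantic similarity, model 1** — each disease term contributes
  to its descendants with a per-edge decay ``delta`` (the semantic
  contribution factor); two diseases are similar in proportion to the
  contributions of their shared DAG ancestors.
* **Disease semantic similarity, model 2** — an information-content
  variant: a term appearing in few disease DAGs is more specific and
  contributes ``-log(n_DAGs_containing_term / n_diseases)``.
* **miRNA functional similarity** — the MISIM construction: two miRNAs are
  similar when their associated disease sets are semantically similar,
  using the best-match average of pairwise disease similarities.
* **Gaussian interaction-profile kernels** — ``exp(-gamma * ||IP(u) -
  IP(v)||^2)`` over binary association profiles, with the bandwidth gamma
  normalized by the mean squared profile norm.
* **Integrated similarities** ``SM`` (miRNA) and ``SD`` (disease) — the
  kernel averaged with the knowledge-based similarity wherever the latter
  is defined, the kernel alone elsewhere.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .datasets_io import BipartiteAssociations, DataError, DiseaseDAG, SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SemanticConfig",
    "KernelConfig",
    "semantic_contribution_m1",
    "semantic_value",
    "semantic_similarity_m1",
    "semantic_contribution_m2",
    "semantic_similarity_m2",
    "combined_semantic_similarity",
    "mirna_functional_similarity",
    "gaussian_profile_kernel",
    "integrate_mirna_similarity",
    "integrate_disease_similarity",
]


@dataclass(frozen=True)
class SemanticConfig:
    """Parameters of the semantic similarity models.

    delta: semantic contribution factor in (0, 1); each DAG edge attenuates
        an ancestor's contribution by this factor (model 1).
    log_base: "natural" or "10", the logarithm used by model 2.
    selfsim_degenerate: self-similarity assigned in model 2 to a disease
        whose semantic value is zero (a root term present in every DAG).
    """

    delta: float = 0.5
    log_base: str = "natural"
    selfsim_degenerate: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.delta < 1.0):
            raise ValueError(f"delta must lie strictly in (0, 1), got {self.delta}")
        if self.log_base not in ("natural", "10"):
            raise ValueError("log_base must be 'natural' or '10'")

    def _log(self, x: float) -> float:
        return math.log10(x) if self.log_base == "10" else math.log(x)


@dataclass(frozen=True)
class KernelConfig:
    """Bandwidth scale factors for the three interaction-profile kernels."""

    gamma_prime_d: float = 1.0
    gamma_prime_m: float = 1.0
    gamma_prime_l: float = 1.0

    def __post_init__(self) -> None:
        for name in ("gamma_prime_d", "gamma_prime_m", "gamma_prime_l"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def semantic_contribution_m1(
    dag: DiseaseDAG, D: str, cfg: SemanticConfig | None = None
) -> dict[str, float]:
    """Model-1 contribution of every term in T(D) to disease D.

    D itself contributes 1; an ancestor contributes ``delta`` times the
    largest contribution among its children inside T(D), so contributions
    decay geometrically with distance from D.
    """
    cfg = cfg or SemanticConfig()
    if D not in dag._ancestor_sets:
        raise DataError(f"disease {D!r} not in DAG")
    t_d = dag.ancestors(D)
    memo: dict[str, float] = {D: 1.0}

    def contrib(d: str) -> float:
        if d not in memo:
            memo[d] = max(
                cfg.delta * contrib(c) for c in dag.children(d) if c in t_d
            )
        return memo[d]

    for d in t_d:
        contrib(d)
    return memo


def semantic_value(contributions: Mapping[str, float]) -> float:
    """Semantic value DV of a disease: the sum of its term contributions."""
    if not contributions:
        raise DataError("empty contribution map")
    return float(sum(contributions.values()))


def _pairwise_semantic(
    dag: DiseaseDAG,
    contribs: Mapping[str, Mapping[str, float]],
    values: Mapping[str, float],
    degenerate_selfsim: float | None = None,
) -> SimilarityMatrix:
    """Shared combination rule of both semantic models.

    SS(i, j) = sum over shared terms t of (C_i(t) + C_j(t)), divided by
    DV(i) + DV(j).  When both semantic values are zero (only possible in
    model 2) the pair is degenerate: the diagonal receives the configured
    self-similarity, off-diagonal pairs receive 0.
    """
    nodes = dag.nodes
    n = len(nodes)
    mat = np.zeros((n, n))
    n_degenerate = 0
    for i, di in enumerate(nodes):
        ti, ci = dag.ancestors(di), contribs[di]
        for j in range(i, n):
            dj = nodes[j]
            denom = values[di] + values[dj]
            if denom == 0.0:
                n_degenerate += 1
                val = degenerate_selfsim if i == j else 0.0
            elif i == j:
                val = 1.0
            else:
                cj = contribs[dj]
                shared = ti & dag.ancestors(dj)
                val = sum(ci[t] + cj[t] for t in shared) / denom
            mat[i, j] = mat[j, i] = val
    if n_degenerate:
        logger.info("%d degenerate (zero semantic value) disease pairs", n_degenerate)
    return SimilarityMatrix(nodes, mat)


def semantic_similarity_m1(
    dag: DiseaseDAG, cfg: SemanticConfig | None = None
) -> SimilarityMatrix:
    """Disease semantic similarity model 1 over all DAG nodes."""
    cfg = cfg or SemanticConfig()
    contribs = {d: semantic_contribution_m1(dag, d, cfg) for d in dag.nodes}
    values = {d: semantic_value(c) for d, c in contribs.items()}
    return _pairwise_semantic(dag, contribs, values)


def semantic_contribution_m2(
    dag: DiseaseDAG, cfg: SemanticConfig | None = None
) -> dict[str, float]:
    """Model-2 contribution of each term: -log(fraction of DAGs containing it).

    A term contained in every disease's DAG (a ubiquitous root) contributes
    0; rarer, more specific terms contribute more.
    """
    cfg = cfg or SemanticConfig()
    n = len(dag.nodes)
    return {
        d: -cfg._log(len(dag.dag_membership[d]) / n) for d in dag.nodes
    }


def semantic_similarity_m2(
    dag: DiseaseDAG, cfg: SemanticConfig | None = None
) -> SimilarityMatrix:
    """Disease semantic similarity model 2 over all DAG nodes."""
    cfg = cfg or SemanticConfig()
    dd2 = semantic_contribution_m2(dag, cfg)
    contribs = {d: {t: dd2[t] for t in dag.ancestors(d)} for d in dag.nodes}
    values = {d: float(sum(c.values())) for d, c in contribs.items()}
    return _pairwise_semantic(dag, contribs, values, cfg.selfsim_degenerate)


def combined_semantic_similarity(
    ss1: SimilarityMatrix, ss2: SimilarityMatrix
) -> SimilarityMatrix:
    """Entrywise mean of the two semantic models; coverage intersects."""
    if ss1.labels != ss2.labels:
        raise DataError("semantic similarity matrices have different label sets")
    return SimilarityMatrix(
        ss1.labels, (ss1.matrix + ss2.matrix) / 2.0, ss1.coverage & ss2.coverage
    )


def mirna_functional_similarity(
    disease_sets: Mapping[str, set[str]],
    ss: SimilarityMatrix,
) -> SimilarityMatrix:
    """MISIM-style functional similarity from associated disease sets.

    For miRNAs m_i, m_j with disease sets D_i, D_j, every disease of one set
    is matched to its most similar disease in the other set and the matched
    similarities are averaged:

        FS(i, j) = [ sum_{d in D_i} max_{d' in D_j} SS(d, d')
                   + sum_{d in D_j} max_{d' in D_i} SS(d, d') ]
                   / (|D_i| + |D_j|)

    Pairs where either disease set is empty are left uncovered.
    """
    mirnas = tuple(sorted(disease_sets))
    missing = {d for s in disease_sets.values() for d in s} - set(ss.labels)
    if missing:
        raise DataError(f"diseases absent from the similarity matrix: {sorted(missing)}")
    idx_sets = {
        m: np.array(sorted(ss.index[d] for d in s), dtype=int)
        for m, s in disease_sets.items()
    }
    n = len(mirnas)
    mat = np.zeros((n, n))
    cov = np.zeros((n, n), dtype=bool)
    for i, mi in enumerate(mirnas):
        ai = idx_sets[mi]
        if ai.size == 0:
            continue
        for j in range(i, n):
            aj = idx_sets[mirnas[j]]
            if aj.size == 0:
                continue
            sub = ss.matrix[np.ix_(ai, aj)]
            val = (sub.max(axis=1).sum() + sub.max(axis=0).sum()) / (ai.size + aj.size)
            if not (-1e-10 <= val <= 1 + 1e-10):
                raise DataError(f"functional similarity {val} outside [0, 1]")
            mat[i, j] = mat[j, i] = val
            cov[i, j] = cov[j, i] = True
    return SimilarityMatrix(mirnas, mat, cov)


def gaussian_profile_kernel(
    profiles: BipartiteAssociations,
    axis: str,
    gamma_prime: float = 1.0,
) -> SimilarityMatrix:
    """Gaussian kernel over binary interaction profiles.

    With ``axis="rows"`` each row of the bipartite matrix is an entity's
    interaction profile IP; ``axis="cols"`` uses columns.  The bandwidth is
    gamma = gamma_prime / mean(||IP||^2), so the kernel scale adapts to the
    average profile size.  K(u, v) = exp(-gamma * ||IP(u) - IP(v)||^2);
    the diagonal is exactly 1.
    """
    if axis not in ("rows", "cols"):
        raise ValueError("axis must be 'rows' or 'cols'")
    if gamma_prime <= 0:
        raise ValueError("gamma_prime must be strictly positive")
    if axis == "rows":
        p = profiles.matrix.astype(float)
        labels = profiles.row_labels
    else:
        p = profiles.matrix.T.astype(float)
        labels = profiles.col_labels
    mean_sq = float((p ** 2).sum(axis=1).mean())
    if mean_sq == 0.0:
        raise DataError("all profiles empty; kernel undefined")
    gamma = gamma_prime / mean_sq
    if p.shape[0] > 1:
        d2 = squareform(pdist(p, metric="sqeuclidean"))
    else:
        d2 = np.zeros((1, 1))
    k = np.exp(-gamma * d2)
    np.fill_diagonal(k, 1.0)
    return SimilarityMatrix(labels, k)


def _integrate(kernel: SimilarityMatrix, knowledge: SimilarityMatrix | None) -> SimilarityMatrix:
    """Average kernel with knowledge similarity where defined, else kernel."""
    if knowledge is None:
        return SimilarityMatrix(kernel.labels, kernel.matrix.copy())
    out = kernel.matrix.copy()
    common = [lab for lab in kernel.labels if lab in knowledge.index]
    if common:
        ki = np.array([kernel.index[l] for l in common])
        si = np.array([knowledge.index[l] for l in common])
        cov = knowledge.coverage[np.ix_(si, si)]
        blended = (kernel.matrix[np.ix_(ki, ki)] + knowledge.matrix[np.ix_(si, si)]) / 2.0
        block = out[np.ix_(ki, ki)]
        block[cov] = blended[cov]
        out[np.ix_(ki, ki)] = block
    return SimilarityMatrix(kernel.labels, out)


def integrate_mirna_similarity(
    km: SimilarityMatrix, fs: SimilarityMatrix | None
) -> SimilarityMatrix:
    """Integrated miRNA similarity SM: mean of kernel and functional
    similarity where the latter is covered, the kernel elsewhere."""
    return _integrate(km, fs)


def integrate_disease_similarity(
    kd: SimilarityMatrix, ss: SimilarityMatrix | None
) -> SimilarityMatrix:
    """Integrated disease similarity SD: mean of kernel and semantic
    similarity where the latter is covered, the kernel elsewhere."""
    return _integrate(kd, ss)
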