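"""Cross-validation harness: global LOOCV, repeated k-fold, ROC/AUC.

The validation protocol holds out known disease-miRNA positives, reruns the
propagation model on the censored association matrix, and compares the
held-out scores with the scores of all candidate pairs (pairs with no known
association anywhere in the full matrix).  AUC is computed by the
rank/Mann-Whitney statistic, AUC = P(pos > neg) + 0.5 * P(pos = neg), which
equals trapezoidal integration of the ROC curve; ROC points are still
emitted for plotting.

Knowledge-based similarities (disease semantic similarity and miRNA
functional similarity) derive from external annotation, not from the
association matrix under test, so they are computed once and never refit.
The interaction-profile kernels DO derive from the association matrix;
``refit=True`` (default) recomputes them after censoring each fold so no
information leaks from held-out entries, ``refit=False`` reuses the
full-data kernels for speed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

from .datasets_io import BipartiteAssociations, DataError, DiseaseDAG, SimilarityMatrix
from .propagation import PropagationConfig, tlhnmda
from .similarity import (
    KernelConfig,
    SemanticConfig,
    combined_semantic_similarity,
    gaussian_profile_kernel,
    integrate_disease_similarity,
    integrate_mirna_similarity,
    mirna_functional_similarity,
    semantic_similarity_m1,
    semantic_similarity_m2,
)

logger = logging.getLogger(__name__)

__all__ = ["CVOptions", "CVResult", "roc_auc", "global_loocv", "kfold_cv"]


@dataclass(frozen=True)
class CVOptions:
    """Cross-validation policy knobs.

    refit: recompute the interaction-profile kernels (and hence SM/SD)
        after censoring each fold.
    candidate_scores: "per_fold" compares each held-out score with the
        candidate scores of its own fold's model; "full_model" uses one
        uncensored run's candidate scores for every fold.
    candidate_pool: "global" pools candidate pairs over all diseases (the
        protocol's default); "per_disease" restricts each held-out pair's
        candidates to the same disease row (diagnostic).
    """

    refit: bool = True
    candidate_scores: str = "per_fold"
    candidate_pool: str = "global"

    def __post_init__(self) -> None:
        if self.candidate_scores not in ("per_fold", "full_model"):
            raise ValueError("candidate_scores must be 'per_fold' or 'full_model'")
        if self.candidate_pool not in ("global", "per_disease"):
            raise ValueError("candidate_pool must be 'global' or 'per_disease'")


@dataclass
class CVResult:
    """Cross-validation outcome: per-run AUCs plus a pooled ROC curve."""

    auc_per_run: list[float]
    mean_auc: float
    sd_auc: float
    roc_points: list[tuple[float, float]]
    n_test: int
    n_candidate: int
    seed: int | None = None
    degenerate: bool = False


def roc_auc(pos_scores, neg_scores, seed: int | None = None) -> CVResult:
    """AUC and ROC curve from positive and negative score lists.

    AUC is the normalized Mann-Whitney U statistic: the probability that a
    random positive outscores a random negative, ties counting one half.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise DataError("both score lists must be nonempty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    auc = float(u / (pos.size * neg.size))
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    fpr, tpr, _ = roc_curve(y, np.concatenate([pos, neg]))
    all_tied = bool(np.all(pos[:, None] == neg[None, :])) if pos.size * neg.size <= 10**7 else False
    return CVResult(
        auc_per_run=[auc],
        mean_auc=auc,
        sd_auc=0.0,
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        n_test=int(pos.size),
        n_candidate=int(neg.size),
        seed=seed,
        degenerate=all_tied,
    )


@dataclass
class _ModelInputs:
    """Fold-independent quantities cached across CV folds."""

    A: BipartiteAssociations
    B: BipartiteAssociations
    SS: SimilarityMatrix | None
    FS: SimilarityMatrix | None
    KL: SimilarityMatrix
    kernel_cfg: KernelConfig
    prop_cfg: PropagationConfig


def _prepare_inputs(
    A: BipartiteAssociations,
    B: BipartiteAssociations,
    dag: DiseaseDAG | None,
    SS: SimilarityMatrix | None,
    FS: SimilarityMatrix | None,
    semantic_cfg: SemanticConfig,
    kernel_cfg: KernelConfig,
    prop_cfg: PropagationConfig,
) -> _ModelInputs:
    if SS is None and dag is not None:
        SS = combined_semantic_similarity(
            semantic_similarity_m1(dag, semantic_cfg),
            semantic_similarity_m2(dag, semantic_cfg),
        )
    if FS is None and SS is not None:
        disease_sets = {
            m: {d for i, d in enumerate(A.row_labels) if A.matrix[i, j]}
            for j, m in enumerate(A.col_labels)
        }
        FS = mirna_functional_similarity(disease_sets, SS)
    KL = gaussian_profile_kernel(B, "cols", kernel_cfg.gamma_prime_l)
    return _ModelInputs(A, B, SS, FS, KL, kernel_cfg, prop_cfg)


def _run_model(inputs: _ModelInputs, A_censored: np.ndarray) -> np.ndarray:
    """Score matrix from the propagation model on a censored A."""
    A_cv = BipartiteAssociations(inputs.A.row_labels, inputs.A.col_labels, A_censored)
    kd = gaussian_profile_kernel(A_cv, "rows", inputs.kernel_cfg.gamma_prime_d)
    km = gaussian_profile_kernel(A_cv, "cols", inputs.kernel_cfg.gamma_prime_m)
    sm = integrate_mirna_similarity(km, inputs.FS)
    sd = integrate_disease_similarity(kd, inputs.SS)
    scores, _ = tlhnmda(A_cv, inputs.B, sm, sd, inputs.KL, inputs.prop_cfg)
    return scores.dm_scores


def _fold_auc_terms(
    test_scores: np.ndarray, cand_scores: np.ndarray
) -> tuple[float, int, int]:
    """(U contribution, tie count, comparison count) of one fold."""
    gt = (test_scores[:, None] > cand_scores[None, :]).sum()
    ties = (test_scores[:, None] == cand_scores[None, :]).sum()
    return float(gt + 0.5 * ties), int(ties), int(test_scores.size * cand_scores.size)


def _pooled_cv(
    inputs: _ModelInputs,
    folds: list[np.ndarray],
    opts: CVOptions,
) -> tuple[float, bool, list[float], list[float]]:
    """Run the model once per fold, pool the held-out/candidate comparisons.

    ``folds`` lists, per fold, the flat indices (into A) of the positives to
    censor.  Returns (AUC, degenerate flag, pooled positive scores, pooled
    negative scores); the score pools feed the ROC curve only.
    """
    A_full = inputs.A.matrix.astype(float)
    cand_mask = A_full == 0
    full_scores = None
    if not opts.refit or opts.candidate_scores == "full_model":
        full_scores = _run_model(inputs, inputs.A.matrix)
    kernels_cached = None
    if not opts.refit:
        kd = gaussian_profile_kernel(inputs.A, "rows", inputs.kernel_cfg.gamma_prime_d)
        km = gaussian_profile_kernel(inputs.A, "cols", inputs.kernel_cfg.gamma_prime_m)
        kernels_cached = (
            integrate_mirna_similarity(km, inputs.FS),
            integrate_disease_similarity(kd, inputs.SS),
        )
    u_total = 0.0
    ties_total = 0
    pairs_total = 0
    pos_pool: list[float] = []
    neg_pool: list[float] = []
    for fold in folds:
        A_cv = A_full.copy()
        rows, cols = np.unravel_index(fold, A_full.shape)
        A_cv[rows, cols] = 0.0
        if opts.refit:
            W = _run_model(inputs, A_cv)
        else:
            sm, sd = kernels_cached
            A_obj = BipartiteAssociations(inputs.A.row_labels, inputs.A.col_labels, A_cv)
            scores, _ = tlhnmda(A_obj, inputs.B, sm, sd, inputs.KL, inputs.prop_cfg)
            W = scores.dm_scores
        test_scores = W[rows, cols]
        cand_source = full_scores if opts.candidate_scores == "full_model" else W
        if opts.candidate_pool == "global":
            cand = cand_source[cand_mask]
            u, ties, pairs = _fold_auc_terms(test_scores, cand)
            u_total += u
            ties_total += ties
            pairs_total += pairs
            neg_pool.extend(cand.tolist())
        else:
            for r, c, s in zip(rows, cols, test_scores):
                cand = cand_source[r, cand_mask[r]]
                u, ties, pairs = _fold_auc_terms(np.array([s]), cand)
                u_total += u
                ties_total += ties
                pairs_total += pairs
                neg_pool.extend(cand.tolist())
        pos_pool.extend(test_scores.tolist())
    auc = u_total / pairs_total
    degenerate = ties_total == pairs_total
    if degenerate:
        logger.warning("all held-out/candidate comparisons are ties; AUC is degenerate")
    return auc, degenerate, pos_pool, neg_pool


def _roc_from_pools(pos_pool: list[float], neg_pool: list[float]) -> list[tuple[float, float]]:
    y = np.concatenate([np.ones(len(pos_pool)), np.zeros(len(neg_pool))])
    fpr, tpr, _ = roc_curve(y, np.concatenate([pos_pool, neg_pool]))
    return list(zip(fpr.tolist(), tpr.tolist()))


def global_loocv(
    A: BipartiteAssociations,
    B: BipartiteAssociations,
    dag: DiseaseDAG | None = None,
    SS: SimilarityMatrix | None = None,
    FS: SimilarityMatrix | None = None,
    semantic_cfg: SemanticConfig | None = None,
    kernel_cfg: KernelConfig | None = None,
    prop_cfg: PropagationConfig | None = None,
    cv_opts: CVOptions | None = None,
) -> CVResult:
    """Global leave-one-out cross-validation.

    Each known positive of ``A`` is censored in turn, the model rerun, and
    the held-out score compared with the scores of all candidate pairs
    (zero entries of the FULL matrix).  The pooled comparison fraction is
    the LOOCV AUC.
    """
    opts = cv_opts or CVOptions()
    inputs = _prepare_inputs(
        A, B, dag, SS, FS,
        semantic_cfg or SemanticConfig(),
        kernel_cfg or KernelConfig(),
        prop_cfg or PropagationConfig(),
    )
    positives = np.flatnonzero(A.matrix)
    if positives.size < 2:
        raise DataError("LOOCV needs at least 2 known associations")
    folds = [np.array([p]) for p in positives]
    auc, degenerate, pos_pool, neg_pool = _pooled_cv(inputs, folds, opts)
    n_cand = int((A.matrix == 0).sum())
    return CVResult(
        auc_per_run=[auc],
        mean_auc=auc,
        sd_auc=0.0,
        roc_points=_roc_from_pools(pos_pool, neg_pool),
        n_test=int(positives.size),
        n_candidate=n_cand,
        degenerate=degenerate,
    )


def kfold_cv(
    A: BipartiteAssociations,
    B: BipartiteAssociations,
    dag: DiseaseDAG | None = None,
    SS: SimilarityMatrix | None = None,
    FS: SimilarityMatrix | None = None,
    k: int = 5,
    repeats: int = 100,
    seed: int = 0,
    semantic_cfg: SemanticConfig | None = None,
    kernel_cfg: KernelConfig | None = None,
    prop_cfg: PropagationConfig | None = None,
    cv_opts: CVOptions | None = None,
) -> CVResult:
    """Repeated k-fold cross-validation over the known positives.

    Positives are randomly partitioned into k folds of near-equal size
    (differing by at most one); each fold is censored in turn and its
    held-out scores compared with all candidate scores.  Fold comparisons
    are pooled into one AUC per repeat; the result reports mean and sd over
    repeats.  Fully reproducible from ``seed``.
    """
    if k < 2:
        raise DataError("k must be at least 2")
    positives = np.flatnonzero(A.matrix)
    if k > positives.size:
        raise DataError(f"k={k} exceeds the {positives.size} known associations")
    if repeats < 1:
        raise DataError("repeats must be positive")
    opts = cv_opts or CVOptions()
    inputs = _prepare_inputs(
        A, B, dag, SS, FS,
        semantic_cfg or SemanticConfig(),
        kernel_cfg or KernelConfig(),
        prop_cfg or PropagationConfig(),
    )
    rng = np.random.default_rng(seed)
    aucs: list[float] = []
    degenerate_any = False
    pos_pool: list[float] = []
    neg_pool: list[float] = []
    for _ in range(repeats):
        perm = rng.permutation(positives)
        folds = [f for f in np.array_split(perm, k) if f.size]
        auc, degenerate, pp, np_ = _pooled_cv(inputs, folds, opts)
        aucs.append(auc)
        degenerate_any |= degenerate
        pos_pool.extend(pp)
        neg_pool.extend(np_)
    mean = float(np.mean(aucs))
    sd = float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0
    return CVResult(
        auc_per_run=aucs,
        mean_auc=mean,
        sd_auc=sd,
        roc_points=_roc_from_pools(pos_pool, neg_pool),
        n_test=int(positives.size),
        n_candidate=int((A.matrix == 0).sum()),
        seed=seed,
        degenerate=degenerate_any,
    )
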