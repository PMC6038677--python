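"""Coupled label propagation on the triple-layer heterogeneous network.

The model iterates two coupled updates from the observed binary matrices
(W_dm^0 = A, W_ml^0 = B):

    W_dm^{k+1} = alpha * W_dm^k @ N(IM^k) + (1 - alpha) * A
    W_ml^{k+1} = alpha * N(ID^k) @ W_ml^k + (1 - alpha) * B

where the coupling matrices are recomputed each step from the current
iterates,

    IM^k = SM @ W_ml^k @ KL @ W_ml^k.T        (miRNA x miRNA)
    ID^k = W_dm^k.T @ SD @ W_dm^k @ SM        (miRNA x miRNA)

and N(.) is a row-sum normalization.  alpha in (0, 1) is a restart-style
decay factor: the observed associations are re-injected with weight
1 - alpha at every step, which anchors known links and, together with the
normalization, makes the iteration contract to a fixed point.  Iteration
stops when the L1 change of W_dm (optionally also W_ml) drops below the
cutoff.

Two normalization variants are provided.  ``symmetric_sqrt`` divides entry
(i, j) by sqrt(rowsum_i * rowsum_j), which bounds the spectral radius of
the normalized coupling by 1 and guarantees contraction for alpha < 1.
``row_product_literal`` divides by the plain product rowsum_i * rowsum_j;
it normalizes much more aggressively and is kept for fidelity experiments.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .datasets_io import BipartiteAssociations, DataError, SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PropagationConfig",
    "PropagationState",
    "PredictionScores",
    "coupling_IM",
    "coupling_ID",
    "normalize_coupling",
    "tlhnmda",
    "one_shot_disease_lncrna",
    "rank_candidates",
]

_NORMALIZATIONS = ("symmetric_sqrt", "row_product_literal")


@dataclass(frozen=True)
class PropagationConfig:
    """Iteration parameters.

    alpha: decay factor in (0, 1); weight of the propagated term versus the
        observed associations.
    cutoff: L1 stopping threshold on the change of the iterates.
    max_iter: hard cap on iterations.
    normalization: "symmetric_sqrt" (default) or "row_product_literal".
    track: "dm_only" checks convergence on W_dm; "both" additionally
        requires the W_ml change below cutoff.
    """

    alpha: float = 0.4
    cutoff: float = 1e-6
    max_iter: int = 1000
    normalization: str = "symmetric_sqrt"
    track: str = "dm_only"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie strictly in (0, 1), got {self.alpha}")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be a positive integer")
        if self.normalization not in _NORMALIZATIONS:
            raise ValueError(f"normalization must be one of {_NORMALIZATIONS}")
        if self.track not in ("dm_only", "both"):
            raise ValueError("track must be 'dm_only' or 'both'")


@dataclass
class PropagationState:
    """Final iterates plus convergence telemetry."""

    W_dm: np.ndarray
    W_ml: np.ndarray
    iteration: int
    delta_dm: float
    delta_ml: float
    converged: bool


@dataclass
class PredictionScores:
    """Converged association scores with label context and provenance."""

    dm_scores: np.ndarray
    ml_scores: np.ndarray
    disease_labels: tuple[str, ...]
    mirna_labels: tuple[str, ...]
    lncrna_labels: tuple[str, ...]
    provenance: dict = field(default_factory=dict)


def coupling_IM(
    SM: np.ndarray, W_ml: np.ndarray, KL: np.ndarray
) -> np.ndarray:
    """miRNA x miRNA coupling through the lncRNA layer: SM @ W_ml @ KL @ W_ml.T."""
    SM, W_ml, KL = (np.asarray(x, dtype=float) for x in (SM, W_ml, KL))
    nm, nl = W_ml.shape
    if SM.shape != (nm, nm) or KL.shape != (nl, nl):
        raise DataError(
            f"non-conformable coupling shapes: SM {SM.shape}, W_ml {W_ml.shape}, KL {KL.shape}"
        )
    return SM @ W_ml @ KL @ W_ml.T


def coupling_ID(
    SD: np.ndarray, W_dm: np.ndarray, SM: np.ndarray
) -> np.ndarray:
    """miRNA x miRNA coupling through the disease layer: W_dm.T @ SD @ W_dm @ SM."""
    SD, W_dm, SM = (np.asarray(x, dtype=float) for x in (SD, W_dm, SM))
    nd, nm = W_dm.shape
    if SD.shape != (nd, nd) or SM.shape != (nm, nm):
        raise DataError(
            f"non-conformable coupling shapes: SD {SD.shape}, W_dm {W_dm.shape}, SM {SM.shape}"
        )
    return W_dm.T @ SD @ W_dm @ SM


def normalize_coupling(M: np.ndarray, variant: str = "symmetric_sqrt") -> np.ndarray:
    """Row-sum normalization of a nonnegative square coupling matrix.

    symmetric_sqrt:      N(i,j) = M(i,j) / sqrt(rowsum_i * rowsum_j)
    row_product_literal: N(i,j) = M(i,j) / (rowsum_i * rowsum_j)

    Rows with zero sum map to zero rows (0/0 := 0), so isolated nodes
    propagate nothing.
    """
    if variant not in _NORMALIZATIONS:
        raise ValueError(f"normalization must be one of {_NORMALIZATIONS}")
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise DataError("coupling matrix must be square")
    if M.size and M.min() < 0:
        raise DataError("coupling matrix has negative entries")
    rs = M.sum(axis=1)
    denom = np.outer(rs, rs)
    if variant == "symmetric_sqrt":
        denom = np.sqrt(denom)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, M / np.where(denom > 0, denom, 1.0), 0.0)
    return out


def _sha256(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


def tlhnmda(
    A: BipartiteAssociations | np.ndarray,
    B: BipartiteAssociations | np.ndarray,
    SM: SimilarityMatrix | np.ndarray,
    SD: SimilarityMatrix | np.ndarray,
    KL: SimilarityMatrix | np.ndarray,
    cfg: PropagationConfig | None = None,
) -> tuple[PredictionScores, PropagationState]:
    """Run the coupled propagation to convergence.

    ``A`` (disease x miRNA) and ``B`` (miRNA x lncRNA) are the observed
    binary layers; ``SM``, ``SD``, ``KL`` the integrated miRNA, disease and
    lncRNA similarities.  Labeled containers are checked for alignment;
    bare arrays are accepted for low-level use.  Returns the converged
    scores and the final iteration state.
    """
    cfg = cfg or PropagationConfig()
    d_labels, m_labels, l_labels = (), (), ()
    if isinstance(A, BipartiteAssociations):
        d_labels, m_labels = A.row_labels, A.col_labels
    if isinstance(B, BipartiteAssociations):
        if m_labels and B.row_labels != m_labels:
            raise DataError("miRNA labels of A (columns) and B (rows) differ")
        m_labels = m_labels or B.row_labels
        l_labels = B.col_labels
    for sim, labels, name in ((SM, m_labels, "SM"), (SD, d_labels, "SD"), (KL, l_labels, "KL")):
        if isinstance(sim, SimilarityMatrix) and labels and sim.labels != labels:
            raise DataError(f"{name} labels do not match the association matrices")

    def arr(x) -> np.ndarray:
        if isinstance(x, BipartiteAssociations):
            return x.matrix.astype(float)
        if isinstance(x, SimilarityMatrix):
            return x.matrix.astype(float)
        return np.asarray(x, dtype=float)

    A_, B_, SM_, SD_, KL_ = map(arr, (A, B, SM, SD, KL))
    nd, nm = A_.shape
    if B_.shape[0] != nm:
        raise DataError(f"A has {nm} miRNAs but B has {B_.shape[0]} rows")
    nl = B_.shape[1]
    if SM_.shape != (nm, nm) or SD_.shape != (nd, nd) or KL_.shape != (nl, nl):
        raise DataError("similarity matrix shapes do not match the association layers")

    W_dm, W_ml = A_.copy(), B_.copy()
    delta_dm = delta_ml = np.inf
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        NIM = normalize_coupling(coupling_IM(SM_, W_ml, KL_), cfg.normalization)
        NID = normalize_coupling(coupling_ID(SD_, W_dm, SM_), cfg.normalization)
        W_dm_next = cfg.alpha * (W_dm @ NIM) + (1.0 - cfg.alpha) * A_
        W_ml_next = cfg.alpha * (NID @ W_ml) + (1.0 - cfg.alpha) * B_
        if not (np.isfinite(W_dm_next).all() and np.isfinite(W_ml_next).all()):
            raise FloatingPointError(f"non-finite value at iteration {it}")
        delta_dm = float(np.abs(W_dm_next - W_dm).sum())
        delta_ml = float(np.abs(W_ml_next - W_ml).sum())
        W_dm, W_ml = W_dm_next, W_ml_next
        logger.debug("iteration=%d delta_dm=%.3e delta_ml=%.3e", it, delta_dm, delta_ml)
        if delta_dm < cfg.cutoff and (cfg.track != "both" or delta_ml < cfg.cutoff):
            converged = True
            break
    if not converged:
        warnings.warn(
            f"propagation hit max_iter={cfg.max_iter} without reaching cutoff "
            f"(delta_dm={delta_dm:.3e})",
            RuntimeWarning,
            stacklevel=2,
        )
    state = PropagationState(W_dm, W_ml, it, delta_dm, delta_ml, converged)
    scores = PredictionScores(
        dm_scores=W_dm,
        ml_scores=W_ml,
        disease_labels=tuple(d_labels),
        mirna_labels=tuple(m_labels),
        lncrna_labels=tuple(l_labels),
        provenance={
            "alpha": cfg.alpha,
            "cutoff": cfg.cutoff,
            "max_iter": cfg.max_iter,
            "normalization": cfg.normalization,
            "track": cfg.track,
            "iterations": it,
            "converged": converged,
            "input_sha256": _sha256(A_, B_, SM_, SD_, KL_),
        },
    )
    return scores, state


def one_shot_disease_lncrna(
    W_dm: np.ndarray, SM: np.ndarray, W_ml: np.ndarray
) -> np.ndarray:
    """Single-pass disease x lncRNA inference: W_dm @ SM @ W_ml.

    The intermediate disease-lncRNA layer the coupled updates are derived
    from; exposed as a diagnostic by-product.
    """
    W_dm, SM, W_ml = (np.asarray(x, dtype=float) for x in (W_dm, SM, W_ml))
    return W_dm @ SM @ W_ml


def rank_candidates(
    scores: PredictionScores,
    A: BipartiteAssociations,
    disease: str,
) -> list[tuple[str, float]]:
    """Rank candidate miRNAs (no known association) for one disease.

    Returns (miRNA, score) pairs sorted by score descending; ties break on
    the miRNA label ascending, so the ordering is deterministic.
    """
    if disease not in A.row_index:
        raise DataError(f"unknown disease {disease!r}")
    i = A.row_index[disease]
    out = [
        (m, float(scores.dm_scores[i, j]))
        for j, m in enumerate(A.col_labels)
        if A.matrix[i, j] == 0
    ]
    out.sort(key=lambda t: (-t[1], t[0]))
    return out
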