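"""Conventional-PCA-based unsupervised feature extraction (CPCAFE).

Features are embedded as points in PC space via an SVD of the (optionally
preprocessed) feature-by-sample matrix, ``X = B A^T`` with orthonormal
per-sample loadings ``A``; features with the largest absolute projections
``|B_{i,pc}|`` on a chosen component are the extracted outliers.  An
optional pre-filter removes features that are extreme on another component
first (e.g. PC2) before ranking on the selected one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import ExpressionMatrix
from .result import FEResult

__all__ = ["PCAEmbedding", "pca_embed", "cpcafe_select"]


@dataclass
class PCAEmbedding:
    """SVD factorisation of a processed feature-by-sample matrix.

    ``feature_scores`` (N x Q) are the feature projections ``B``;
    ``sample_loadings`` (M x Q) the orthonormal per-sample contributions
    ``A``; ``explained`` the per-component variance shares.
    ``preprocessing`` records exactly what was applied, so a run is
    self-describing.
    """

    feature_scores: np.ndarray
    sample_loadings: np.ndarray
    explained: np.ndarray
    preprocessing: dict = field(default_factory=dict)
    feature_ids: list[str] | None = None
    sample_ids: list[str] | None = None

    @property
    def Q(self) -> int:
        return self.feature_scores.shape[1]


def pca_embed(
    X: ExpressionMatrix | np.ndarray,
    standardize_features: bool = False,
    center: str = "none",
) -> PCAEmbedding:
    """Embed features into PC space.

    If ``standardize_features`` each feature row is shifted and scaled to
    mean 0, sd 1 first (the preprocessing used for real mRNA arrays; a
    zero-variance feature is an error naming the culprit).  ``center`` then
    removes ``"feature"`` (row) or ``"sample"`` (column) means, or nothing
    (``"none"``, the convention for the simulation benchmark, where the
    generator already centres the signal).  The SVD of the processed matrix
    yields ``X_proc = B A^T`` with orthonormal ``A`` columns; each
    component's sign is fixed so that the largest-magnitude entry of its
    sample-loading vector is positive.
    """
    if center not in ("none", "feature", "sample"):
        raise ValueError("center must be 'none', 'feature' or 'sample'")
    em = X if isinstance(X, ExpressionMatrix) else None
    V = (em.values if em is not None else np.asarray(X, dtype=float)).copy()
    if np.isnan(V).any():
        raise ValueError("missing values are not supported")
    if standardize_features:
        sd = V.std(axis=1, ddof=0)
        dead = np.where(sd == 0)[0]
        if dead.size:
            name = em.feature_ids[dead[0]] if em is not None else str(dead[0])
            raise ValueError(f"zero-variance feature under standardization: {name}")
        V = (V - V.mean(axis=1, keepdims=True)) / sd[:, None]
    if center == "feature":
        V = V - V.mean(axis=1, keepdims=True)
    elif center == "sample":
        V = V - V.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(V, full_matrices=False)
    A = Vt.T                       # (M, Q), orthonormal columns
    B = U * S                      # (N, Q)
    for q in range(A.shape[1]):    # deterministic sign convention
        j = np.argmax(np.abs(A[:, q]))
        if A[j, q] < 0:
            A[:, q] = -A[:, q]
            B[:, q] = -B[:, q]
    total = (S**2).sum()
    explained = S**2 / total if total > 0 else np.zeros_like(S)
    return PCAEmbedding(
        B,
        A,
        explained,
        {"standardize_features": standardize_features, "center": center},
        None if em is None else list(em.feature_ids),
        None if em is None else list(em.sample_ids),
    )


def cpcafe_select(
    emb: PCAEmbedding,
    pc: int = 1,
    n_top: int = 10,
    exclude_pc: int | None = None,
    exclude_quantile: float = 0.99,
) -> FEResult:
    """Select the ``n_top`` features with largest ``|B_{i,pc}|``.

    With ``exclude_pc`` set, features whose absolute score on that
    component exceeds its ``exclude_quantile`` quantile are removed before
    ranking (the "extreme on another PC" pre-filter).  Results are invariant
    to global sign flips of any component since only magnitudes are used.
    """
    if not 1 <= pc <= emb.Q:
        raise ValueError(f"pc index {pc} outside 1..{emb.Q}")
    scores = np.abs(emb.feature_scores[:, pc - 1])
    keep = np.arange(scores.shape[0])
    if exclude_pc is not None:
        if not 1 <= exclude_pc <= emb.Q:
            raise ValueError(f"exclude_pc index {exclude_pc} outside 1..{emb.Q}")
        other = np.abs(emb.feature_scores[:, exclude_pc - 1])
        keep = keep[other <= np.quantile(other, exclude_quantile)]
    if len(keep) < n_top:
        raise ValueError(
            f"only {len(keep)} features survive the exclusion filter, need {n_top}"
        )
    order = keep[np.argsort(-scores[keep], kind="stable")][:n_top]
    return FEResult(
        order,
        scores,
        "cpcafe",
        {"pc": pc, "n_top": n_top, "exclude_pc": exclude_pc,
         "exclude_quantile": exclude_quantile},
    )
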