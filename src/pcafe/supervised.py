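"""Supervised feature-extraction baselines.

Three label-using methods serve as baselines for the unsupervised PCA-based
extractors:

* one-vs-one t-test FE — a feature is kept only if every pairwise class
  comparison is significant after BH adjustment;
* categorical regression FE — per-feature regression on class-membership
  dummies; the overall model F-test (equivalently a one-way ANOVA across
  classes) ranks features, used either with a BH-adjusted significance
  threshold or as a fixed-size top-``n`` ranking;
* BAHSIC — backward elimination by smallest contribution to the
  Hilbert-Schmidt independence criterion between expression and labels,
  with a linear kernel on the data and a delta kernel on the labels.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .matrix import ExpressionMatrix, labels_to_codes
from .result import FEResult
from .stats import bh_adjust

__all__ = ["ttest_ovo_fe", "categorical_regression_fe", "hsic", "bahsic_select"]


def _require_labels(X: ExpressionMatrix) -> np.ndarray:
    if X.labels is None:
        raise ValueError("this method requires per-sample class labels")
    codes, _ = labels_to_codes(X.labels)
    return codes


def ttest_ovo_fe(
    X: ExpressionMatrix, alpha: float = 0.05, adjust: str = "joint"
) -> FEResult:
    """One-vs-one t-test FE.

    For every feature and every pair of classes a Welch two-sample t-test is
    computed; the ``N * K(K-1)/2`` P-values are BH-adjusted (jointly by
    default, or within each class pair with ``adjust="per-pair"``) and a
    feature is selected iff its adjusted P-value is below ``alpha`` for
    *all* pairs.  Selected features are ordered by their worst adjusted
    pairwise P-value; ``scores`` holds that worst value per feature.
    """
    codes = _require_labels(X)
    K = codes.max() + 1
    for k in range(K):
        if (codes == k).sum() < 2:
            raise ValueError(f"class {k} has fewer than 2 samples")
    if adjust not in ("joint", "per-pair"):
        raise ValueError("adjust must be 'joint' or 'per-pair'")
    pvals = []
    for k in range(K):
        for k2 in range(k + 1, K):
            res = stats.ttest_ind(
                X.values[:, codes == k], X.values[:, codes == k2], axis=1, equal_var=False
            )
            pvals.append(res.pvalue)
    P = np.array(pvals)  # (n_pairs, N)
    if adjust == "joint":
        Padj = bh_adjust(P.ravel()).reshape(P.shape)
    else:
        Padj = np.array([bh_adjust(row) for row in P])
    worst = Padj.max(axis=0)
    selected = np.where((Padj < alpha).all(axis=0))[0]
    selected = selected[np.argsort(worst[selected], kind="stable")]
    return FEResult(selected, worst, "ttest-ovo", {"alpha": alpha, "adjust": adjust})


def _anova_f_p(values: np.ndarray, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised one-way ANOVA F statistic and P-value per feature row.

    Zero-variance features (constant within every class and across classes)
    get ``F = 0`` and ``P = 1`` so they never outrank an informative feature.
    """
    K = codes.max() + 1
    M = values.shape[1]
    grand = values.mean(axis=1)
    ssb = np.zeros(values.shape[0])
    ssw = np.zeros(values.shape[0])
    for k in range(K):
        grp = values[:, codes == k]
        m_k = grp.mean(axis=1)
        ssb += grp.shape[1] * (m_k - grand) ** 2
        ssw += ((grp - m_k[:, None]) ** 2).sum(axis=1)
    df1, df2 = K - 1, M - K
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df1) / (ssw / df2)
    p = stats.f.sf(F, df1, df2)
    dead = (ssw == 0) & (ssb == 0)
    F[dead] = 0.0
    p[dead] = 1.0
    # ssw == 0 with ssb > 0: perfect separation, F -> inf, P -> 0
    p[np.isnan(p)] = 1.0
    return F, p


def categorical_regression_fe(
    X: ExpressionMatrix,
    mode: str = "adjusted",
    alpha: float = 0.05,
    n_top: int = 10,
) -> FEResult:
    """Categorical regression FE (per-feature one-way ANOVA across classes).

    Fitting ``x_ij = C_i0 + sum_k C_ik d_jk`` with class-membership dummies
    and testing overall model significance is the classical one-way ANOVA
    F-test, which is how the P-value is computed here.

    ``mode="adjusted"`` selects features with BH-adjusted P below ``alpha``;
    ``mode="ranked"`` selects the ``n_top`` smallest P-values regardless of
    significance.  Ties in P are broken by larger F, then lower index.
    """
    codes = _require_labels(X)
    if codes.max() + 1 < 2:
        raise ValueError("at least two classes are required")
    F, p = _anova_f_p(X.values, codes)
    order = np.lexsort((np.arange(len(p)), -F, p))
    if mode == "adjusted":
        padj = bh_adjust(p)
        selected = order[padj[order] < alpha]
        params = {"alpha": alpha}
    elif mode == "ranked":
        if n_top > len(p):
            raise ValueError("n_top exceeds the number of features")
        selected = order[:n_top]
        params = {"n_top": n_top}
    else:
        raise ValueError("mode must be 'adjusted' or 'ranked'")
    return FEResult(selected, p, f"catreg-{mode[:4] if mode == 'adjusted' else 'rank'}", params)


def hsic(X_sub: np.ndarray, labels: np.ndarray) -> float:
    """Linear-kernel / delta-kernel HSIC between a feature subset and labels.

    ``K_{jj'} = sum_i x_ij x_ij'`` (linear kernel over the selected
    features) and ``L_{jj'} = 1`` iff samples j and j' share a label.  The
    returned value is the biased three-term estimate

        <K L>_{jj'} + <K><L> - 2 <  <K>_{j''} <L>_{j'''} >_j

    with uniform averages over all index pairs (diagonal included), which
    equals ``tr(K H L H) / M^2`` for the centering matrix
    ``H = I - (1/M) 1 1^T``.  Nonnegative for the delta label kernel, up to
    floating-point tolerance.
    """
    X_sub = np.atleast_2d(np.asarray(X_sub, dtype=float))
    labels = np.asarray(labels)
    M = X_sub.shape[1]
    if labels.shape != (M,):
        raise ValueError("labels length does not match the number of samples")
    if M < 2:
        raise ValueError("at least two samples are required")
    Km = X_sub.T @ X_sub
    L = (labels[:, None] == labels[None, :]).astype(float)
    t1 = (Km * L).mean()
    t2 = Km.mean() * L.mean()
    t3 = (Km.mean(axis=1) * L.mean(axis=1)).mean()
    return float(t1 + t2 - 2.0 * t3)


def _per_feature_hsic(values: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Per-feature HSIC contributions (linear kernel is additive over features)."""
    M = values.shape[1]
    L = (codes[:, None] == codes[None, :]).astype(float)
    H = np.eye(M) - 1.0 / M
    HLH = H @ L @ H
    return np.einsum("ij,jk,ik->i", values, HLH, values) / M**2


def bahsic_select(
    X: ExpressionMatrix, n_target: int, drop_rule: dict | None = None
) -> FEResult:
    """BAHSIC backward elimination.

    At each step the per-feature HSIC contributions of the remaining set
    are recomputed and the batch with the smallest contributions removed
    (``drop_rule={"count": 1}`` removes one feature per step, the default;
    ``{"fraction": 0.10}`` removes 10% of the remaining set).  Elimination
    stops once ``n_target`` features remain, trimming the final batch to
    land exactly on ``n_target``.  Survivors are returned ordered by their
    final HSIC contribution, descending; ``scores`` holds the single-feature
    HSIC of every feature.
    """
    codes = _require_labels(X)
    if n_target <= 0:
        raise ValueError("n_target must be positive")
    if n_target > X.n_features:
        raise ValueError("n_target exceeds the number of features")
    drop_rule = drop_rule or {"count": 1}
    full_scores = _per_feature_hsic(X.values, codes)
    remaining = np.arange(X.n_features)
    while len(remaining) > n_target:
        contrib = _per_feature_hsic(X.values[remaining], codes)
        if "count" in drop_rule:
            batch = int(drop_rule["count"])
        else:
            batch = max(1, int(len(remaining) * drop_rule["fraction"]))
        batch = min(batch, len(remaining) - n_target)
        drop = np.argsort(contrib, kind="stable")[:batch]
        remaining = np.delete(remaining, drop)
    final = _per_feature_hsic(X.values[remaining], codes)
    remaining = remaining[np.argsort(-final, kind="stable")]
    return FEResult(remaining, full_scores, "bahsic", {"n_target": n_target, "drop_rule": drop_rule})
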