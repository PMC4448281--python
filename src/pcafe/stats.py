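"""Small statistical utilities shared across modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "correlation_significance", "correlation_significance_batch"]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("P-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlation_significance(r: float, M: int) -> tuple[float, float]:
    """Two-sided significance of a Pearson correlation over ``M`` samples.

    Uses the exact-null transform ``t = r * sqrt(M - 2) / sqrt(1 - r^2)``,
    which follows a t distribution with ``M - 2`` degrees of freedom when
    the true correlation is zero.  Returns ``(t, p)``.  ``|r| = 1`` is the
    limiting case ``p = 0``.
    """
    if M < 3:
        raise ValueError("at least 3 samples are required")
    if abs(r) > 1:
        raise ValueError("correlation coefficient outside [-1, 1]")
    if abs(r) == 1.0:
        return float(np.sign(r) * np.inf), 0.0
    t = r * np.sqrt(M - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * sps.t.sf(abs(t), df=M - 2)
    return float(t), float(p)


def correlation_significance_batch(rs, M: int, alpha: float = 0.05) -> pd.DataFrame:
    """Batch version: t, raw P, BH-adjusted P and a significance flag per r."""
    rs = np.asarray(rs, dtype=float)
    tp = [correlation_significance(r, M) for r in rs]
    t = np.array([x[0] for x in tp])
    p = np.array([x[1] for x in tp])
    padj = bh_adjust(p)
    return pd.DataFrame(
        {"r": rs, "t": t, "p": p, "p_adj": padj, "significant": padj < alpha}
    )
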