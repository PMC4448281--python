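"""Selection-quality metrics and the ensemble benchmark runner.

A feature-extraction run is scored against the known distinct-feature set
with the Matthews correlation coefficient and the F measure computed from
the standard confusion counts.  ``run_benchmark`` repeats the whole
pipeline — simulate, optionally mislabel, extract, score — over many
independent ensembles and difficulty levels and reports per-method means
with standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cpca import cpcafe_select, pca_embed
from .matrix import ExpressionMatrix
from .simdata import MislabelScheme, SimulationConfig, apply_mislabeling, simulate_dataset
from .supervised import bahsic_select, categorical_regression_fe, ttest_ovo_fe
from .vbpca import vbpca_fit, vbpcafe_select

__all__ = [
    "ConfusionCounts",
    "confusion",
    "mcc",
    "f_measure",
    "BenchmarkSummary",
    "run_benchmark",
    "BENCHMARK_METHODS",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def N(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(selected, truth, N: int) -> ConfusionCounts:
    """Set-overlap confusion counts of a selection against the ground truth.

    ``selected`` and ``truth`` are collections of 0-based feature indices
    within ``range(N)``.
    """
    sel = set(int(i) for i in selected)
    tru = set(int(i) for i in truth)
    for s in (sel, tru):
        if s and (min(s) < 0 or max(s) >= N):
            raise ValueError("feature indices outside 0..N-1")
    TP = len(sel & tru)
    FP = len(sel - tru)
    FN = len(tru - sel)
    return ConfusionCounts(TP, N - TP - FP - FN, FP, FN)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient, in [-1, 1].

    ``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``, defined as 0
    when any factor of the denominator vanishes (empty or exhaustive
    selections).
    """
    den = (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    if den == 0:
        return 0.0
    return (c.TP * c.TN - c.FP * c.FN) / math.sqrt(den)


def f_measure(c: ConfusionCounts) -> float:
    """F measure ``2TP / ((TP+FP) + (TP+FN))`` — the harmonic mean of
    sensitivity and precision; 0 when the selection and truth are both empty."""
    den = (c.TP + c.FP) + (c.TP + c.FN)
    return 0.0 if den == 0 else 2.0 * c.TP / den


# ---------------------------------------------------------------------------
# Benchmark runner
# ---------------------------------------------------------------------------

def _run_ttest(em, n_top):
    return ttest_ovo_fe(em, alpha=0.05)

def _run_catreg_adj(em, n_top):
    return categorical_regression_fe(em, mode="adjusted", alpha=0.05)

def _run_catreg_rank(em, n_top):
    return categorical_regression_fe(em, mode="ranked", n_top=n_top)

def _run_bahsic(em, n_top):
    return bahsic_select(em, n_target=n_top, drop_rule={"count": 1})

def _run_vbpcafe(em, n_top):
    state = vbpca_fit(em, Q=10, max_iter=2000, patience=100, n_top=n_top)
    return vbpcafe_select(state, q=1, n_top=n_top)

def _run_cpcafe(em, n_top):
    emb = pca_embed(em, standardize_features=False, center="none")
    return cpcafe_select(emb, pc=1, n_top=n_top)


#: method name -> (callable, uses_labels)
BENCHMARK_METHODS = {
    "ttest": (_run_ttest, True),
    "catreg-adj": (_run_catreg_adj, True),
    "catreg-rank": (_run_catreg_rank, True),
    "bahsic": (_run_bahsic, True),
    "vbpcafe": (_run_vbpcafe, False),
    "cpcafe": (_run_cpcafe, False),
}


@dataclass
class BenchmarkSummary:
    """Per-ensemble records and per-(method, s) means of MCC and F."""

    records: pd.DataFrame   # method, s, ensemble, mcc, f, n_selected
    summary: pd.DataFrame   # method, s, mean_mcc, se_mcc, mean_f, se_f, n_ensembles


def run_benchmark(
    methods: list[str],
    config: SimulationConfig,
    s_values: list[float],
    mislabel: MislabelScheme | None = None,
    seed: int | None = None,
    n_top: int = 10,
) -> BenchmarkSummary:
    """Score each method over ``config.n_ensembles`` simulated ensembles.

    For every difficulty ``s`` and ensemble index ``e`` one data set is
    drawn with the deterministic per-ensemble seed ``seed + e``, so any
    single ensemble can be reproduced in isolation.  When ``mislabel`` is
    given, the corrupted labels are handed to the label-using methods only;
    the unsupervised methods never see labels, which is the mechanism behind
    their mislabeling robustness.
    """
    unknown = [m for m in methods if m not in BENCHMARK_METHODS]
    if unknown:
        raise ValueError(f"unknown methods: {unknown}")
    root = config.seed if seed is None else seed
    rows = []
    for s in s_values:
        cfg = SimulationConfig(
            N=config.N, N_prime=config.N_prime, K=config.K, M=config.M,
            s=s, sigma=config.sigma, seed=root, n_ensembles=config.n_ensembles,
            epsilon_mode=config.epsilon_mode,
        )
        for e in range(cfg.n_ensembles):
            em, truth = simulate_dataset(cfg, seed=root + e)
            if mislabel is not None:
                bad_labels, _ = apply_mislabeling(em.labels, mislabel, seed=root + e)
                em_bad = ExpressionMatrix(
                    em.values, em.feature_ids, em.sample_ids, bad_labels
                )
            else:
                em_bad = em
            for m in methods:
                fn, uses_labels = BENCHMARK_METHODS[m]
                try:
                    res = fn(em_bad if uses_labels else em, n_top)
                except Exception as err:  # attach context, then re-raise
                    raise RuntimeError(
                        f"method {m!r} failed on ensemble {e} (s={s})"
                    ) from err
                c = confusion(res.selected, truth, cfg.N)
                rows.append(
                    {"method": m, "s": s, "ensemble": e,
                     "mcc": mcc(c), "f": f_measure(c), "n_selected": len(res.selected)}
                )
    records = pd.DataFrame(rows)
    grouped = records.groupby(["method", "s"], sort=False)
    summary = grouped.agg(
        mean_mcc=("mcc", "mean"),
        se_mcc=("mcc", lambda v: v.std(ddof=1) / math.sqrt(len(v)) if len(v) > 1 else 0.0),
        mean_f=("f", "mean"),
        se_f=("f", lambda v: v.std(ddof=1) / math.sqrt(len(v)) if len(v) > 1 else 0.0),
        n_ensembles=("mcc", "size"),
    ).reset_index()
    return BenchmarkSummary(records, summary)
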