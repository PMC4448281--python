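"""Downstream integration of selected miRNAs and mRNAs.

After unsupervised extraction on real (or fixture) expression data, this
module provides the cross-omics follow-up: treatment-vs-control group
tests on per-feature P-values and log expression ratios, correlation of
sample loadings between two PCA embeddings, miRNA-mRNA pair correlation
with t-transform significance and BH adjustment, 7mer-m8 seed-site
scanning, and a replicate-resampling stability count for any extraction
method.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cpca import PCAEmbedding
from .matrix import ExpressionMatrix
from .stats import bh_adjust, correlation_significance, correlation_significance_batch

__all__ = [
    "ConditionDesign",
    "SeedMatch",
    "per_feature_group_pvalues",
    "selected_vs_others_test",
    "log_ratio_group_test",
    "loading_correlation",
    "seed_match_7mer_m8",
    "cv_stability",
    "mirna_mrna_pairs",
]

DESIGN_COLUMNS = ["sample_id", "condition", "role", "pair_id", "replicate"]


@dataclass
class ConditionDesign:
    """Validated sample sheet: condition, role and treatment/control pairing.

    ``table`` must carry the columns sample_id, condition, role
    (treatment|control), pair_id (empty string for unpaired conditions) and
    replicate.  Treatment conditions with no matching control are allowed
    but flagged in ``unpaired``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table lacks columns: {missing}")
        bad = set(self.table["role"]) - {"treatment", "control"}
        if bad:
            raise ValueError(f"unknown roles: {bad}")
        self.table = self.table.copy()
        self.table["pair_id"] = self.table["pair_id"].fillna("").astype(str)
        for pid, grp in self.table[self.table["pair_id"] != ""].groupby("pair_id"):
            roles = set(grp["role"])
            if roles != {"treatment", "control"}:
                raise ValueError(f"pair {pid!r} lacks a {'control' if roles == {'treatment'} else 'treatment'} arm")

    @property
    def unpaired(self) -> list[str]:
        t = self.table
        return sorted(t.loc[(t["role"] == "treatment") & (t["pair_id"] == ""), "condition"].unique())

    @property
    def pair_ids(self) -> list[str]:
        return sorted(p for p in self.table["pair_id"].unique() if p)

    def samples_of(self, condition: str) -> list[str]:
        return self.table.loc[self.table["condition"] == condition, "sample_id"].tolist()

    def pair_conditions(self, pair_id: str) -> tuple[str, str]:
        grp = self.table[self.table["pair_id"] == pair_id]
        if grp.empty:
            raise ValueError(f"unknown pair id {pair_id!r}")
        treat = grp.loc[grp["role"] == "treatment", "condition"].iloc[0]
        ctrl = grp.loc[grp["role"] == "control", "condition"].iloc[0]
        return treat, ctrl


def _columns_for(X: ExpressionMatrix, sample_ids: list[str]) -> np.ndarray:
    pos = {s: j for j, s in enumerate(X.sample_ids)}
    missing = [s for s in sample_ids if s not in pos]
    if missing:
        raise ValueError(f"samples not in matrix: {missing[:5]}")
    return X.values[:, [pos[s] for s in sample_ids]]


def per_feature_group_pvalues(
    X: ExpressionMatrix,
    design: ConditionDesign,
    condition_pair: str | tuple[str, str],
    alternative: str = "greater",
) -> np.ndarray:
    """Per-feature treatment-vs-control t-test P-values for one condition pair.

    ``condition_pair`` is a pair id from the design (or an explicit
    ``(treatment_condition, control_condition)`` tuple).  With
    ``alternative="greater"`` the test is oriented so that P < 0.5 indicates
    upregulation under treatment; ``P_greater + P_less = 1`` per feature.
    """
    if isinstance(condition_pair, str):
        treat_c, ctrl_c = design.pair_conditions(condition_pair)
    else:
        treat_c, ctrl_c = condition_pair
    treat = _columns_for(X, design.samples_of(treat_c))
    ctrl = _columns_for(X, design.samples_of(ctrl_c))
    if treat.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("both conditions need at least 2 replicates")
    res = sps.ttest_ind(treat, ctrl, axis=1, equal_var=False, alternative=alternative)
    return np.asarray(res.pvalue)


GroupTestResult = namedtuple("GroupTestResult", ["p_greater", "p_less"])


def selected_vs_others_test(log_p: np.ndarray, selected) -> GroupTestResult:
    """Do the selected features' log P-values differ from the others'?

    Two one-sided Welch t-tests of the selected group against all remaining
    features; returns ``(p_greater, p_less)`` for the alternatives
    "selected mean is greater" and "selected mean is less".  The two
    one-sided P-values sum to 1.
    """
    log_p = np.asarray(log_p, dtype=float)
    sel = np.zeros(log_p.shape[0], dtype=bool)
    sel[np.asarray(list(selected), dtype=int)] = True
    if not sel.any() or sel.all():
        raise ValueError("both groups must be nonempty")
    a, b = log_p[sel], log_p[~sel]
    if a.std() == 0 and b.std() == 0:
        # degenerate but well-defined limits: equal constants are maximally
        # uninformative (t = 0), unequal ones maximally one-sided
        if a.mean() == b.mean():
            return GroupTestResult(0.5, 0.5)
        return GroupTestResult(0.0, 1.0) if a.mean() > b.mean() else GroupTestResult(1.0, 0.0)
    p_gt = sps.ttest_ind(a, b, equal_var=False, alternative="greater").pvalue
    p_lt = sps.ttest_ind(a, b, equal_var=False, alternative="less").pvalue
    return GroupTestResult(float(p_gt), float(p_lt))


def log_ratio_group_test(
    X: ExpressionMatrix,
    design: ConditionDesign,
    condition_pair: str | tuple[str, str],
    selected,
) -> GroupTestResult:
    """Group test on per-feature log(treated/control) expression ratios.

    Expression is replicate-averaged per condition first (one ratio per
    feature per condition pair), then the selected features' mean log-ratio
    is compared against the remaining features' with one-sided Welch
    t-tests in both directions: ``p_greater`` small means the selected set
    is shifted *up* under treatment relative to the background.  Natural
    logarithms; nonpositive averaged expression is an error (offset the
    data first if it contains zeros).
    """
    if isinstance(condition_pair, str):
        treat_c, ctrl_c = design.pair_conditions(condition_pair)
    else:
        treat_c, ctrl_c = condition_pair
    treat = _columns_for(X, design.samples_of(treat_c)).mean(axis=1)
    ctrl = _columns_for(X, design.samples_of(ctrl_c)).mean(axis=1)
    if (treat <= 0).any() or (ctrl <= 0).any():
        raise ValueError(
            "log-ratios require positive replicate-averaged expression; "
            "offset the matrix before calling"
        )
    ratios = np.log(treat) - np.log(ctrl)
    return selected_vs_others_test(ratios, selected)


def loading_correlation(
    emb_a: PCAEmbedding,
    emb_b: PCAEmbedding,
    by_condition: bool = False,
    design: ConditionDesign | None = None,
    pc: int = 1,
) -> tuple[float, float]:
    """Pearson correlation of two embeddings' sample loadings on one PC.

    Correlates ``A_.pc`` of the two embeddings over samples (matched by
    sample id when available), or over condition-averaged loadings when
    ``by_condition``; the P-value comes from the t-transform with the
    number of correlated points as ``M``.
    """
    a = emb_a.sample_loadings[:, pc - 1]
    b = emb_b.sample_loadings[:, pc - 1]
    if emb_a.sample_ids is not None and emb_b.sample_ids is not None:
        if set(emb_a.sample_ids) != set(emb_b.sample_ids):
            raise ValueError("embeddings cover different sample sets")
        pos = {s: j for j, s in enumerate(emb_b.sample_ids)}
        b = b[[pos[s] for s in emb_a.sample_ids]]
    elif a.shape != b.shape:
        raise ValueError("embeddings cover different numbers of samples")
    if by_condition:
        if design is None or emb_a.sample_ids is None:
            raise ValueError("by_condition requires a design and sample ids")
        cond = design.table.set_index("sample_id")["condition"]
        groups = pd.Series(emb_a.sample_ids).map(cond)
        a = pd.Series(a).groupby(groups.values).mean().to_numpy()
        b = pd.Series(b).groupby(groups.values).mean().to_numpy()
    r = float(np.corrcoef(a, b)[0, 1])
    _, p = correlation_significance(r, len(a))
    return r, p


# ---------------------------------------------------------------------------
# Seed matching
# ---------------------------------------------------------------------------

SeedMatch = namedtuple("SeedMatch", ["mirna_id", "mrna_id", "utr_offset", "matched_site"])

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A"}


def seed_match_7mer_m8(
    mirna_seq: str,
    utr_seq: str,
    mirna_id: str = "",
    mrna_id: str = "",
) -> list[SeedMatch]:
    """Scan a UTR for 7mer-m8 sites of a mature miRNA.

    The site is the reverse complement (DNA alphabet) of miRNA positions
    2-8 (1-based, 5'->3': the 6-nt seed plus position 8); every UTR offset
    (0-based) whose 7-mer window equals it exactly is reported.  Both
    sequences may use U or T; ambiguous bases (N) never match.
    """
    mirna = mirna_seq.upper().replace("U", "T")
    utr = utr_seq.upper().replace("U", "T")
    if len(mirna) < 8:
        raise ValueError("mature miRNA must be at least 8 nt")
    if set(mirna) - set("ACGTN") or set(utr) - set("ACGTN"):
        raise ValueError("sequences must be over {A, C, G, T/U, N}")
    site = "".join(_COMPLEMENT[b] if b in _COMPLEMENT else "N" for b in reversed(mirna[1:8]))
    if "N" in site:
        return []
    out = []
    start = utr.find(site)
    while start != -1:
        out.append(SeedMatch(mirna_id, mrna_id, start, site))
        start = utr.find(site, start + 1)
    return out


# ---------------------------------------------------------------------------
# Pair correlations and stability
# ---------------------------------------------------------------------------

def mirna_mrna_pairs(
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    selected_mirna: list[str],
    selected_mrna: list[str],
    probe_map: pd.DataFrame | None = None,
    mirna_seqs: dict[str, str] | None = None,
    utr_seqs: dict[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate selected miRNAs against selected mRNAs across samples.

    Pearson correlations are computed per probe and, when ``probe_map``
    (columns probe_id, mirna_id) maps several probes to one miRNA,
    summarised per miRNA by the median r.  Significance uses the
    t-transform with M = number of samples and BH adjustment over the whole
    pair batch.  When sequences are supplied, each pair also gets a
    ``seed_match`` flag (any 7mer-m8 site of the miRNA in the mRNA UTR).
    """
    if mirna.sample_ids != mrna.sample_ids:
        raise ValueError("miRNA and mRNA matrices must share the sample set")
    M = mirna.n_samples
    if probe_map is not None:
        probe_of = probe_map.set_index("probe_id")["mirna_id"]
    rows = []
    mrna_pos = {f: i for i, f in enumerate(mrna.feature_ids)}
    mirna_rows: dict[str, list[int]] = {}
    for i, fid in enumerate(mirna.feature_ids):
        mid = str(probe_of[fid]) if probe_map is not None and fid in probe_of.index else fid
        mirna_rows.setdefault(mid, []).append(i)
    for mid in selected_mirna:
        if mid not in mirna_rows:
            raise ValueError(f"unknown miRNA id {mid!r}")
        for gid in selected_mrna:
            if gid not in mrna_pos:
                raise ValueError(f"unknown mRNA id {gid!r}")
            y = mrna.values[mrna_pos[gid]]
            rs = [
                float(np.corrcoef(mirna.values[i], y)[0, 1]) for i in mirna_rows[mid]
            ]
            r = float(np.median(rs))
            match = None
            if mirna_seqs is not None and utr_seqs is not None:
                match = bool(seed_match_7mer_m8(mirna_seqs[mid], utr_seqs[gid], mid, gid))
            rows.append({"mirna_id": mid, "mrna_id": gid, "r": r, "seed_match": match})
    out = pd.DataFrame(rows)
    sig = correlation_significance_batch(out["r"].to_numpy(), M, alpha=alpha)
    out[["t_stat", "p_value", "adjusted_p", "significant"]] = sig[
        ["t", "p", "p_adj", "significant"]
    ].to_numpy()
    if mirna_seqs is None or utr_seqs is None:
        out = out.drop(columns=["seed_match"])
    return out


def cv_stability(
    X: ExpressionMatrix,
    design: ConditionDesign,
    fe_method,
    n_samplings: int = 100,
    seed: int | None = None,
) -> tuple[np.ndarray, int, int]:
    """Selection frequency under replicate-dropping cross-validation.

    For each of ``n_samplings`` draws, one replicate per condition is
    dropped uniformly at random (conditions with a replicate count other
    than 4 keep ~3/4 of their replicates, at least one) and ``fe_method``
    — a callable mapping an ``ExpressionMatrix`` to an iterable of selected
    0-based feature indices — is rerun on the reduced matrix.  Returns
    ``(frequencies, n_effective, n_failures)`` where ``frequencies[i]`` is
    the number of samplings in which feature ``i`` was selected; samplings
    where the method raised are skipped and counted in ``n_failures``.
    """
    rng = np.random.default_rng(seed)
    tab = design.table.set_index("sample_id").loc[X.sample_ids].reset_index()
    freq = np.zeros(X.n_features, dtype=int)
    failures = 0
    for _ in range(n_samplings):
        keep_idx = []
        for _, grp in tab.groupby("condition", sort=False):
            idx = grp.index.to_numpy()
            n = len(idx)
            n_keep = n - 1 if n == 4 else max(1, round(0.75 * n))
            keep_idx.extend(rng.choice(idx, size=n_keep, replace=False))
        sub = X.subset_samples(np.sort(np.asarray(keep_idx)))
        try:
            sel = np.asarray(list(fe_method(sub)), dtype=int)
        except Exception:
            failures += 1
            continue
        freq[sel] += 1
    return freq, n_samplings - failures, failures
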