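"""Synthetic data generators.

Two kinds of synthetic data are produced here.

1. The categorical multiclass benchmark: ``N`` Gaussian features over ``M``
   samples split into ``K`` unordered classes.  The first ``N'`` features
   carry a class-dependent mean ``mu_k = ((k-1)/(K-1) - 1/2) * s`` (half of
   them with sign flipped, emulating co-existing up- and down-regulated
   genes); the remaining ``N - N'`` features are pure noise whose mean is
   resampled uniformly from ``{mu_1, ..., mu_K}`` so that signal and noise
   features share an identical marginal mixture distribution.  ``s`` tunes
   class separability (the only difficulty knob); the Gaussian standard
   deviation is fixed at 0.5.

2. A miRNA/mRNA expression fixture laid out like a stress-exposure
   microarray study: 12 conditions (7 treatment, 5 control) x 4 replicates
   = 48 samples, miRNAs measured by several probes each, and a configurable
   number of planted miRNA-mRNA pairs that are negatively correlated across
   samples and whose mRNA 3'UTR contains the 7mer-m8 complement of the
   paired miRNA seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "MislabelScheme",
    "FixtureSpec",
    "class_mean",
    "simulate_dataset",
    "apply_mislabeling",
    "generate_fixture",
    "default_design",
]


@dataclass
class SimulationConfig:
    """Parameters of the categorical multiclass benchmark generator.

    ``epsilon_mode`` controls how the noise-feature mean ``eps`` is drawn:
    ``"cell"`` (default) resamples it independently for every matrix entry,
    ``"feature"`` draws one value per noise feature that is shared by all of
    its samples.
    """

    N: int = 100
    N_prime: int = 10
    K: int = 4
    M: int = 20
    s: float = 2.0
    sigma: float = 0.5
    seed: int = 0
    n_ensembles: int = 100
    epsilon_mode: str = "cell"

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("at least two classes are required")
        if self.N_prime > self.N:
            raise ValueError("N_prime must not exceed N")
        if self.N_prime % 2:
            raise ValueError("N_prime must be even (half up-, half down-regulated)")
        if self.M % self.K:
            raise ValueError("M must be divisible by K (equal class sizes)")
        if self.s < 0:
            raise ValueError("class-separation scale s must be nonnegative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.epsilon_mode not in ("cell", "feature"):
            raise ValueError("epsilon_mode must be 'cell' or 'feature'")


def class_mean(k: int, K: int, s: float) -> float:
    """Mean of class ``k`` (1-based), ``mu_k = ((k-1)/(K-1) - 1/2) * s``.

    The means are equally spaced and symmetric about zero, spanning
    ``[-s/2, s/2]``.
    """
    if K < 2:
        raise ValueError("at least two classes are required")
    if not 1 <= k <= K:
        raise ValueError(f"class index {k} outside 1..{K}")
    return ((k - 1) / (K - 1) - 0.5) * s


def simulate_dataset(
    config: SimulationConfig, seed: int | None = None
) -> tuple[ExpressionMatrix, frozenset[int]]:
    """Draw one benchmark ensemble.

    Returns the expression matrix (with 0-based class codes as labels) and
    the ground-truth set of class-distinct feature indices (0-based, the
    first ``N'`` rows).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    mu = np.array([class_mean(k, cfg.K, cfg.s) for k in range(1, cfg.K + 1)])
    labels = np.repeat(np.arange(cfg.K), cfg.M // cfg.K)
    X = rng.normal(0.0, cfg.sigma, size=(cfg.N, cfg.M))
    half = cfg.N_prime // 2
    for k in range(cfg.K):
        cols = labels == k
        X[:half, cols] += mu[k]
        X[half : cfg.N_prime, cols] -= mu[k]
    n_noise = cfg.N - cfg.N_prime
    if n_noise:
        if cfg.epsilon_mode == "cell":
            eps = mu[rng.integers(0, cfg.K, size=(n_noise, cfg.M))]
        else:
            eps = mu[rng.integers(0, cfg.K, size=n_noise)][:, None]
        X[cfg.N_prime :] += eps
    em = ExpressionMatrix(
        X,
        [f"feature_{i + 1}" for i in range(cfg.N)],
        [f"sample_{j + 1}" for j in range(cfg.M)],
        labels,
    )
    return em, frozenset(range(cfg.N_prime))


@dataclass
class MislabelScheme:
    """A K x K table of (true class -> assigned class) sample counts."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        K = self.counts.shape[0]
        if self.counts.shape != (K, K):
            raise ValueError("counts must be a square K x K table")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n_mislabeled(self) -> int:
        return int(self.counts.sum() - np.trace(self.counts))

    @classmethod
    def identity(cls, class_sizes: list[int]) -> "MislabelScheme":
        return cls(np.diag(class_sizes))

    @classmethod
    def from_moves(cls, class_sizes: list[int], moves: list[tuple[int, int, int]]) -> "MislabelScheme":
        """Build a scheme from ``(true_class, assigned_class, count)`` moves (0-based)."""
        counts = np.diag(np.asarray(class_sizes, dtype=int)).copy()
        for k, k2, n in moves:
            counts[k, k] -= n
            counts[k, k2] += n
        if (counts < 0).any():
            raise ValueError("moves exceed class sizes")
        return cls(counts)


def apply_mislabeling(
    labels: np.ndarray, scheme: MislabelScheme, seed: int | None = None
) -> tuple[np.ndarray, float]:
    """Reassign labels according to ``scheme`` and report the label correlation.

    Exactly ``scheme.counts[k, k']`` samples of true class ``k`` receive
    label ``k'`` (which samples is decided uniformly at random).  The
    returned ``r`` is the Pearson correlation between the true and the
    modified labels encoded as integers — the summary the mislabeling
    robustness analysis is indexed by.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    K = len(classes)
    if scheme.counts.shape[0] != K:
        raise ValueError("scheme size does not match number of classes")
    new = labels.copy()
    for ki, k in enumerate(classes):
        idx = np.where(labels == k)[0]
        if scheme.counts[ki].sum() != len(idx):
            raise ValueError(
                f"row {ki} of the scheme sums to {scheme.counts[ki].sum()} "
                f"but class {k!r} has {len(idx)} samples"
            )
        perm = rng.permutation(idx)
        pos = 0
        for kj, k2 in enumerate(classes):
            n = scheme.counts[ki, kj]
            new[perm[pos : pos + n]] = k2
            pos += n
    code = {c: i for i, c in enumerate(classes)}
    a = np.array([code[v] for v in labels], dtype=float)
    b = np.array([code[v] for v in new], dtype=float)
    if a.std() == 0 or b.std() == 0:
        r = 1.0 if np.array_equal(a, b) else 0.0
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    return new, r


# ---------------------------------------------------------------------------
# Expression fixture with planted miRNA-mRNA biology
# ---------------------------------------------------------------------------

#: Condition layout of the emulated stress study: "T<stress>-<rest>d" are
#: treatment conditions (days of stress exposure / days of rest), "C..."
#: their separately housed controls.  Two treatment conditions lack a
#: matching control and are therefore unpaired.
TREATMENT_CONDITIONS = ["T1-1d", "T2-1d", "T3-1d", "T5-1d", "T10-1d", "T5-10d", "T10-42d"]
CONTROL_CONDITIONS = ["C2-1d", "C5-1d", "C10-1d", "C5-10d", "C10-42d"]
UNPAIRED_TREATMENTS = ["T1-1d", "T3-1d"]


def default_design(n_replicates: int = 4) -> pd.DataFrame:
    """The 12-condition x n-replicate sample sheet of the emulated study.

    Columns: sample_id, condition, role, pair_id (shared by a
    treatment/control pair, empty for unpaired conditions), replicate.
    """
    rows = []
    for cond in TREATMENT_CONDITIONS + CONTROL_CONDITIONS:
        role = "treatment" if cond.startswith("T") else "control"
        pair = "" if cond in UNPAIRED_TREATMENTS else cond[1:]
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample_id": f"{cond}_r{rep}",
                    "condition": cond,
                    "role": role,
                    "pair_id": pair,
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class FixtureSpec:
    """Layout and effect sizes of the planted-biology expression fixture."""

    n_conditions_treatment: int = 7
    n_conditions_control: int = 5
    n_replicates: int = 4
    n_mirna: int = 20
    n_probes_per_mirna: int = 2
    n_mrna: int = 60
    n_planted_pairs: int = 8
    effect_size: float = 0.8
    noise_sd: float = 0.25
    shared_signal: float = 0.8
    baseline: float = 8.0
    mirna_length: int = 22
    utr_length: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("at least two replicates per condition are required")
        if self.n_planted_pairs > min(self.n_mirna, self.n_mrna):
            raise ValueError("planted pairs must reference existing miRNA and mRNA ids")
        if self.n_conditions_treatment != 7 or self.n_conditions_control != 5:
            raise ValueError("the fixture emulates the fixed 7+5 condition layout")
        if not 0.0 <= self.shared_signal <= 1.0:
            raise ValueError("shared_signal must be in [0, 1]")


_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A"}


def _revcomp_dna(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq.upper()))


def generate_fixture(
    spec: FixtureSpec,
) -> tuple[ExpressionMatrix, ExpressionMatrix, dict[str, str], dict[str, str], dict[str, pd.DataFrame]]:
    """Generate the miRNA/mRNA fixture with planted negative correlations.

    Returns ``(mirna, mrna, mirna_seqs, utr_seqs, truth)`` where the
    expression matrices carry condition labels, the sequence dicts map ids to
    5'->3' strings (miRNAs in RNA alphabet, UTRs in DNA), and ``truth``
    holds the planted-pair table and the probe->miRNA map.

    Construction: each miRNA ``p`` carries a per-sample latent signal
    ``z_p = shift + sqrt(shared_signal) * g + sqrt(1 - shared_signal) * own_p``
    where ``shift`` is +1 under treatment, ``g`` is a condition-level
    stress-response program common to all miRNAs and ``own_p`` a
    condition-level private component; a planted pair's miRNA follows
    ``baseline + effect_size * z_p`` and its target mRNA
    ``baseline - effect_size * z_p``, giving a strongly negative Pearson
    correlation whenever ``noise_sd`` is small against ``effect_size``
    (expected magnitude ``effect_size^2 var(z) / (effect_size^2 var(z) +
    noise_sd^2)``).  The shared program makes the planted features load a
    common dominant axis, as co-regulated stress-response modules do in
    real arrays.  Probes of the same miRNA share its full signal and differ
    by independent noise.
    """
    rng = np.random.default_rng(spec.seed)
    design = default_design(spec.n_replicates)
    sample_ids = design["sample_id"].tolist()
    conditions = design["condition"].to_numpy()
    n_samples = len(sample_ids)
    is_treat = (design["role"] == "treatment").to_numpy().astype(float)

    mirna_ids = [f"mir-{i + 1}" for i in range(spec.n_mirna)]
    mrna_ids = [f"gene_{i + 1}" for i in range(spec.n_mrna)]

    # condition-level latents: one shared program + one private per miRNA
    uniq_cond = design["condition"].unique()
    cond_idx = {c: i for i, c in enumerate(uniq_cond)}
    cond_of_sample = np.array([cond_idx[c] for c in conditions])
    shared = rng.normal(0.0, 1.0, size=len(uniq_cond))[cond_of_sample]
    own = rng.normal(0.0, 1.0, size=(spec.n_mirna, len(uniq_cond)))[:, cond_of_sample]
    z = (
        is_treat[None, :]
        + np.sqrt(spec.shared_signal) * shared[None, :]
        + np.sqrt(1.0 - spec.shared_signal) * own
    )

    probe_rows, probe_ids, probe_map = [], [], []
    for mi, mid in enumerate(mirna_ids):
        for p in range(spec.n_probes_per_mirna):
            probe_ids.append(f"{mid}_probe{p + 1}")
            probe_map.append({"probe_id": probe_ids[-1], "mirna_id": mid})
            probe_rows.append(
                spec.baseline
                + spec.effect_size * z[mi]
                + rng.normal(0.0, spec.noise_sd, n_samples)
            )
    mirna = ExpressionMatrix(np.array(probe_rows), probe_ids, sample_ids, conditions)

    mrna_vals = spec.baseline + rng.normal(0.0, spec.noise_sd, size=(spec.n_mrna, n_samples))
    for p in range(spec.n_planted_pairs):
        mrna_vals[p] -= spec.effect_size * z[p]
    mrna = ExpressionMatrix(mrna_vals, mrna_ids, sample_ids, conditions)

    bases_rna = np.array(list("ACGU"))
    bases_dna = np.array(list("ACGT"))
    mirna_seqs = {
        mid: "".join(rng.choice(bases_rna, spec.mirna_length)) for mid in mirna_ids
    }
    utr_seqs = {}
    planted_offsets = {}
    for gi, gid in enumerate(mrna_ids):
        seq = list("".join(rng.choice(bases_dna, spec.utr_length)))
        if gi < spec.n_planted_pairs:
            site = _revcomp_dna(mirna_seqs[mirna_ids[gi]][1:8])
            off = int(rng.integers(0, spec.utr_length - 7))
            seq[off : off + 7] = site
            planted_offsets[gid] = off
        utr_seqs[gid] = "".join(seq)

    pairs = pd.DataFrame(
        {
            "mirna_id": mirna_ids[: spec.n_planted_pairs],
            "mrna_id": mrna_ids[: spec.n_planted_pairs],
            "utr_offset": [planted_offsets[g] for g in mrna_ids[: spec.n_planted_pairs]],
        }
    )
    truth = {"pairs": pairs, "probe_map": pd.DataFrame(probe_map), "design": design}
    return mirna, mrna, mirna_seqs, utr_seqs, truth
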