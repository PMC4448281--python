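# Methods

## The model behind VBPCAFE

The data matrix `V` (N features × M samples) is modelled as a low-rank
factorisation plus Gaussian noise,

    V = B Aᵀ + E,      E_ij ~ N(0, σ_E²),

with `B` (N×Q) the feature scores and `A` (M×Q) the sample loadings,
Q ≪ N, M.  Both factors carry Gaussian priors.  The prior on `A` is
shared across samples with per-component variances `C_A^q`; the prior on
`B` is *feature-dependent*,

    P(B_iq) ∝ exp(−B_iq²/2C_B^{iq}),

which is the whole point of the extension: in plain variational Bayes
PCA the `C_B` hyperparameters have only a component index and perform
automatic relevance determination over *components*; giving them a
feature index makes the same mechanism prune *features*.  After the
variational optimisation, `C_B^{i1}` is an unsupervised per-feature
relevance weight for the leading expression pattern, and feature
extraction reads off its largest values.

The variational posterior is Gaussian: mean `Â` with a shared covariance
`Σ_A`, and mean `B̂` with one covariance `Σ_B^i` per feature.  One update
cycle (applied in this fixed order; the coordinate updates are mutually
independent so the order affects only the trajectory, not the fixed
points) is:

    Σ_A   ← σ_E² (B̂ᵀB̂ + Σ_i Σ_B^i + σ_E² C_A⁻¹)⁻¹
    Â     ← Vᵀ B̂ Σ_A / σ_E²
    Σ_B^i ← σ_E² (ÂᵀÂ + M Σ_A + σ_E² (C_B^i)⁻¹)⁻¹
    B̂_i   ← V_i Â Σ_B^i / σ_E²
    C_A^q ← normalise(‖Â_q‖²/M + (Σ_A)_qq)
    C_B^{iq} ← B̂_iq² + (Σ_B^i)_qq
    σ_E²  ← (1/NM){‖V‖² − 2 tr(VᵀB̂Âᵀ) + tr((ÂᵀÂ + MΣ_A)(B̂ᵀB̂ + Σ_iΣ_B^i))}

The `C_A` normalisation (summing to 1) pins the global scale that the
feature-dependent extension would otherwise leave free; `C_A` then acts
as a relative component-relevance spectrum.  The iteration tracks the
variational free energy

    F = ‖V‖²/(2σ_E²) + (NM/2)log σ_E² + (M/2)log(|C_A|/|Σ_A|)
        + ½ Σ_i log(|C_B^i|/|Σ_B^i|) + ½ Σ_i B̂_iᵀ(C_B^i)⁻¹B̂_i
        + ½ tr{C_A⁻¹(ÂᵀÂ + MΣ_A) + Σ_i (C_B^i)⁻¹Σ_B^i
               + σ_E⁻²(−2ÂᵀVᵀB̂ + (ÂᵀÂ + MΣ_A)(B̂ᵀB̂ + Σ_iΣ_B^i))}

up to an additive constant, and the minimum-`F` visited state is the one
reported.

The key structural fact is the `C_B` update itself: at convergence
`C_B^{i1} = B̂_i1² + (Σ_B^i)_11`, i.e. the relevance weight is the
squared feature score plus a small posterior-variance term.  Ranking by
`C_B^{i1}` therefore nearly coincides with ranking by the squared
conventional PC1 score — which is CPCAFE, at a tiny fraction of the
cost.  The package treats this equivalence as a testable claim (quadratic
fit of `C_B^{i1}` on the PC1 score attains R² > 0.9 on the 200-feature
test construction; top-set overlap ≥ 80%).

### Numerical choices

* `Q = 10` by default for the 100×20 benchmark (exposed); `Q` must not
  exceed min(N, M).
* `C_B^{iq}`, `C_A^q` and `σ_E²` are floored at 1e-12 before inversion.
  The floor is load-bearing: ARD drives pruned features' `C_B` toward
  zero, which is exactly the regime in which `(C_B^i)⁻¹` would blow up.
* Singular matrices in an inversion get one retry with a 1e-10 ridge.
* Initialisation: `B̂, Â` from the SVD of the input (so component 1 *is*
  conventional PC1 at the start), covariances at 1e-6·I, `C_A` uniform,
  `C_B` from its own update rule, `σ_E²` from the rank-Q residual.
  Identity-scaled covariance initialisation was chosen over sampling
  from the prior; with PCA-based factor initialisation the first update
  cycle overwrites the covariances anyway.
* Convergence: the top-`n_top` set by `C_B^{i,pc}` must be unchanged for
  `patience` (default 100) consecutive iterations, capped at `max_iter`
  (default 2000).  Free-energy divergence (NaN/Inf) raises with the
  iteration index.
* Pruned features approach `C_B → 0` along a power-law trajectory, so
  "parameter convergence" is only ever reached by the live entries; the
  extracted-set criterion sidesteps this.

## CPCAFE

`pca_embed` computes the SVD of the processed matrix; `feature_scores`
`B = U·S` are the embedded feature points and `sample_loadings A = V`
are orthonormal.  Preprocessing is explicit and recorded in the
embedding (`standardize_features` for per-feature mean-0/sd-1, then
`center` ∈ {none, feature, sample}): the benchmark uses raw matrices
(`center="none"`, the simulation already centres the signal), real-data
style runs standardize mRNA and leave miRNA raw.  Each component's sign
is fixed so the largest-magnitude sample loading is positive — selection
uses `|B|` so this affects nothing downstream, but it makes outputs
deterministic across linear-algebra backends.  Note the convention makes
the *sign* of a cross-omics loading correlation arbitrary; orient by the
selected features' scores when the direction matters.

`cpcafe_select` takes the `n_top` largest `|B_{i,pc}|`, optionally first
removing features above a quantile (default 0.99, exposed, not a
published value) of `|score|` on another component — the "extreme on
PC2" pre-filter used on real arrays.  Erroneous-probe removal is a
manual exclusion list, not an automatic rule.

## Supervised baselines

* **One-vs-one t-test FE**: Welch tests for every feature × class pair;
  BH adjustment is joint over all N·K(K−1)/2 P-values by default
  (exposed switch for per-pair adjustment); a feature needs *all* pairs
  significant.  Welch rather than pooled variance, matching the default
  two-sample test of the usual statistical environments.
* **Categorical regression FE**: regressing on class dummies and testing
  overall model significance is exactly the one-way ANOVA F-test, which
  is what is computed (vectorised); the dummy encoding's redundant level
  is irrelevant to the overall F.  Zero-variance features get P = 1 (and
  F = 0) so the ranking stays total and conservative.  Ties break by
  larger F, then lower index.
* **BAHSIC**: biased HSIC estimate `tr(K H L H)/M²` with the linear data
  kernel and delta label kernel, uniform averages including diagonal
  pairs.  The linear kernel makes HSIC additive over features, so
  per-feature contributions are static across elimination steps and
  drop-1 elimination equals a single sort; the step loop is retained for
  fidelity to the batched schedule (drop 10% per step for large data).

## The simulators

**Categorical multiclass benchmark** (the study conditions): N=100
features, M=20 samples, K=4 equal contiguous classes, sd fixed at 0.5,
`μ_k = ((k−1)/(K−1) − ½)s` with s ∈ {2, 1, 0.5} as easy/medium/hard.
Features 1–5 carry `+μ_k`, 6–10 `−μ_k` (coexisting up/down regulation),
and the 90 noise features draw their mean ε uniformly from `{μ_k}` —
independently for every matrix entry by default (`epsilon_mode="cell"`).
The per-cell draw makes signal and noise features share the identical
marginal mixture, so nothing distinguishes them except covariance with
the class structure; a per-feature draw (`epsilon_mode="feature"`) is
also available but gives noise features persistent offsets that an
unsupervised method can only see as extra rank-one structure, making the
task markedly easier for PCA-based and HSIC-based selectors.  Ensemble
`e` uses seed `root_seed + e`, so any ensemble reproduces in isolation.

**Expression fixture**: 12 conditions (7 treatment, 5 control, two
treatments unpaired) × 4 replicates = 48 samples, named `T5-10d` style
(role, stress days, rest days).  Each miRNA has a condition-level latent
`z_p = treatment_shift + √ρ·g + √(1−ρ)·own_p` with a shared program `g`
(ρ = `shared_signal`, default 0.8) — co-regulation that gives the data a
dominant PC1, as real stress-response modules do.  Planted pair `p`
couples `baseline + effect·z_p` (miRNA, each probe plus independent
noise) with `baseline − effect·z_p` (mRNA), expected Pearson correlation
`−effect²·var(z)/(effect²·var(z) + noise²)` ≈ −0.93 at the defaults
(effect 0.8, noise sd 0.25).  Planted mRNA UTRs carry the exact 7mer-m8
complement of their miRNA's positions 2–8 at a recorded offset.

What the fixture does *not* emulate: probe-level cross-hybridisation,
intensity-dependent (heteroscedastic) array noise, missing values,
annotation ambiguity, or any real regulatory network topology.  Tests
passing on it show the pipeline's statistics and bookkeeping are right —
not that the biological discovery rates on a real accession would match.

## Scoring

Confusion counts against the planted truth; MCC with the standard
denominator `(TP+FP)(TP+FN)(TN+FP)(TN+FN)` (0 on degenerate tables) and
`F = 2TP/((TP+FP)+(TP+FN))` (0 when selection and truth are both empty).
The benchmark reports per-(method, s) means over ensembles with standard
errors — the standard errors are what make tolerance-based comparisons
principled.

## Integration stage

Group tests are one-sided Welch t-tests (both orientations returned;
they sum to 1).  "Logarithmic P-values" and expression log-ratios use
natural logs — the base shifts the group statistic's inputs by a
constant factor and leaves its P-value unchanged.  Log-ratios are
computed on replicate-averaged expression (one ratio per feature per
condition pair) and require positive values.  Pair correlations are
Pearson across the 48 samples, significance via `t = r√(M−2)/√(1−r²)`
with M−2 df, BH-adjusted over the pair batch, significant below 0.05;
multiple probes of one miRNA are summarised by the median r (a choice —
the alternatives, mean or best-probe, differ only in outlier handling).
Seed matching reports every exact 7-mer window match to the reverse
complement of miRNA positions 2–8; the region scanned (3'UTR vs whole
transcript) is whatever sequence set the caller supplies.  Stability
counting drops one replicate per condition per resample (default 100
resamples), proportionally for conditions without exactly 4 replicates,
and reports per-feature selection frequencies; unpaired treatment
conditions are excluded from paired analyses by construction of the
design table.

## Problem sizes used by the shipped checks

The test suite runs the benchmark at 100 ensembles for the
closed-form-per-ensemble methods and 25 for the iterative VBPCAFE (with
a correspondingly widened tolerance); the acceptance script runs all
methods at 100 ensembles, which completes in well under a minute.  The
fixture-based checks use 20–60 features per layer, 48 samples, and 20
seeds where seed-robustness is the claim.

## Known limitations

* VBPCAFE cost scales linearly in N with a Q³ factor per feature
  (one Q×Q inversion each); whole-transcriptome runs are out of scope —
  the supported real-data path is the 200-feature test-set construction
  (selected features plus a background sample).
* The CPCAFE/VBPCAFE equivalence is an empirical regularity of the
  converged state, tight when one component dominates; with several
  comparable components the learned basis can rotate away from the PCA
  basis and the per-component correspondence weakens.
* `MislabelScheme` accepts arbitrary corruption tables; the three
  severity levels used in the robustness tests (label correlations 0.92,
  0.68, 0.63) are this package's own constructions.
* The categorical-regression threshold variant's F measure at s=1 sits
  ~0.09 above the published figure in repeated runs while its MCC
  agrees; the printed (MCC, F) pair is mutually inconsistent for
  BH-thresholded selections in that regime (small nearly-all-correct
  selections force F ≈ 0.85·MCC), so the package reports what the
  procedure actually yields.
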