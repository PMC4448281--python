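# pcafe

PCA-based **unsupervised feature extraction** for multiclass omics data,
with supervised baselines, a simulation benchmark, and miRNA–mRNA
integration utilities.

## The problem

Given a feature-by-sample expression matrix whose samples fall into
several *unordered* classes (experimental conditions, disease stages),
which features (genes, probes) actually distinguish the classes?
Pairwise tests lose power once every class pair must be significant, and
any label-using method inherits whatever noise is in the labels.  This
package implements two label-free extractors that treat the data as a
single multiclass table, the supervised methods they are benchmarked
against, and the downstream cross-omics analysis the extraction feeds.

It is aimed at computational biologists working with bulk or single-cell
expression matrices — anything shaped features × samples with a
categorical sample annotation.

## Methods

**CPCAFE** (conventional-PCA feature extraction).  Factor the (optionally
standardized) matrix as `X = B Aᵀ` by SVD, with `A` the orthonormal
per-sample loadings and `B` the feature scores, and select the features
with the largest `|B_{i,PC}|` — the outliers along a chosen principal
component.

**VBPCAFE** (feature-dependent variational Bayes PCA).  Model
`V = B Aᵀ + E` with Gaussian noise `σ_E²` and Gaussian priors on both
factors, where the prior variance of the feature scores is
*feature-dependent*:

    P(B_iq) ∝ exp(−B_iq² / 2C_B^{iq})

The variational updates learn `C_B^{iq}` per feature and component
(automatic relevance determination): features that do not follow
component `q` have `C_B^{iq}` driven toward zero, so the largest
`C_B^{i1}` values mark the features relevant to the leading pattern.  The
iteration minimises the variational free energy `F`, is initialised from
conventional PCA, and stops when the extracted set has been stable for
`patience` iterations; the minimum-`F` visited state is reported.  At
convergence `C_B^{i1} ≈ B_{i1}² + (Σ_B^i)_{11}`, which is why cheap
CPCAFE closely matches VBPCAFE — the package's central point.

**Baselines.**  One-vs-one Welch t-tests (all class pairs BH-significant),
categorical regression (per-feature one-way ANOVA across class dummies;
threshold or top-`n` ranking), and BAHSIC (backward elimination by the
smallest contribution to the linear-kernel HSIC between expression and a
delta label kernel, `HSIC = tr(K H L H)/M²`).

**Benchmark.**  A categorical multiclass simulator: `N` features, `M`
samples in `K` classes with means `μ_k = ((k−1)/(K−1) − 1/2)·s`, Gaussian
sd 0.5; the first `N′` features carry `±μ_k`, the rest draw their mean
from `{μ_k}` at random.  Selections are scored against the planted truth
with the Matthews correlation coefficient and the F measure over
independent ensembles.

**Integration.**  Treatment-vs-control group tests, cross-omics loading
correlation, miRNA–mRNA Pearson correlation with `t = r√(M−2)/√(1−r²)`
significance and BH adjustment, 7mer-m8 seed-site scanning, and
replicate-dropping selection-stability counts.

## A worked example

```python
import pcafe

em, truth = pcafe.simulate_dataset(pcafe.SimulationConfig(s=2.0), seed=1)
state = pcafe.vbpca_fit(em, Q=10, max_iter=2000, patience=100, n_top=10)
result = pcafe.vbpcafe_select(state, q=1, n_top=10)
c = pcafe.confusion(result.selected, truth, em.n_features)
print(pcafe.mcc(c), pcafe.f_measure(c))
```

Running `python examples/02_vbpca_feature_relevance.py` (the same
computation with commentary) prints:

```
converged after 102 iterations, free energy F = 1240.4
median C_B^i1 of planted features: 7.918
median C_B^i1 of noise features:   4.73e-03
selected (top 10 by C_B^i1): [0, 1, 2, 3, 4, 5, 6, 7, 8, 9]
MCC = 1.00, F = 1.00
```

The three-orders-of-magnitude gap in `C_B^{i1}` is the relevance
determination at work: the ten planted features are recovered exactly,
with no use of the class labels.  The other scripts in `examples/`
walk through the full benchmark, mislabeling robustness, and the
miRNA–mRNA integration pipeline; each prints its numbers with a note on
what they mean.

A thin CLI mirrors the library (`pcafe simulate|fixture|fe|vbpcafe|
cpcafe|benchmark|integrate`); every run writes a JSON manifest with its
parameters, seed and output checksums.

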