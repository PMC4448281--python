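"""miRNA-mRNA integration on a synthetic stress-study fixture.

Generates a 12-condition x 4-replicate expression fixture with planted
negatively correlated miRNA-mRNA pairs (the mRNA 3'UTRs carry the 7mer-m8
complement of the paired miRNA seed), extracts outlier features with
CPCAFE, and runs the downstream steps: pair correlations with
significance, seed matching, and replicate-dropping stability.
"""

import numpy as np

import pcafe

spec = pcafe.FixtureSpec(seed=0)
mirna, mrna, mirna_seqs, utr_seqs, truth = pcafe.generate_fixture(spec)
design = pcafe.ConditionDesign(truth["design"])
print(f"fixture: {mirna.n_features} miRNA probes, {mrna.n_features} mRNAs, "
      f"{mirna.n_samples} samples, {spec.n_planted_pairs} planted pairs")

# unsupervised extraction on each omics layer
emb_mr = pcafe.pca_embed(mrna, standardize_features=True)
sel_mr = pcafe.cpcafe_select(emb_mr, pc=1, n_top=12)
sel_genes = [mrna.feature_ids[i] for i in sel_mr.selected]

emb_mi = pcafe.pca_embed(mirna, center="feature")
sel_mi = pcafe.cpcafe_select(emb_mi, pc=1, n_top=24)
probe_map = truth["probe_map"]
sel_mirnas = sorted(
    {probe_map.set_index("probe_id").mirna_id[mirna.feature_ids[i]] for i in sel_mi.selected}
)
print(f"CPCAFE selected {len(sel_genes)} mRNAs and {len(sel_mirnas)} unique miRNAs")

# pair correlations + seed matching
pairs = pcafe.mirna_mrna_pairs(
    mirna, mrna, sel_mirnas, sel_genes,
    probe_map=probe_map, mirna_seqs=mirna_seqs, utr_seqs=utr_seqs,
)
hits = pairs[pairs.significant & (pairs.r < 0) & pairs.seed_match]
print(f"{len(hits)} significant negative pairs with a 7mer-m8 site:")
print(hits[["mirna_id", "mrna_id", "r", "adjusted_p"]].round(3).to_string(index=False))

# stability of the mRNA selection under replicate dropping
def run_fe(sub):
    emb = pcafe.pca_embed(sub, standardize_features=True)
    return pcafe.cpcafe_select(emb, pc=1, n_top=spec.n_planted_pairs).selected

freq, n_eff, _ = pcafe.cv_stability(mrna, design, run_fe, n_samplings=50, seed=0)
always = int((freq == n_eff).sum())
never = int((freq == 0).sum())
print(f"\nstability over {n_eff} replicate-dropping resamples: "
      f"{always} mRNAs always selected, {never} never selected "
      f"({mrna.n_features - always - never} in between)")
print()
print(
    "Each reported pair links an upregulated miRNA to a suppressed mRNA\n"
    "whose UTR carries the miRNA's seed complement — the signature of\n"
    "direct targeting.  The near-bimodal stability counts show the\n"
    "unsupervised selection is essentially deterministic under replicate\n"
    "resampling."
)
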