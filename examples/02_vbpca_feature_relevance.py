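"""Automatic relevance determination with feature-dependent VBPCA.

Fits the variational Bayes factorisation V = B A^T + E on one simulated
ensemble and shows how the learned per-feature prior variances C_B^{i1}
separate the 10 planted features from the 90 noise features — without
using the class labels.
"""

import numpy as np

import pcafe

em, truth = pcafe.simulate_dataset(pcafe.SimulationConfig(s=2.0), seed=1)
state = pcafe.vbpca_fit(em, Q=10, max_iter=2000, patience=100, n_top=10)
result = pcafe.vbpcafe_select(state, q=1, n_top=10)

cb = state.C_B[:, 0]
print(f"converged after {state.n_iter} iterations, free energy F = {state.F:.1f}")
print(f"median C_B^i1 of planted features: {np.median(cb[:10]):.3f}")
print(f"median C_B^i1 of noise features:   {np.median(cb[10:]):.2e}")
print(f"selected (top 10 by C_B^i1): {sorted(result.selected.tolist())}")

c = pcafe.confusion(result.selected, truth, em.n_features)
print(f"MCC = {pcafe.mcc(c):.2f}, F = {pcafe.f_measure(c):.2f}")
print()
print(
    "The prior variance of each feature's score acts as a relevance weight:\n"
    "features that do not follow the dominant expression pattern have their\n"
    "C_B^i1 driven toward zero (automatic relevance determination), so the\n"
    "largest C_B^i1 values mark the class-distinct features."
)
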