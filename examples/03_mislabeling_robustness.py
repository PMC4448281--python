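"""Why unsupervised extraction shrugs off label noise.

Corrupts up to 20% of the class labels at three severities and compares a
label-using method (categorical regression) with label-free CPCAFE on the
same simulated ensembles.
"""

import numpy as np

import pcafe
from pcafe.simdata import MislabelScheme

schemes = {
    "none": None,
    "little": MislabelScheme.from_moves([5] * 4, [(0, 1, 1), (1, 0, 1), (2, 3, 1), (3, 2, 1)]),
    "medium": MislabelScheme.from_moves([5] * 4, [(0, 2, 1), (1, 3, 1), (2, 0, 1), (3, 1, 1)]),
    "heavy": MislabelScheme.from_moves([5] * 4, [(0, 3, 1), (3, 0, 1), (1, 0, 1), (2, 3, 1)]),
}

labels = np.repeat(np.arange(4), 5)
config = pcafe.SimulationConfig(n_ensembles=30)
print(f"{'corruption':<10} {'label r':>8} {'catreg MCC':>11} {'cpcafe MCC':>11}")
for name, scheme in schemes.items():
    r = 1.0 if scheme is None else pcafe.apply_mislabeling(labels, scheme, seed=0)[1]
    out = pcafe.run_benchmark(
        ["catreg-rank", "cpcafe"], config, [1.0], mislabel=scheme, seed=4
    ).summary.set_index("method")
    print(f"{name:<10} {r:>8.2f} {out.loc['catreg-rank', 'mean_mcc']:>11.3f} "
          f"{out.loc['cpcafe', 'mean_mcc']:>11.3f}")

print()
print(
    "'label r' is the Pearson correlation between true and corrupted labels.\n"
    "The supervised method degrades as labels worsen; CPCAFE's column is\n"
    "constant because it never reads the labels — its selections are bitwise\n"
    "identical across all four rows."
)
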