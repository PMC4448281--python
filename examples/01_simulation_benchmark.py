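"""Benchmark the five feature-extraction methods on simulated data.

Draws categorical multiclass ensembles (100 features, 20 samples in 4
unordered classes, 10 features truly class-distinct) and scores each
method's selected set against the planted truth.  A scaled-down run (20
ensembles) keeps this example quick; the published-scale comparison uses
100.
"""

import pcafe

config = pcafe.SimulationConfig(n_ensembles=20)
summary = pcafe.run_benchmark(
    ["catreg-adj", "catreg-rank", "bahsic", "vbpcafe", "cpcafe"],
    config,
    s_values=[2.0, 1.0, 0.5],
    seed=0,
).summary

print(summary.round(3).to_string(index=False))
print()
print(
    "mean_mcc/mean_f score the overlap between each method's selected\n"
    "features and the 10 planted ones (1 = perfect recovery, ~0 = chance).\n"
    "s controls class separation: at s=2 every method does well; at s=0.5\n"
    "the classes almost coincide and all methods approach chance.  The two\n"
    "unsupervised methods (vbpcafe, cpcafe) reach this without ever seeing\n"
    "the class labels."
)
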