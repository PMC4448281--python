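import numpy as np
import pytest

import pcafe


@pytest.fixture(scope="session")
def easy_dataset():
    """One benchmark ensemble in the easy regime (s=2)."""
    cfg = pcafe.SimulationConfig(s=2.0)
    em, truth = pcafe.simulate_dataset(cfg, seed=42)
    return em, truth


@pytest.fixture(scope="session")
def fixture_data():
    """The planted-biology miRNA/mRNA fixture with its ground truth."""
    spec = pcafe.FixtureSpec(seed=7)
    mirna, mrna, mirna_seqs, utr_seqs, truth = pcafe.generate_fixture(spec)
    return {
        "spec": spec,
        "mirna": mirna,
        "mrna": mrna,
        "mirna_seqs": mirna_seqs,
        "utr_seqs": utr_seqs,
        "truth": truth,
        "design": pcafe.ConditionDesign(truth["design"]),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
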