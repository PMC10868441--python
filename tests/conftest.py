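import numpy as np
import pytest

from ensemblekit.generator import GeneratorConfig, generate_ensemble
from ensemblekit.io import ca_trace


@pytest.fixture(scope="session")
def small_ensemble():
    """30-residue, 40-conformer unrestrained ensemble (mixed classes)."""
    cfg = GeneratorConfig(sequence="ASGTPLKQEDGYSNHT" * 2,
                          n_conformers=40, seed=101)
    return generate_ensemble(cfg)


@pytest.fixture(scope="session")
def small_trace(small_ensemble):
    return ca_trace(small_ensemble)


@pytest.fixture(scope="session")
def ensemble_pair():
    """Two independent small ensembles of the same sequence."""
    seq = "ASGTPLKQEDGYSNH"
    e1 = generate_ensemble(GeneratorConfig(sequence=seq, n_conformers=15,
                                           seed=7))
    e2 = generate_ensemble(GeneratorConfig(sequence=seq, n_conformers=12,
                                           seed=8))
    return e1, e2


def random_weights(n, seed):
    rng = np.random.default_rng(seed)
    w = rng.random(n) + 0.05
    return w / w.sum()
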