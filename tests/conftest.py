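import numpy as np
import pytest

from sigtarget import SyntheticConfig, generate


@pytest.fixture(scope="session")
def small_dataset():
    """Small high-signal synthetic dataset shared by read-only tests."""
    cfg = SyntheticConfig(
        n_genes=120,
        n_proteins=6,
        n_compounds=40,
        signal_strength=3.0,
        fraction_activators=0.25,
        seed=7,
    )
    return generate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
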