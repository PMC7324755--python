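import numpy as np
import pytest

from panveil import simulate as sim


@pytest.fixture(scope="session")
def small_panel():
    """A small simulated strain panel with ground truth (3 strains)."""
    cfg = sim.SimulationConfig(
        n_strains=3, n_core=10, n_accessory=4, n_specific=1,
        mean_protein_length=120, divergence=0.05, paralog_rate=0.0, seed=7,
    )
    proteomes, truth = sim.simulate_pangenome(cfg)
    return cfg, proteomes, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
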