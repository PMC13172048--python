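import numpy as np
import pytest

from ifnkit import SimulationConfig, simulate


def small_config(seed: int = 7, **overrides) -> SimulationConfig:
    """A desk-scale simulation: 50 genes, short chromosome, few cells."""
    defaults = dict(
        seed=seed,
        n_coding_genes=40,
        n_noncoding_genes=10,
        chrom_length=400_000,
        n_cells_per_sample=60,
        n_decoy_pwms=3,
        frac_core=0.2,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_sim():
    return simulate(small_config())


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
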