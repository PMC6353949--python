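import numpy as np
import pandas as pd
import pytest

from xenonet import SimulationConfig


@pytest.fixture
def small_config():
    return SimulationConfig(
        seed=7,
        n_reads=1000,
        n_genes_per_species=100,
        n_samples_per_group=5,
        n_modules=2,
        module_sizes=(20, 20),
        n_de_genes=10,
        de_log2fc=1.5,
    )


@pytest.fixture
def groups_5v5():
    samples = [f"C{i}" for i in range(1, 6)] + [f"T{i}" for i in range(1, 6)]
    return pd.Series(
        {s: "control" if s.startswith("C") else "treated" for s in samples}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
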