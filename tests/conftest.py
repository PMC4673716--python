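import numpy as np
import pytest

from isoscan.sim import SimConfig, simulate


TINY = dict(n_true_genes=24, n_clr_reads=120, per_base_error=0.0,
            short_read_depth=5.0, short_read_error=0.0,
            chimera_rate=0.05, truncation_rate=0.1)


@pytest.fixture(scope="session")
def tiny_sim():
    """Small error-free dataset shared by read-only tests."""
    return simulate(SimConfig(seed=11, **TINY))


@pytest.fixture(scope="session")
def tiny_result(tiny_sim):
    from isoscan.pipeline import run_synthetic

    return run_synthetic(tiny_sim)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
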