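import numpy as np
import pytest

from mitometh import EmissionModel, ReadLengthModel, SimConfig, simulate_calls


@pytest.fixture(scope="session")
def fu_sample():
    """A moderate FU-control run with its truth, shared across tests."""
    cfg = SimConfig(
        genome_length=8000,
        n_reads=25,
        seed=11,
        emission=EmissionModel(mu=4.0, sigma=2.5),
    )
    calls, truth = simulate_calls(cfg, mode="FU")
    return calls, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
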