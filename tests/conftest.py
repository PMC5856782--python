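import numpy as np
import pytest

from altipop.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic L/M/H dataset shared across read-only tests."""
    cfg = SimulationConfig(n_transcripts=300, seed=11)
    table, annotation, design, counts, lengths, truth = simulate_dataset(cfg)
    return dict(
        config=cfg, table=table, annotation=annotation, design=design,
        counts=counts, lengths=lengths, truth=truth,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
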