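import numpy as np
import pytest

from tyquant import synthgen


@pytest.fixture(scope="session")
def small_config():
    return synthgen.SimulationConfig(
        seed=11,
        n_reads_per_sample=300,
        sequencing_error_rate=0.0,
        substitution_rate=0.02,
    )


@pytest.fixture(scope="session")
def panel(small_config):
    return synthgen.make_panel(small_config)


@pytest.fixture(scope="session")
def sample_with_truth(panel, small_config):
    rng = np.random.default_rng(small_config.seed)
    variants = synthgen.make_variants(panel, small_config, rng)
    return synthgen.simulate_sample(
        panel, small_config, sample_id="s0", variants=variants, rng=rng
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
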