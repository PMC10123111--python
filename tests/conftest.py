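import numpy as np
import pytest

from kymotrace.simulate import SimulationConfig, simulate_kymograph


@pytest.fixture(scope="session")
def small_kymo():
    """One immobile high-SNR event on a short tether (shared, read-only)."""
    cfg = SimulationConfig(
        n_lines=300,
        dna_length=10000,
        damage_sites=[5000],
        arrival_rate=0.02,
        dwell_components=[(3.0, 1.0)],
        emission_rate=80.0,
        background_rate=1.0,
        seed=7,
    )
    return simulate_kymograph(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
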