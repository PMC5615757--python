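import numpy as np
import pytest

from tissuelight import OpticalProperties, SlabStack, fixture_table, run_mc


@pytest.fixture(scope="session")
def liver_635() -> OpticalProperties:
    """Normal chicken liver at 635 nm, the canonical reference tissue state."""
    return OpticalProperties(mu_a=1.4129, mu_s=24.7830, g=0.6794, thickness=0.2)


@pytest.fixture(scope="session")
def tissue_states():
    return fixture_table()


@pytest.fixture(scope="session")
def mc_reference_runs(tissue_states):
    """One 10^6-photon MC run per reference tissue state (shared across tests)."""
    out = {}
    for name, wl, props in tissue_states:
        out[(name, wl)] = run_mc(SlabStack.single(props), n_photons=1_000_000,
                                 seed=20_260_925)
    return out


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
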