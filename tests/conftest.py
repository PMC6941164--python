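import numpy as np
import pytest

from vfamethane import (
    CowRecord,
    Dataset,
    SimulationConfig,
    VFAProfile,
    make_fixture,
    simulate_dataset,
)


@pytest.fixture
def mean_profile():
    """A profile at the development data's mean composition."""
    return VFAProfile(acetate=63.3, propionate=20.2, butyrate=9.9)


@pytest.fixture
def tiny_dataset():
    """Three hand-built valid records across two experiments."""
    return Dataset(
        records=[
            CowRecord("E1", "T1", "C1", VFAProfile(63.3, 20.2, 9.9), 20.7),
            CowRecord("E1", "T1", "C2", VFAProfile(60.0, 25.0, 8.0), 17.0),
            CowRecord("E2", "T1", "C1", VFAProfile(66.0, 17.0, 11.0), 24.5),
        ],
        provenance="hand-built",
    )


@pytest.fixture(scope="session")
def tiny_2exp():
    return make_fixture("tiny_2exp")


@pytest.fixture(scope="session")
def noiseless_m3():
    return make_fixture("noiseless_m3")


@pytest.fixture(scope="session")
def noiseless_m4():
    return make_fixture("noiseless_m4")


@pytest.fixture(scope="session")
def study_scale():
    return make_fixture("study_scale_seed42")


def random_profile(rng: np.random.Generator, with_conc: bool = False) -> VFAProfile:
    """A random valid profile spanning the equations' domain."""
    p = rng.uniform(12.0, 42.0)
    b = rng.uniform(1.0, 16.0)
    a = rng.uniform(40.0, 99.0 - p - b)
    kwargs = {}
    if with_conc:
        total = rng.uniform(60.0, 160.0)
        kwargs = {"total_vfa_conc": total, "propionate_conc": p / 100.0 * total}
    return VFAProfile(acetate=a, propionate=p, butyrate=b, **kwargs)
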