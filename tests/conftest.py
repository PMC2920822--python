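import numpy as np
import pytest

from fusedcna import (
    FusedLassoParams,
    PlantedEvent,
    ProbeMap,
    compute_fusion_weights,
    generate_dataset,
    make_probe_map,
)


@pytest.fixture(scope="session")
def probe_map_10() -> ProbeMap:
    """Ten uniformly spaced probes on one chromosome, arms split 5/5."""
    return make_probe_map(10, gap_model="uniform", gap=1000)


@pytest.fixture(scope="session")
def planted_cohort():
    """40 samples x 100 probes, 20 carriers of a +1.0 gain on probes 40-60."""
    probe_map = make_probe_map(100)
    event = PlantedEvent(tuple(range(20)), 40, 60, 1.0)
    profiles, events = generate_dataset(40, probe_map, [event], noise_sd=0.2, seed=11)
    return profiles, events[0]


@pytest.fixture(scope="session")
def default_params() -> FusedLassoParams:
    return FusedLassoParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
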