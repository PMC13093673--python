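import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from seedsieve.phenology import FloweringSchedule, Plant
from seedsieve.synth import GeneratorParams, generate_experiment
from seedsieve.toy_model import GenotypeValueMap, assortative_batches


@pytest.fixture(scope="session")
def values():
    return GenotypeValueMap()


@pytest.fixture()
def default_batches():
    return assortative_batches()


@pytest.fixture(scope="session")
def offset_population():
    """16 early + 16 late plants; late line starts 14 days later."""
    early = [
        Plant(f"E{i:02d}", "EE", "EE", FloweringSchedule(30.0, 30.0))
        for i in range(16)
    ]
    late = [
        Plant(f"L{i:02d}", "LL", "LL", FloweringSchedule(44.0, 30.0))
        for i in range(16)
    ]
    return early + late


@pytest.fixture(scope="session")
def degenerate_pair():
    """Two plants whose overlap makes first seeds pure-sired and the
    mixed windows exactly 50:50 when self pollen is counted."""
    return [
        Plant("E1", "EE", "EE", FloweringSchedule(0.0, 20.0)),
        Plant("L1", "LL", "LL", FloweringSchedule(10.0, 20.0)),
    ]


@pytest.fixture(scope="session")
def synthetic_table():
    return generate_experiment(GeneratorParams(rng_seed=11))
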