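import pytest
from hypothesis import settings

from fibermech.probe import ProbeSpec, probe_preset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from fibermech.samples import PlantParams, plant_preset


@pytest.fixture(scope="session")
def short_probe() -> ProbeSpec:
    return probe_preset("short")


@pytest.fixture(scope="session")
def long_probe() -> ProbeSpec:
    return probe_preset("long")


@pytest.fixture(scope="session")
def core() -> PlantParams:
    return plant_preset("pre_culture_core")


@pytest.fixture(scope="session")
def myobundle() -> PlantParams:
    return plant_preset("myobundle")


@pytest.fixture(scope="session")
def linear_core(core) -> PlantParams:
    """Pre-culture core without strain stiffening: a truly linear plant."""
    from dataclasses import replace

    return replace(core, passive_stiffening=0.0)


@pytest.fixture(scope="session")
def elastic_plant() -> PlantParams:
    """Purely elastic, linear sample (no arm, no drag, no stiffening)."""
    return PlantParams(
        equilibrium_modulus=3000.0,
        diameter=200e-6,
        rest_length=5e-3,
    )
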