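import pytest

from redcal import (
    ProtonBeam,
    SimulationConfig,
    build_report,
    load_tissue_table,
    water_reference,
)


@pytest.fixture(scope="session")
def reference_set():
    return load_tissue_table("icrp23_reference")


@pytest.fixture(scope="session")
def water():
    return water_reference()


@pytest.fixture(scope="session")
def beam():
    return ProtonBeam.from_energy()


@pytest.fixture(scope="session")
def default_bundle():
    """Full pipeline under the study conditions (5% sigma, 100/tissue)."""
    return build_report(config=SimulationConfig(seed=0))
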