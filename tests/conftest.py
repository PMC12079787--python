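import pytest

from bondbreak import (
    SamplerConfig,
    embed_geometry,
    parse_molecule,
    run_bond_trajectory,
)
from bondbreak.toy_models import ToyForceField


@pytest.fixture(scope="session")
def methane():
    return parse_molecule("C", "methane")


@pytest.fixture(scope="session")
def ethane():
    return parse_molecule("CC", "ethane")


@pytest.fixture(scope="session")
def ethane_geometry(ethane):
    return embed_geometry(ethane, seed=0)


@pytest.fixture(scope="session")
def ethane_calc(ethane):
    return ToyForceField(ethane, reference_bond=(0, 1))


@pytest.fixture
def fast_config():
    """Shrunk sampling loop for quick unit tests (2 steps, 50 fs of MD)."""
    return SamplerConfig(
        stages=((1.5, 2),), t_md=0.05, t_dump=10.0, snapshot_cap=3, rng_seed=7
    )


@pytest.fixture(scope="session")
def full_ethane_run(ethane, ethane_geometry, ethane_calc):
    """One complete default-configuration run on ethane's C-C bond.

    Session-scoped: this is the workflow's flagship result (15 + 150
    conformers) and several tests inspect different aspects of it.
    """
    config = SamplerConfig(rng_seed=0)
    return run_bond_trajectory(ethane, ethane_geometry, (0, 1), ethane_calc, config)
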