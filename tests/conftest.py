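import numpy as np
import pytest

from plumetrace.inference import DEFAULT_GAP
from plumetrace.kinematics import InstrumentConfig
from plumetrace.plume import PlumeModel, ScenarioGrid, generate_scenario
from plumetrace.species import DIMER, MONOMER


@pytest.fixture(scope="session")
def instrument():
    """The 4.5-kV single-stage instrument (field 3.54e5 V/m)."""
    return InstrumentConfig(voltage=4500.0, gap=DEFAULT_GAP)


@pytest.fixture(scope="session")
def monomer():
    return MONOMER


@pytest.fixture(scope="session")
def dimer():
    return DIMER


@pytest.fixture(scope="session")
def default_models():
    """Generator truth at the published distribution parameters."""
    return [
        PlumeModel(MONOMER, tE_mean=46e-9, tE_sd=11e-9),
        PlumeModel(DIMER, tE_mean=64e-9, tE_sd=12e-9),
    ]


def small_models(ions_per_shot=800):
    return [
        PlumeModel(MONOMER, tE_mean=46e-9, tE_sd=11e-9, ions_per_shot=ions_per_shot),
        PlumeModel(DIMER, tE_mean=64e-9, tE_sd=12e-9, ions_per_shot=ions_per_shot),
    ]


@pytest.fixture(scope="session")
def small_archive(instrument):
    """A reduced default-design archive (one voltage, fewer ions) shared by
    the depletion and inference tests."""
    grid = ScenarioGrid(
        slabs=tuple((0.6e-3 + i * 1e-3, 1.6e-3 + i * 1e-3) for i in range(4)),
        delays=tuple(i * 50e-9 for i in range(11)),
        voltages=(4500.0,),
        shots_per_spectrum=8,
        seed=7,
    )
    return grid, generate_scenario(grid, small_models(), instrument)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
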