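"""Shared fixtures: noiseless synthetic datasets reused across test modules."""

import pytest

from otophys import met
from otophys.synth import (
    ImagingSimConfig, MetSimConfig, simulate_imaging_fixtures, simulate_met_family,
    simulate_vg_family, type_ii_config,
)


@pytest.fixture(scope="session")
def noiseless_met_family():
    family, truth = simulate_met_family(MetSimConfig(noise_sd=0.0))
    return met.correct_voltages(family), truth


@pytest.fixture(scope="session")
def noiseless_vg_family():
    return simulate_vg_family(type_ii_config(inactivating_fraction=0.0))


@pytest.fixture(scope="session")
def imaging_fixture():
    return simulate_imaging_fixtures(ImagingSimConfig())
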