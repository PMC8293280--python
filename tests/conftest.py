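import copy

import numpy as np
import pytest

from kv4pace.channels import RegionDensities, load_channel_defaults
from kv4pace.morphology import (
    Morphology,
    MorphologyTemplate,
    Section,
    generate_population,
)
from kv4pace.simulator import assemble_model, run_pacemaking


@pytest.fixture(scope="session")
def population():
    return generate_population(3, seed=7)


@pytest.fixture(scope="session")
def morph(population):
    return population[0]


@pytest.fixture(scope="session")
def default_model(morph):
    return assemble_model(morph)


@pytest.fixture(scope="session")
def pacemaking_trace(default_model):
    """One full spontaneous-activity run of the default model (shared across
    tests; the simulation is deterministic)."""
    return run_pacemaking(default_model)


@pytest.fixture(scope="session")
def zero_active_densities():
    """Density table with every active conductance silenced (passive cell)."""
    gmax = copy.deepcopy(load_channel_defaults()["densities"].gmax)
    for chan in gmax:
        if chan == "leak":
            continue
        for region in gmax[chan]:
            gmax[chan][region] = 0.0
    return RegionDensities(gmax=gmax)


@pytest.fixture()
def soma_only_morph():
    return Morphology(sections=[Section("soma", 27.0, 27.0, -1)], id="soma_only")
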