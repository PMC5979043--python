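"""Shared fixtures.

The long coupled simulations (one-minute stimulation protocols) are
expensive, so each distinct run is computed once per session and shared
between the property tests and the acceptance tests.
"""

from __future__ import annotations

import pytest

from pscsim import (CompartmentState, DEFAULT_CONSTANTS, astro_params,
                    build_combined, build_glu_puff, build_k_driven,
                    build_unstimulated, derive_morphology, neuron_params,
                    prepare_setup, run_simulation)


@pytest.fixture(scope="session")
def constants():
    return DEFAULT_CONSTANTS


@pytest.fixture(scope="session")
def morph():
    return derive_morphology()


@pytest.fixture(scope="session")
def astro():
    return astro_params()


@pytest.fixture(scope="session")
def baseline():
    return CompartmentState()


@pytest.fixture(scope="session")
def neuron_defaults():
    return neuron_params()


@pytest.fixture(scope="session")
def setup_default():
    """Fully calibrated bundle under the as-printed EAAT profile."""
    return prepare_setup()


@pytest.fixture(scope="session")
def setup_rescaled():
    return prepare_setup(eaat_profile="rescaled")


@pytest.fixture(scope="session")
def k_driven_runs(setup_default):
    """K+-driven protocol at the four standard firing rates."""
    return {rate: run_simulation(build_k_driven(rate), setup=setup_default)
            for rate in (20, 40, 60, 80)}


@pytest.fixture(scope="session")
def run40(k_driven_runs):
    return k_driven_runs[40]


@pytest.fixture(scope="session")
def run80(k_driven_runs):
    return k_driven_runs[80]


@pytest.fixture(scope="session")
def unstimulated_run(setup_default):
    return run_simulation(build_unstimulated(duration=6.0), setup=setup_default)


@pytest.fixture(scope="session")
def glu_puff_run(setup_rescaled):
    return run_simulation(build_glu_puff(), setup=setup_rescaled)


@pytest.fixture(scope="session")
def combined40_run(setup_rescaled):
    return run_simulation(build_combined(40), setup=setup_rescaled)
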