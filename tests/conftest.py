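import numpy as np
import pytest

from helicoid import HelicoidParams, simulate_species_panel

#: Full synthetic-instrument wavelength window, nm.
FULL_RANGE = (350.0, 900.0)


@pytest.fixture(scope="session")
def thick_wall_params() -> HelicoidParams:
    """A many-turn wall (near-total reflection) with 320 nm pitch."""
    return HelicoidParams(pitch_nm=320.0, n_turns=70)


@pytest.fixture(scope="session")
def left_panel(thick_wall_params):
    """A ten-cell left-handed panel at default study conditions."""
    return simulate_species_panel(thick_wall_params, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
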