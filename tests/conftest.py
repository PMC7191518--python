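import numpy as np
import pytest

from cgc import stimgen, synth


@pytest.fixture(scope="session")
def low_drc_40s():
    """Canonical 40-s low-contrast DRC (1,600 chords x 25 tones)."""
    return stimgen.generate_drc(stimgen.LOW_CONTRAST, 40.0, seed=7)


@pytest.fixture(scope="session")
def high_drc_40s():
    return stimgen.generate_drc(stimgen.HIGH_CONTRAST, 40.0, seed=8)


@pytest.fixture(scope="session")
def linear_ln_unit():
    """Noiseless LN unit in the exactly linear regime (no rate flooring)."""
    return synth.make_ln_params(seed=3, nonlinearity="linear", noise_sd=0.0, bias=50.0)


@pytest.fixture(scope="session")
def passive_cell_sweeps():
    """Noiseless passive cell with electrode, pulse train + 0.1-s silence."""
    params = synth.PatchSimParams(
        R_input=100.0, tau_input=20.0, R_access=20.0, tau_access=0.5,
        trial_noise_sd=0.0, seed=1,
    )
    sweeps = synth.simulate_whole_cell(
        params, I_levels=[-40.0, 40.0], n_trials=1,
        g_syn=np.zeros(2000), fs=20_000.0,
    )
    return params, sweeps
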