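import numpy as np
import pytest

from audiopred.stimuli import StimulusSpec, make_am_noise_stimulus


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def am_stimulus():
    """3 Hz, 80 % depth, 3 s + 833 ms constant; 8 kHz keeps tests light."""
    return make_am_noise_stimulus(StimulusSpec(sample_rate_hz=8000.0, seed=0))


@pytest.fixture(scope="session")
def small_recording():
    """Tiny sustained-only cohort recording shared by slow-ish tests."""
    from audiopred.simulate import make_electrode_table, make_ground_truth, simulate_neural_response
    from audiopred.stimuli import StimulusSpec, make_am_noise_stimulus

    stim = make_am_noise_stimulus(StimulusSpec(sample_rate_hz=4000.0, seed=0))
    electrodes = make_electrode_table(n_sustained=6, n_transient=2, n_null=2, seed=0)
    truth = make_ground_truth(electrodes)
    rec = simulate_neural_response(stim, electrodes, truth, n_trials=12, seed=0)
    return stim, electrodes, truth, rec
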