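import numpy as np
import pytest

from mspilot.synth import (
    generate_template_maps,
    rectified_sine_envelope,
    render_eeg,
    sample_label_sequence,
    uniform_sequence_model,
)


@pytest.fixture(scope="session")
def template_maps():
    """7 planted topographies on the 64-channel montage."""
    return generate_template_maps(7, 64, max_similarity=0.7, seed=1)


@pytest.fixture(scope="session")
def planted_sequence():
    """30 s semi-Markov label sequence, mean dwell 20 samples at 250 Hz."""
    model = uniform_sequence_model(7, mean_dwell=20)
    return sample_label_sequence(model, 30 * 250, seed=5, fs=250.0)


@pytest.fixture(scope="session")
def clean_recording(template_maps, planted_sequence):
    """Noiseless render of the planted sequence."""
    env = rectified_sine_envelope(planted_sequence.n_samples, 250.0)
    return render_eeg(
        template_maps, planted_sequence, env, snr_db=np.inf, seed=6
    )


@pytest.fixture(scope="session")
def noisy_recording(template_maps, planted_sequence):
    """Same render at 20 dB SNR."""
    env = rectified_sine_envelope(planted_sequence.n_samples, 250.0)
    return render_eeg(template_maps, planted_sequence, env, snr_db=20.0, seed=6)
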