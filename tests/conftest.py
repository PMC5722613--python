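import numpy as np
import pytest

from tmsep import spikedetect, synthgen


@pytest.fixture(scope="session")
def rendered_session():
    """One rendered baseline-only session with ground-truth spikes.

    Shared by the detection tests: 30 trials of homogeneous 15/s multiunit
    firing, 80 uV biphasic waveforms on 8 uV white noise, 40 kHz, with
    blanking intervals around each stimulus.
    """
    cfg = synthgen.SynthSessionConfig(n_trials=30, intensities=(0.0,),
                                      orientation="ML", seed=7, noise_sd=8.0)
    session, truth = synthgen.simulate_session(cfg, ground_truth=True)
    filtered = spikedetect.bandpass(session.recording, (300.0, 5000.0))
    return session, truth, filtered


@pytest.fixture()
def gaussian_noise():
    rng = np.random.default_rng(42)
    return rng.normal(0.0, 1.0, size=400_000)
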