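import numpy as np
import pytest

import somnotype as st


@pytest.fixture(scope="session")
def wistar():
    return st.wistar_like()


@pytest.fixture(scope="session")
def msp():
    return st.msp_like()


@pytest.fixture(scope="session")
def nrem_30min():
    """30 min of pure NREM scoring at 4-s epochs."""
    return st.Hypnogram(np.array(["N"] * 450))


@pytest.fixture(scope="session")
def synthetic_nrem(wistar, nrem_30min):
    """30-min synthetic NREM recording (256 Hz) with ground truth."""
    fs = 256.0
    sig, truth = st.synthesize_eeg(nrem_30min, wistar, fs=fs, seed=42)
    rec = st.PSGRecording({"EEG Frontal": sig}, fs=fs)
    return rec, nrem_30min, truth


def random_hypnogram(rng, max_epochs=50):
    """Uniform random short hypnogram for oracle-equivalence tests."""
    n = rng.integers(1, max_epochs + 1)
    return st.Hypnogram(rng.choice(list("WNR"), size=n))
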