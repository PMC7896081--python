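import numpy as np
import pytest

from tonecortex import features as feat
from tonecortex import synth


@pytest.fixture(scope="session")
def small_stimulus():
    return synth.make_stimulus(30, seed=11)


@pytest.fixture(scope="session")
def small_features(small_stimulus):
    return feat.build_stimulus_features(small_stimulus, seed=7)


@pytest.fixture(scope="session")
def pitch_truth(small_features):
    """Three electrodes driven by speaker-normalized pitch only."""
    dims = small_features.set_dims(["intensity", "rel_pitch", "pitch_change"])
    return synth.random_truth(
        dims, [["rel_pitch", "pitch_change"]] * 3, n_lags=15, seed=5, noise_sd=1.0
    )


@pytest.fixture(scope="session")
def small_recording(small_stimulus, small_features, pitch_truth):
    return synth.make_neural(
        small_stimulus, small_features, pitch_truth, seed=9, noise_relative=True
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
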