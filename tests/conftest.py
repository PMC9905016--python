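import numpy as np
import pytest

from avcortex import synth
from avcortex.pipeline import _neural_tensor


@pytest.fixture(scope="session")
def small_session():
    """High-SNR 6x6x4 session, 30 neurons, 8 motion PCs: the sound kernels
    are strong enough that every downstream stage should recover the planted
    structure cleanly."""
    sched = synth.generate_schedule(6, 6, 4, seed=0, spontaneous_duration=240)
    truth = synth.default_ground_truth(
        n_neurons=30, n_videos=6, n_sounds=6, n_motion_pcs=8,
        seed=1, amplitude=3.0)
    return synth.generate_session(sched, truth, seed=2)


@pytest.fixture(scope="session")
def small_tensor(small_session):
    D, _ = _neural_tensor(small_session)
    return D


@pytest.fixture(scope="session")
def full_session():
    """Full 12x12 factorial design (576 trials), 40 neurons, 16 motion PCs,
    strong sound kernels."""
    sched = synth.generate_schedule(12, 12, 4, seed=10, spontaneous_duration=240)
    truth = synth.default_ground_truth(
        n_neurons=40, n_motion_pcs=16, seed=11, amplitude=3.0)
    return synth.generate_session(sched, truth, seed=12)


@pytest.fixture(scope="session")
def full_tensor(full_session):
    D, _ = _neural_tensor(full_session)
    return D


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
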