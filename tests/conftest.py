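import numpy as np
import pandas as pd
import pytest

from eightart.simulate import EEGRecording
from eightart.task import ShapeSet


@pytest.fixture(scope="session")
def shapes():
    return ShapeSet()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_recording(data_uV, ch_names, sfreq=500.0, events=None):
    """Build an EEGRecording from raw arrays (test helper)."""
    if events is None:
        events = pd.DataFrame(columns=["sample", "kind", "trial_index"])
    return EEGRecording(
        ch_names=tuple(ch_names),
        data=np.asarray(data_uV, np.float64),
        sfreq=sfreq,
        events=events,
    )


@pytest.fixture(scope="session")
def small_session():
    """A short two-condition session for end-to-end tests."""
    from dataclasses import replace

    from eightart.task import ISDesign, MIDesign, generate_is_sequence, generate_mi_sequence

    shapes = ShapeSet()
    mi = generate_mi_sequence(MIDesign(n_blocks=2, trials_per_block=40), shapes, 7)
    is_ = generate_is_sequence(ISDesign(n_blocks=1, trials_per_block=40), shapes, 8)
    trials = [replace(t, trial_index=i) for i, t in enumerate(mi + is_)]
    return shapes, trials
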