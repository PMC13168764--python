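import numpy as np
import pytest

from tkebgc.data import MultimodalTrial, TrialMeta


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_trial(rng, n_ticks=40, tick_rate=60.0, task="desk", subject="S1", rep=1):
    """A random but range-valid multimodal trial."""
    return MultimodalTrial(
        tick_rate=tick_rate,
        emg=rng.uniform(0.0, 0.5, (n_ticks, 3)),
        tactile=rng.uniform(0.0, 15.0, (n_ticks, 9)),
        joints=rng.uniform(0.0, 90.0, (n_ticks, 5)),
        meta=TrialMeta(subject_id=subject, task=task, repetition=rep,
                       duration_s=n_ticks / tick_rate),
    )


@pytest.fixture
def trial_factory():
    return random_trial
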