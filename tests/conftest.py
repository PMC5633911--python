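import numpy as np
import pytest

from cyclespm.datatypes import RawCycle


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cycle(
    samples,
    missing=None,
    subject="s1",
    task="RF",
    recording="r1",
    repetition=2,
    channels=None,
):
    """Build a RawCycle from a (C, T) array (or (T,) for one channel)."""
    samples = np.atleast_2d(np.asarray(samples, float))
    if channels is None:
        channels = tuple(("elbow", f"ch{i}") for i in range(samples.shape[0]))
    return RawCycle(
        subject_id=subject,
        task=task,
        recording_id=recording,
        repetition_index=repetition,
        channels=channels,
        samples=samples,
        missing=missing,
    )


@pytest.fixture
def cycle_factory():
    return make_cycle
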