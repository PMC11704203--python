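import numpy as np
import pytest

from sfdyn import AccelRecording, PHASES


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(xyz, fs=100.0, sensor="torso", phase_marks=None, **kw):
    xyz = np.asarray(xyz, dtype=float)
    t = np.arange(len(xyz)) / fs
    return AccelRecording(
        sensor_location=sensor, fs=fs, t=t, xyz=xyz, phase_marks=phase_marks or {}, **kw
    )


@pytest.fixture
def five_phase_recording(rng):
    """10-min recording with 5 contiguous 2-min phases at 100 Hz."""
    n = 12000
    xyz = rng.standard_normal((5 * n, 3))
    marks = {p: (i * n, (i + 1) * n) for i, p in enumerate(PHASES)}
    return make_recording(xyz, phase_marks=marks, participant="p001")
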