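import numpy as np
import pytest

from blowspiro import AudioSignal, BlowParams, CWDConfig, synth_blow

RATE = 44_100.0


@pytest.fixture(scope="session")
def cold_blow() -> AudioSignal:
    return synth_blow(BlowParams(blow_type="cold", duration=2.0, seed=7), RATE)


@pytest.fixture(scope="session")
def hot_blow() -> AudioSignal:
    return synth_blow(BlowParams(blow_type="hot", duration=2.0, seed=7), RATE)


@pytest.fixture(scope="session")
def fast_cfg() -> CWDConfig:
    """Analysis config capped at a handful of frames to keep tests quick."""
    return CWDConfig(max_frames=4)


@pytest.fixture()
def tone() -> AudioSignal:
    t = np.arange(int(RATE)) / RATE
    return AudioSignal(samples=np.sin(2 * np.pi * 1000.0 * t), sample_rate=RATE)
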