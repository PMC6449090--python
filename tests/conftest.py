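import numpy as np
import pytest

from pfkinetics import synthetic_data as syn


class StubIdealized:
    """Minimal idealized-trace stand-in: a class-label path plus frame interval."""

    def __init__(self, labels, frame_interval=1.0):
        self.labels = np.asarray(labels, dtype=int)
        self._dt = frame_interval

    @property
    def frame_interval(self):
        return self._dt


@pytest.fixture
def stub_ideal():
    return StubIdealized


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def dna_scheme():
    """Three-state binding scheme at the published naked-DNA rate constants."""
    return syn.reb1_dna_scheme()
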