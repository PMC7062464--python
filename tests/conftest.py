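"""Shared fixtures: small stimuli and populations, generated at test time."""

import numpy as np
import pytest

from icophys import simulate as S
from icophys import stimuli as X


@pytest.fixture(scope="session")
def grid50():
    return X.make_frequency_grid(50, 3000.0, 70000.0)


@pytest.fixture(scope="session")
def drc_grid():
    return X.make_frequency_grid(50, 5000.0, 40000.0)


@pytest.fixture(scope="session")
def small_grid():
    return X.make_frequency_grid(10, 4000.0, 40000.0)


@pytest.fixture(scope="session")
def small_sched(small_grid):
    """10 frequencies x 6 repeats, paper timing: 60 events, 30 s."""
    return X.make_tone_schedule(small_grid, n_repeats=6, seed=11)


@pytest.fixture(scope="session")
def tiny_drc(drc_grid):
    """20 s DRC (1000 chords), 2 files."""
    return X.make_drc(drc_grid, total_dur=20.0, n_files=2, seed=5)


def regular_spikes(rate_hz: float, duration: float, phase: float = 0.0) -> np.ndarray:
    """Deterministic spike train: one spike every 1/rate seconds."""
    period = 1.0 / rate_hz
    t = np.arange(phase, duration, period)
    return t[(t >= 0) & (t < duration)]


@pytest.fixture(scope="session")
def modulated_population():
    """30 units with the gain/offset ground truth used in recovery checks."""
    mod = S.ModulationModel(spont_delta=2.0, evoked_gain=0.8)
    return S.make_population(30, modulation=mod, seed=21)
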