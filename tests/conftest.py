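import numpy as np
import pytest

from rrband import BandParams, SimScenario, Window, default_band_table, simulate_signal


@pytest.fixture
def band_table():
    return default_band_table()


@pytest.fixture
def default_params():
    return BandParams()


def make_sine_window(freq_hz: float, fs: float = 50.0, duration_s: float = 60.0,
                     amp: float = 1.0, offset: float = 0.0, index: int = 0) -> Window:
    t = np.arange(int(duration_s * fs)) / fs
    return Window(samples=offset + amp * np.sin(2 * np.pi * freq_hz * t),
                  fs=fs, index=index, start_s=index * 60.0)


@pytest.fixture
def sine_window():
    return make_sine_window


@pytest.fixture
def clean_signal():
    def _make(rr_bpm: float, duration_s: float = 300.0, seed: int = 0, **kw):
        return simulate_signal(
            SimScenario(rr_bpm=rr_bpm, duration_s=duration_s, seed=seed, **kw)
        )
    return _make
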