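import numpy as np
import pytest

from prekit.relaxation import DEFAULT_DELAYS, PeakSeries


@pytest.fixture
def delays():
    return np.array(DEFAULT_DELAYS)


@pytest.fixture
def titration_grid():
    """Six-point titration grid at 250 uM visible chain (molar)."""
    return np.array([0.0, 0.25, 0.5, 0.75, 1.0, 1.5]) * 250e-6


def make_decay_series(residue, delays, i0, r2, noise=0.0, rng=None):
    clean = i0 * np.exp(-r2 * np.asarray(delays, float))
    if noise > 0:
        clean = clean * (1.0 + noise * rng.standard_normal(len(delays)))
    return PeakSeries(residue, np.asarray(delays, float), np.clip(clean, 0.0, None))
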