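import numpy as np
import pytest

from hdsemg import (
    ActivationMap,
    ContractionSegment,
    GridGeometry,
    GridRecording,
    SimulationConfig,
    simulate_recording,
)


@pytest.fixture(scope="session")
def geometry() -> GridGeometry:
    """Default study layout: 13x5, one corner missing, 64 electrodes."""
    return GridGeometry()


@pytest.fixture
def make_map():
    """Factory for activation maps on an arbitrary full grid."""

    def _make(values, mask=None, mode="monopolar", window=(0.0, 0.25)):
        values = np.asarray(values, dtype=float)
        if mask is None:
            mask = np.ones_like(values, dtype=bool)
        return ActivationMap(values=values, valid_mask=np.asarray(mask, bool), window=window, mode=mode)

    return _make


@pytest.fixture
def uniform_59_map(geometry, make_map):
    """Uniform single-differential map: 59 valid channels on a 12x5 grid."""
    mask = np.ones((12, 5), dtype=bool)
    mask[0, 0] = False  # pair lost to the missing corner electrode
    return make_map(np.full((12, 5), 0.1) * mask, mask=mask, mode="single_differential")


@pytest.fixture(scope="session")
def default_trial():
    """One simulated trial under the default (study-like) conditions."""
    cfg = SimulationConfig(seed=7)
    rec, truth = simulate_recording(cfg)
    return rec, truth


@pytest.fixture
def constant_recording(geometry):
    """All electrodes carry the same constant 1 mV signal."""

    signals = np.ones((geometry.n_electrodes, 1024))
    return GridRecording(signals=signals, fs_hz=1024.0, geometry=geometry)


@pytest.fixture
def full_segment():
    return ContractionSegment(start_sample=0, end_sample=1024, method="manual")
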