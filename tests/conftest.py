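import numpy as np
import pytest

from cfpipe.electropherogram import Electropherogram


@pytest.fixture
def bp_grid():
    """One-bp grid spanning the instrument's sizing range."""
    return np.arange(35.0, 10381.0, 1.0)


@pytest.fixture
def make_trace(bp_grid):
    """Build an eluate trace from an arbitrary density function or array."""

    def _make(density, *, eluate_index=1, eluate_volume_ul=85.0,
              plasma_volume_ml=3.6, sample_id="S1", qubit=None):
        if callable(density):
            density = np.array([density(x) for x in bp_grid])
        return Electropherogram(
            sample_id=sample_id,
            eluate_index=eluate_index,
            grid=bp_grid.copy(),
            density=np.asarray(density, dtype=float),
            eluate_volume_ul=eluate_volume_ul,
            plasma_volume_ml=plasma_volume_ml,
            qubit_total_ng_per_ml=qubit,
        )

    return _make


@pytest.fixture
def rectangle_trace(make_trace, bp_grid):
    """Density ``height`` on [lo, hi] (inclusive grid points), 0 elsewhere."""

    def _make(lo, hi, height, **kw):
        density = np.where((bp_grid >= lo) & (bp_grid <= hi), height, 0.0)
        return make_trace(density, **kw)

    return _make
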