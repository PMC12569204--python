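import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from methcal.calcium import NormalizedTrace, RawTrace


@pytest.fixture
def worked_dff():
    """10-sample trace with a single clean transient peaking at index 3."""
    return np.array([0, 0, 0.05, 0.6, 0.6, 0.2, 0.05, 0, 0, 0])


@pytest.fixture
def twin_peak_dff():
    """10-sample trace with two local peaks at indices 1 and 4."""
    return np.array([0, 0.5, 0.45, 0.42, 0.5, 0.3, 0.1, 0, 0, 0])


def make_norm(dff, roi_id="roi", interval=1.0):
    dff = np.asarray(dff, dtype=float)
    return NormalizedTrace(roi_id=roi_id, dff=dff, f0=1.0, sampling_interval=interval)


def make_raw(values, roi_id="roi", interval=1.0):
    return RawTrace(roi_id=roi_id, sampling_interval=interval, intensities=np.asarray(values, dtype=float))


@pytest.fixture
def norm_factory():
    return make_norm


@pytest.fixture
def raw_factory():
    return make_raw
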