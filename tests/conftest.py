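import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from famosc.behavior import ChamberGeometry
from famosc.types import TrialLayout, UnitResponse


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def spike_layout():
    return TrialLayout(epoch_length=1.3)


@pytest.fixture
def geometry():
    return ChamberGeometry.three_box()


def make_unit_response(z, bin_s=0.010, unit_id="fixture"):
    """Wrap an explicit z trace (already in z-units) as a UnitResponse."""
    z = np.asarray(z, dtype=float)
    centers = (np.arange(z.size) + 0.5) * bin_s
    return UnitResponse(unit_id, centers, z, baseline_mean_hz=0.0,
                        baseline_sd_hz=1.0, valid=True)
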