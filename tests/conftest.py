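"""Shared fixtures.

The thin-strip simulations (the most expensive fixtures) are session-scoped
and shared between the solver, pacing, post-processing and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from fibrosim.coupling import build_smooth_d
from fibrosim.experiment import default_strip_profile, make_strip_fixture
from fibrosim.grid import GridSpec
from fibrosim.pacing import PacingProtocol
from fibrosim.scar import DiffusionField
from fibrosim.solver import NumericsConfig, simulate

#: measurement column near the far end of the excitable region of the default
#: strip profile (x = 18.125 mm; D just above 0.025 there in every model)
STRIP_FAR_COLUMN = 72
STRIP_PROTOCOL = PacingProtocol(site_center=(2.0, 2.0))


def uniform_strip_model(
    length: float = 25.0, width: float = 2.0, d: float = 0.1, dx: float = 0.25
):
    grid = GridSpec.from_extent(length, width, dx)
    return build_smooth_d(DiffusionField(np.full(grid.shape, d), grid))


@pytest.fixture(scope="session")
def strip_recordings():
    """Thin-strip runs (2.6 s, full dynamic pacing) for the three base models."""
    out = {}
    num = NumericsConfig(duration=2600.0)
    for name in ("ThresholdD", "SmoothD", "ContinuousD"):
        model = make_strip_fixture(default_strip_profile, name)
        out[name] = simulate(model, STRIP_PROTOCOL, num)
    return out


@pytest.fixture(scope="session")
def single_s1_strip_recording():
    """One paced beat on a short uniform strip (planar wave reference)."""
    model = uniform_strip_model()
    proto = PacingProtocol(site_center=(2.0, 1.0), n_s1=1, n_s2=0)
    return simulate(model, proto, NumericsConfig(duration=400.0))
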