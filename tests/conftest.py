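import numpy as np
import pytest

import fpstage as fp
from fpstage.simulate import SimulationParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def template():
    return fp.neutral_template()


@pytest.fixture
def noiseless_params():
    """Factory for zero-noise simulation settings."""

    def make(**overrides):
        defaults = dict(seed=7, noise_sd_px=0.0)
        defaults.update(overrides)
        return SimulationParams(**defaults)

    return make


def run_pipeline(track, windows, scale):
    """Track + windows -> AsymmetryResult, via the public API."""
    bundle = fp.extract_series(track, scale=scale)
    shifts = fp.measure_shifts(bundle, windows)
    return fp.assemble_result(shifts, track.affected_side)
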