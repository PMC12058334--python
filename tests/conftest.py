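"""Shared fixtures: small simulated videos and datasets, built once per session."""

import numpy as np
import pytest

from speckleflow.simulate import (
    SimulationParams, desk_scale_params, make_phantom_dataset, simulate_video,
)


@pytest.fixture(scope="session")
def tiny_params():
    """A 32x32, 96-frame parameter set for fast video-level tests."""
    return desk_scale_params(height=32, width=32, duration=96 / 300, seed=11)


@pytest.fixture(scope="session")
def medium_video(tiny_params):
    """One medium-flow recording at the 3 mm MEDIUM midpoint velocity."""
    from dataclasses import replace
    return simulate_video(replace(tiny_params, velocity=40.5), video_id="med")


@pytest.fixture(scope="session")
def zero_video(tiny_params):
    return simulate_video(tiny_params, video_id="zero")


@pytest.fixture(scope="session")
def small_dataset():
    """A single-cell phantom dataset: 4 conditions x 3 replicates, 96 frames."""
    base = desk_scale_params(height=32, width=32, duration=96 / 300)
    return make_phantom_dataset(grid_spec=[(3.0, 0.0)], seed=5, base_params=base)
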