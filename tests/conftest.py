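import numpy as np
import pytest

from crutchgait import (
    GaitParams,
    RunConfig,
    generate_session,
    match_pattern,
    segment_trajectory,
    three_point_gait,
)


@pytest.fixture(scope="session")
def clean_session():
    """Noise-free 4-cycle left-injured session with its ground truth."""
    params = GaitParams(noise_sigma=0.0)
    traj, gt = generate_session(params, seed=101)
    return traj, gt


@pytest.fixture(scope="session")
def matched_clean(clean_session):
    traj, gt = clean_session
    pattern = three_point_gait("left")
    intervals = segment_trajectory(traj)
    instances, errors = match_pattern(intervals, pattern)
    return traj, gt, pattern, intervals, instances, errors


@pytest.fixture
def run_config():
    return RunConfig()
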