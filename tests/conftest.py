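import numpy as np
import pytest

from cmjkit.kinematics import (
    detect_onset,
    detect_takeoff,
    integrate_motion,
    segment_phases,
)
from cmjkit.synthetic import JumpProfileParams, simulate_trial
from cmjkit.trial_io import compute_body_weight


def analyze(trial, *, min_quiet_sd=0.5, onset_k=5.0, takeoff_threshold=10.0):
    """Run the single-trial chain: body weight -> onset -> take-off ->
    kinematics -> segmentation.  Shared by most integration-style tests."""
    bw = compute_body_weight(trial)
    onset = detect_onset(
        trial, bw.body_weight_N, max(bw.quiet_sd_N, min_quiet_sd), k=onset_k
    )
    takeoff = detect_takeoff(trial, onset, threshold_N=takeoff_threshold)
    kin = integrate_motion(trial, bw.body_mass_kg, onset)
    seg = segment_phases(kin, onset, takeoff)
    return bw, kin, seg


@pytest.fixture(scope="session")
def baseline_params():
    return JumpProfileParams(noise_sd=0.0)


@pytest.fixture(scope="session")
def baseline_trial(baseline_params):
    """One noise-free trial at the default (baseline athlete) parameters,
    with its generating ground truth."""
    return simulate_trial(baseline_params)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
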