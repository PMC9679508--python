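"""Shared fixtures: small synthetic trials reused across test modules."""

import dataclasses

import numpy as np
import pytest

from gaitemg.kinematics import detect_hindlimb_impacts
from gaitemg.synthetic import (noiseless, scenario_preset, simulate_static,
                               simulate_trial)


@pytest.fixture(scope="session")
def baseline_noiseless():
    """Symmetric trot, no kinematic noise / EMG floor, 20 strides."""
    scenario = noiseless(scenario_preset("baseline"))
    trial, truth = simulate_trial(scenario)
    return scenario, trial, truth


@pytest.fixture(scope="session")
def ifl_noiseless():
    scenario = noiseless(scenario_preset("iFL_moderate"))
    trial, truth = simulate_trial(scenario)
    return scenario, trial, truth


@pytest.fixture(scope="session")
def ihl_noiseless():
    scenario = noiseless(scenario_preset("iHL_moderate"))
    trial, truth = simulate_trial(scenario)
    return scenario, trial, truth


@pytest.fixture(scope="session")
def baseline_events(baseline_noiseless):
    _, trial, _ = baseline_noiseless
    return detect_hindlimb_impacts(trial)


@pytest.fixture(scope="session")
def small_trial():
    """A short noisy trial for I/O and plumbing tests."""
    scenario = dataclasses.replace(scenario_preset("baseline"), n_strides=4,
                                   seed=42)
    trial, truth = simulate_trial(scenario)
    return trial, truth


@pytest.fixture(scope="session")
def static_trial():
    return simulate_static(scenario_preset("baseline"))


def match_truth_window(det_window, truth_windows):
    """Index of the ground-truth stride window matching a detected one."""
    starts = np.asarray([w[0] for w in truth_windows])
    return int(np.argmin(np.abs(starts - det_window[0])))
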