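"""Shared fixtures: simulated sessions reused across test modules."""

import numpy as np
import pytest

from wheelperf import (
    SimulationParams,
    simulate_coastdown_pair,
    simulate_course,
    simulate_linear_sprint,
)
from wheelperf.coastdown import process_trial, solve_coefficients
from wheelperf.params import coastdown_course, illinois_course, spider_course


@pytest.fixture(scope="session")
def sprint_noiseless():
    params = SimulationParams(gyro_noise_sd=0.0, seed=7)
    truth, imu, erg = simulate_linear_sprint(params)
    return params, truth, imu, erg


@pytest.fixture(scope="session")
def sprint_noisy():
    params = SimulationParams(gyro_noise_sd=1.0, seed=7)
    truth, imu, erg = simulate_linear_sprint(params)
    return params, truth, imu, erg


@pytest.fixture(scope="session")
def coastdown_noiseless():
    params = SimulationParams(gyro_noise_sd=0.0, seed=11, course=coastdown_course())
    return params, simulate_coastdown_pair(params)


@pytest.fixture(scope="session")
def coast_model_noiseless(coastdown_noiseless):
    params, trials = coastdown_noiseless
    processed = [
        process_trial(imu, "upright" if k < 2 else "forward", params.m_total, filter_mode="none")
        for k, (_, imu) in enumerate(trials)
    ]
    return solve_coefficients(processed)


@pytest.fixture(scope="session")
def illinois_noiseless():
    params = SimulationParams(gyro_noise_sd=0.0, seed=3, course=illinois_course())
    truth, imu = simulate_course(params)
    return params, truth, imu


@pytest.fixture(scope="session")
def spider_noiseless():
    params = SimulationParams(gyro_noise_sd=0.0, seed=3, course=spider_course())
    truth, imu = simulate_course(params)
    return params, truth, imu


def truth_on(t_target: np.ndarray, truth_t: np.ndarray, series: np.ndarray) -> np.ndarray:
    """Interpolate a ground-truth series onto a sensor time base."""
    return np.interp(t_target, truth_t, series)
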