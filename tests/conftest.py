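"""Shared fixtures for the afmbone test suite."""
import numpy as np
import pytest

from afmbone import CantileverCalibration, PullScenario

SOFT_K = 0.006      # N/m
STIFF_K = 0.18      # N/m
INVOLS = 50e-9      # m/V


@pytest.fixture
def calib():
    """Soft-lever calibration used by most force-curve tests."""
    return CantileverCalibration(invols=INVOLS, spring_constant=SOFT_K)


@pytest.fixture
def stiff_calib():
    return CantileverCalibration(invols=INVOLS, spring_constant=STIFF_K)


@pytest.fixture
def scenario():
    """Default three-event pull scenario with its default noise."""
    return PullScenario()


@pytest.fixture
def clean_scenario():
    return PullScenario(baseline_noise_sd=0.0)


@pytest.fixture
def triangle_scenario():
    """Single triangular pulse: depth 1.0 nN, base 100 nm -> 5.0e-17 J."""
    return PullScenario(rupture_events=[(100e-9, 1.0e-9)], shape="triangle",
                        baseline_noise_sd=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def random_events(rng, n_max=5, s_min=50e-9, s_max=2.5e-6,
                  peak_lo=0.1e-9, peak_hi=2e-9, min_gap=5e-9):
    """Random strictly-increasing rupture events for property tests."""
    n = int(rng.integers(1, n_max))
    pos = np.sort(rng.uniform(s_min, s_max, n))
    while n > 1 and np.any(np.diff(pos) < min_gap):
        pos = np.sort(rng.uniform(s_min, s_max, n))
    return [(float(p), float(rng.uniform(peak_lo, peak_hi))) for p in pos]
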