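"""Shared fixtures: one calibration and one coverage sweep reused suite-wide.

The expensive artefacts — the calibrated onset hazards and the full
47/65/80% coverage sweep at 10 replications — are computed once per session
and shared, so the deeper scenario-level tests all interrogate the same
runs.
"""

from __future__ import annotations

import numpy as np
import pytest

from stepcare import DiseaseParams
from stepcare.calibrate import CalibratedIncidence, calibrate_incidence
from stepcare.experiment import ScenarioConfig, run_scenario

BASE_SEED = 1
COVERAGE_LEVELS = (0.47, 0.65, 0.80)


@pytest.fixture(scope="session")
def default_params() -> DiseaseParams:
    return DiseaseParams()


@pytest.fixture(scope="session")
def small_params() -> DiseaseParams:
    """A desk-sized population for fast structural tests."""
    return DiseaseParams(n0=500, horizon_weeks=60)


@pytest.fixture(scope="session")
def calibration(default_params) -> CalibratedIncidence:
    """Onset hazards calibrated at the baseline coverage level."""
    return calibrate_incidence(default_params, coverage=0.47, seed=BASE_SEED)


@pytest.fixture(scope="session")
def sweep(default_params, calibration):
    """Full coverage sweep (47/65/80%), 10 replications each, base seed 1."""
    config = ScenarioConfig(coverage_levels=COVERAGE_LEVELS, base_seed=BASE_SEED)
    return run_scenario(config, default_params, calibration=calibration)


@pytest.fixture(scope="session")
def baseline_runs(sweep):
    """The ten baseline-coverage replications from the session sweep."""
    return sweep.runs[0.47]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
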