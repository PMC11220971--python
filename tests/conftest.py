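import numpy as np
import pandas as pd
import pytest

from crtraj.cohort import LongitudinalCohort
from crtraj.lcmm import ModelSpec, fit
from crtraj.links import build_link
from crtraj.simulate import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def separated_cohort():
    """Well-separated 3-class cohort reused across recovery-style tests."""
    cfg = SyntheticConfig.well_separated(n_subjects=150, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """Small default-style cohort (no distortion) for fast fitting tests."""
    cfg = SyntheticConfig(n_subjects=60, seed=7, distortion=0.0)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def fitted_g1(small_cohort):
    cohort, _ = small_cohort
    return fit(cohort, ModelSpec(1, build_link("linear")))


@pytest.fixture()
def tiny_cohort():
    """Three handmade subjects with irregular visit counts."""
    visits = pd.DataFrame({
        "subject_id": ["a", "a", "b", "b", "b", "c", "c"],
        "time": [0.0, 1.0, 0.0, 1.1, 2.0, 0.0, 0.9],
        "outcome": [0.2, 0.1, -0.5, -0.6, -0.9, 1.0, 1.1],
    })
    baseline = pd.DataFrame({
        "subject_id": ["a", "b", "c"],
        "baseline_age": [70.0, 75.0, 68.0],
        "sex": [1.0, 0.0, 1.0],
        "abeta": [1.1, 1.3, 1.0],
        "tau_ec": [1.2, 1.5, 1.1],
        "adj_hv": [7600.0, 7000.0, 7900.0],
    }).set_index("subject_id")
    return LongitudinalCohort(visits, baseline)
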