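import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rehabscore as rs
from rehabscore.fma_map import records_from_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

COHORT_SEED = 1
COHORT_N = 120


@pytest.fixture(scope="session")
def battery():
    return rs.default_battery()


@pytest.fixture(scope="session")
def template_recording():
    """Clinician's standard execution of one shoulder-flexion task."""
    return rs.generate_template("u01_shoulder_flexion", duration=4.0, seed=1)


@pytest.fixture(scope="session")
def movement_template():
    return rs.build_template("u01_shoulder_flexion", duration=4.0, seed=1)


@pytest.fixture(scope="session")
def cohort120():
    """Study-sized cohort under the default generating conditions."""
    return rs.generate_cohort(COHORT_N, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def scored_cohort(cohort120):
    """(records, scores, templates) for the study-sized cohort."""
    templates = rs.build_battery_templates(seed=COHORT_SEED)
    scores, templates = rs.score_cohort(cohort120, templates)
    records = records_from_cohort(cohort120, scores)
    return records, scores, templates


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
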