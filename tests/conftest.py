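import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from clinstage import cohort_from_confusion_fixture, run_stepwise
from clinstage.data import overall_fixture_spec

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table2_cohort():
    """270-patient cohort rebuilt from the overall derivation table's cells."""
    return cohort_from_confusion_fixture(overall_fixture_spec())


@pytest.fixture(scope="session")
def table2_results(table2_cohort):
    """Stepwise fit with the derivation cutoffs (192, 135) forced."""
    return run_stepwise(table2_cohort, forced_cutoffs={3: 192, 2: 135})


@pytest.fixture
def rng():
    return np.random.default_rng(20259)
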