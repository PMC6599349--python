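import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from honosnet.data import CohortTable, ItemProfile, PatientRecord  # noqa: E402
from honosnet.simulate import simulate_study_cohort  # noqa: E402


def make_profile(*scores):
    base = [0] * 12
    for i, s in enumerate(scores):
        base[i] = s
    return ItemProfile(tuple(base))


@pytest.fixture(scope="session")
def study_cohort():
    """Default-condition synthetic cohort (n=137, sparse/dense truths)."""
    cohort, truth = simulate_study_cohort(seed=123)
    return cohort, truth


@pytest.fixture()
def tiny_cohort():
    """Hand-built 4-patient cohort with a mix of severities."""
    records = (
        PatientRecord("a", 30, "female", make_profile(3, 1), make_profile(1, 1), 400.0),
        PatientRecord("b", 45, "male", make_profile(2, 2), make_profile(4, 0), 380.0),
        PatientRecord("c", 52, "female", make_profile(4), make_profile(0), 500.0),
        PatientRecord("d", 28, "male", make_profile(1), make_profile(2), 365.0),
    )
    return CohortTable(records)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
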