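import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scenario1():
    """A 40-patient zero-covariance cohort with truth labels."""
    from phasemix import make_scenario, simulate_cohort
    return simulate_cohort(make_scenario(1, n_patients=40, seed=202))


@pytest.fixture(scope="session")
def small_scenario1_fit(small_scenario1):
    from phasemix import EMOptions, fit_em
    return fit_em(small_scenario1.cohort, EMOptions(max_iter=300, tol=1e-6))


@pytest.fixture(scope="session")
def mono_cohort():
    """Straight-line cohort (no bi-phasic patients) with noise."""
    from phasemix import Cohort, PatientSeries
    rng = np.random.default_rng(77)
    patients = []
    times = 21.0 * np.arange(18)
    for i in range(30):
        y = 90.0 - 0.25 * times + rng.normal(0, 5, size=18)
        patients.append(PatientSeries(f"m{i}", times, y))
    return Cohort(patients)
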