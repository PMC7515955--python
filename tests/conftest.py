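import pytest

from petdosim.kinetics import subject_residence_times
from petdosim.pipeline import simulate_cohort


@pytest.fixture(scope="session")
def cohort_cv5():
    """24 simulated subjects (12 fed, 12 fasted) at 5% ROI noise, seed 1."""
    return simulate_cohort(n_fed=12, n_fasted=12, seed=1, noise_cv=0.05)


@pytest.fixture(scope="session")
def cohort_tables(cohort_cv5):
    return [subject_residence_times(ds) for ds in cohort_cv5]
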