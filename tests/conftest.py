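import numpy as np
import pytest

from survinterim.study_design import PatientCohort, StudyDesign, SurvivalSnapshot


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)


@pytest.fixture
def default_design():
    return StudyDesign(n_patients=50, l1_intended=60.0, l2=60.0, m1=2, m2=2)


@pytest.fixture
def small_cohort(rng):
    n = 40
    return PatientCohort(
        arrivals=rng.uniform(0, 60, n),
        survival=rng.exponential(60, n),
        short_survivor=rng.random(n) < 0.5,
    )


def make_snapshot(times, events):
    """Snapshot wrapper around plain observed-time/event arrays."""
    times = np.asarray(times, dtype=float)
    return SurvivalSnapshot(
        analysis_time=float(times.max() + 1),
        patient_index=np.arange(len(times)),
        observed_time=times,
        event=np.asarray(events, dtype=np.int8),
    )


@pytest.fixture
def eight_patient_snapshot():
    """Times 1..8, all events: the hand-checkable Cox fixture."""
    return make_snapshot(np.arange(1.0, 9.0), np.ones(8))
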