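import numpy as np
import pytest

from pestmle import SessionLog, StudyConfig, analyze_study, simulate_study

STUDY_SEED = 20260923


@pytest.fixture(scope="session")
def default_study():
    """A seeded default-condition study: 30 subjects x 4 sessions x 2 targets
    (240 sessions), amplitude response path, standard drift."""
    return simulate_study(StudyConfig(n_subjects=30, seed=STUDY_SEED))


@pytest.fixture(scope="session")
def default_report(default_study):
    return analyze_study(default_study)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_log(estimates, intensities=None, outcomes=None, config=None):
    """Build a SessionLog from an estimate series (intensities default to the
    rounded estimates, outcomes alternate)."""
    from pestmle import SessionConfig, TrialRecord
    from pestmle.hunting import round_half_away

    estimates = list(map(float, estimates))
    n = len(estimates)
    if intensities is None:
        intensities = [min(max(round_half_away(e), 1.0), 100.0) for e in estimates]
    if outcomes is None:
        outcomes = [bool(i % 2) for i in range(n)]
    trials = [
        TrialRecord(intensity=float(x), outcome=bool(y))
        for x, y in zip(intensities, outcomes)
    ]
    return SessionLog(
        trials=trials, estimates=estimates, config=config or SessionConfig()
    )
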