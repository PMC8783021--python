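"""Shared fixtures and hypothesis configuration for the test suite."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def toy_cohort():
    """Deterministic 8-subject cohort (4 control, 4 treatment)."""
    rng = np.random.default_rng(11)
    n = 8
    return pd.DataFrame(
        {
            "subject": [f"sub-{i:03d}" for i in range(1, n + 1)],
            "group": [0, 0, 0, 0, 1, 1, 1, 1],
            "age": rng.uniform(18, 35, n),
            "sex": [0, 1, 0, 1, 1, 0, 1, 0],
        }
    )


def make_trials(values_by_subject_session, n_trials=None):
    """Build a TrialSeries table from {subject: {session: [trial values]}}."""
    from npcpipe.behavior import TrialSeries

    recs = []
    for subj, sessions in values_by_subject_session.items():
        for sess, vals in sessions.items():
            for t, v in enumerate(vals, start=1):
                recs.append((subj, sess, t, float(v)))
    return TrialSeries(
        pd.DataFrame(recs, columns=["subject", "session", "trial", "bal"])
    )


@pytest.fixture
def constant_trials():
    """Two subjects, three sessions, all trials at 10 s."""
    return make_trials(
        {
            "s1": {1: [10] * 5, 2: [10] * 5, 3: [10] * 5},
            "s2": {1: [10] * 5, 2: [10] * 5, 3: [10] * 5},
        }
    )
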