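import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import crowdcontext as cc

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cfg():
    """A scaled-down study: 2 studies x 4 tasks x 8 groups."""
    return cc.default_config(n_studies=2, tasks_per_study=4, groups_per_study=8,
                             group_size=(4, 6))


@pytest.fixture(scope="session")
def small_corpus(small_cfg):
    return cc.generate_study(small_cfg, seed=11)


@pytest.fixture(scope="session")
def small_outcomes(small_corpus):
    trials, _ = small_corpus
    trials = cc.filter_positive_tasks(cc.validate_trials(trials))
    out = cc.attach_task_features(trials, cc.summarize_trials(trials))
    return cc.standardize_errors(out)


def make_trials(rows):
    """Build a trial table from (study, task, group, subject, stage, est, truth, cond)."""
    return pd.DataFrame(
        rows,
        columns=["study_id", "task_id", "group_id", "subject_id",
                 "stage", "estimate", "truth", "condition"],
    )


def trial_rows(study, task, group, initial, revised, truth, condition="interactive"):
    rows = []
    for k, (a0, a1) in enumerate(zip(initial, revised)):
        sid = f"{group}p{k}"
        rows.append((study, task, group, sid, "initial", a0, truth, condition))
        rows.append((study, task, group, sid, "revised", a1, truth, condition))
    return rows


@pytest.fixture
def toy_trials():
    """Three tasks; the hand-computable outcomes used across pipeline tests."""
    rows = []
    rows += trial_rows("s1", "t1", "g1", [10, 20, 30], [18, 20, 22], truth=21)
    rows += trial_rows("s1", "t1", "g2", [1, 3], [2, 2], truth=21)
    rows += trial_rows("s1", "t2", "g1", [100], [10], truth=12)
    rows += trial_rows("s1", "t3", "g3", [5, -5, 6], [5, -5, 6], truth=4, condition="control")
    return make_trials(rows)
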