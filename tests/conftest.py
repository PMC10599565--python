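import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import medsurv as ms

settings.register_profile("default", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("default")


@pytest.fixture
def toy_roles():
    return ms.VariableRoles(
        sex="sex", age="age_t1", jobstrain_t1="jobstrain_t1",
        confounders_t1=("conf_t1",), confounders_t2=("conf_t2",),
    )


def build_cohort(n=30, seed=0, roles=None, **columns):
    """Small hand-controllable cohort; unspecified columns get simple fills."""
    rng = np.random.default_rng(seed)
    levels = np.array(["high", "medium", "low"], dtype=object)
    df = pd.DataFrame({
        "subject_id": [f"s{i:04d}" for i in range(n)],
        "sex": rng.integers(0, 2, n),
        "age_t1": rng.normal(41, 8, n).round(1),
        "conf_t1": rng.integers(0, 2, n),
        "jobstrain_t1": rng.integers(0, 2, n),
        "conf_t2": rng.integers(0, 2, n),
        "ses": levels[np.arange(n) % 3],
        "mediator_t2": rng.integers(0, 2, n),
        "followup_time": rng.uniform(30, 1095, n).round(1),
        "event_status": np.where(rng.uniform(size=n) < 0.4, "depression",
                                 "admin_censor"),
    })
    for k, v in columns.items():
        df[k] = v
    roles = roles or ms.VariableRoles(
        sex="sex", age="age_t1", jobstrain_t1="jobstrain_t1",
        confounders_t1=("conf_t1",), confounders_t2=("conf_t2",),
    )
    return ms.CohortTable(df, roles)


@pytest.fixture
def cohort_factory():
    return build_cohort
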