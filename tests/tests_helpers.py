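"""Shared helpers for building small, fully controlled cohorts in tests."""

import numpy as np
import pandas as pd

import medsurv as ms

LEVELS = np.array(["high", "medium", "low"], dtype=object)


def simple_cohort(n=None, roles=None, **columns):
    """A deterministic cohort with any column overridden by keyword."""
    if n is None:
        n = len(next(iter(columns.values()))) if columns else 12
    base = {
        "subject_id": [f"s{i:04d}" for i in range(n)],
        "sex": (np.arange(n) % 2),
        "age_t1": np.linspace(30, 55, n).round(1),
        "conf_t1": np.zeros(n, dtype=int),
        "jobstrain_t1": np.zeros(n, dtype=int),
        "conf_t2": np.zeros(n, dtype=int),
        "ses": LEVELS[np.arange(n) % 3],
        "mediator_t2": (np.arange(n) % 4 == 0).astype(int),
        "followup_time": np.linspace(100, 1095, n).round(1),
        "event_status": np.where(np.arange(n) % 3 == 0, "depression",
                                 "admin_censor"),
    }
    for k, v in columns.items():
        base[k] = np.asarray(v)
    df = pd.DataFrame(base)
    if roles is None:
        roles = ms.VariableRoles(
            sex="sex", age="age_t1", jobstrain_t1="jobstrain_t1",
            confounders_t1=("conf_t1",), confounders_t2=("conf_t2",),
            censored_pre_t2="censored_pre_t2" if "censored_pre_t2" in base else None,
        )
    return ms.CohortTable(df, roles)
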