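"""Marginal structural models and the interventional effect combination."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import medsurv as ms
from medsurv.interventional_mediation import MediatorMSM, OutcomeMSM
from tests_helpers import simple_cohort


def _survival_cohort(n=400, seed=0, weights_rng=None):
    rng = np.random.default_rng(seed)
    levels = np.array(["high", "medium", "low"], dtype=object)
    a = rng.choice(3, n)
    m = rng.integers(0, 2, n)
    eta = 0.3 * (a == 1) + 0.6 * (a == 2) + 0.4 * m
    t = rng.exponential(400 / np.exp(eta))
    event = t < 1095
    return simple_cohort(
        n=n, ses=levels[a], mediator_t2=m,
        followup_time=np.minimum(t, 1095).round(1) + 0.1,
        event_status=np.where(event, "depression", "admin_censor"),
    )


def _unit_weights(cohort):
    return pd.Series(
        1.0, index=pd.Index(cohort.subject_ids, name="subject_id"))


# ---------------------------------------------------------------------------
# outcome MSM


def test_integer_weights_equal_duplicated_rows():
    cohort = _survival_cohort()
    rng = np.random.default_rng(3)
    k = rng.integers(1, 4, len(cohort))
    w = _unit_weights(cohort) * k
    fit_w = ms.fit_outcome_msm(cohort, w, ties="breslow")
    rep = cohort.df.loc[cohort.df.index.repeat(k)].reset_index(drop=True)
    rep["subject_id"] = [f"d{i}" for i in range(len(rep))]
    dup = ms.CohortTable(rep, cohort.roles)
    fit_d = ms.fit_outcome_msm(dup, _unit_weights(dup), ties="breslow")
    for lvl in ("medium", "low"):
        assert fit_w.beta_exposure[lvl] == pytest.approx(
            fit_d.beta_exposure[lvl], abs=1e-8)
    assert fit_w.beta_mediator == pytest.approx(fit_d.beta_mediator, abs=1e-8)


def test_unit_weights_match_independent_cox_fit():
    from lifelines import CoxPHFitter

    cohort = _survival_cohort(seed=5)
    fit = ms.fit_outcome_msm(cohort, _unit_weights(cohort))
    df = pd.DataFrame({
        "medium": (cohort.df.ses == "medium").astype(float),
        "low": (cohort.df.ses == "low").astype(float),
        "m": cohort.df.mediator_t2.astype(float),
        "T": cohort.df.followup_time,
        "E": (cohort.df.event_status == "depression").astype(int),
    })
    ref = CoxPHFitter().fit(df, "T", "E")
    assert fit.beta_exposure["medium"] == pytest.approx(ref.params_["medium"], abs=1e-5)
    assert fit.beta_exposure["low"] == pytest.approx(ref.params_["low"], abs=1e-5)
    assert fit.beta_mediator == pytest.approx(ref.params_["m"], abs=1e-5)
    assert fit.n_events == int(df.E.sum())


def test_outcome_msm_requires_events_per_level():
    cohort = _survival_cohort(n=60, seed=2)
    df = cohort.df.copy()
    df.loc[df.ses == "low", "event_status"] = "admin_censor"
    broken = ms.CohortTable(df, cohort.roles)
    with pytest.raises(ms.ValidationError, match="low"):
        ms.fit_outcome_msm(broken, _unit_weights(broken))
    df["event_status"] = "admin_censor"
    none = ms.CohortTable(df, cohort.roles)
    with pytest.raises(ms.ValidationError, match="no depression events"):
        ms.fit_outcome_msm(none, _unit_weights(none))


# ---------------------------------------------------------------------------
# mediator MSM


def test_saturated_fit_equals_level_prevalences():
    m = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0] + [1, 1, 0, 0, 0, 0, 0, 0, 0, 0] \
        + [1, 0, 0, 0, 0, 0, 0, 0, 0, 0]
    ses = ["high"] * 10 + ["medium"] * 10 + ["low"] * 10
    cohort = simple_cohort(ses=ses, mediator_t2=m)
    fit = ms.fit_mediator_msm(cohort, _unit_weights(cohort))
    assert fit.prevalence == pytest.approx(
        {"high": 0.3, "medium": 0.2, "low": 0.1})
    assert fit.coefficients["intercept"] == pytest.approx(math.log(0.3 / 0.7))


def test_weighted_fit_matches_weighted_logistic_regression():
    import statsmodels.api as sm

    rng = np.random.default_rng(11)
    n = 20
    cohort = simple_cohort(n=n, mediator_t2=rng.integers(0, 2, n))
    w = pd.Series(rng.uniform(0.5, 3.0, n),
                  index=pd.Index(cohort.subject_ids, name="subject_id"))
    fit = ms.fit_mediator_msm(cohort, w)
    X = np.column_stack([
        np.ones(n),
        (cohort.df.ses == "medium").astype(float),
        (cohort.df.ses == "low").astype(float),
    ])
    ref = sm.GLM(cohort.df.mediator_t2.to_numpy(), X,
                 family=sm.families.Binomial(), freq_weights=w.to_numpy()).fit()
    from scipy.special import expit

    assert fit.prevalence["high"] == pytest.approx(expit(ref.params[0]), abs=1e-10)
    assert fit.prevalence["medium"] == pytest.approx(
        expit(ref.params[0] + ref.params[1]), abs=1e-10)
    assert fit.prevalence["low"] == pytest.approx(
        expit(ref.params[0] + ref.params[2]), abs=1e-10)


def test_empty_or_constant_level_errors():
    cohort = simple_cohort(ses=["high"] * 6 + ["medium"] * 6,
                           mediator_t2=[0, 1] * 6)
    with pytest.raises(ms.ValidationError):
        ms.fit_mediator_msm(cohort, _unit_weights(cohort))
    flat = simple_cohort(mediator_t2=[0] * 12)
    with pytest.raises(ms.SeparationError):
        ms.fit_mediator_msm(flat, _unit_weights(flat))


# ---------------------------------------------------------------------------
# effect combination


def _msm_pair(beta_exposure, beta_mediator, prevalence):
    out = OutcomeMSM(beta_exposure=beta_exposure, beta_mediator=beta_mediator,
                     reference="high", n=100, n_events=50, converged=True,
                     ties="efron", grad_norm=0.0)
    med = MediatorMSM(prevalence=prevalence, coefficients={}, reference="high",
                      n=100)
    return out, med


def test_null_mediator_coefficient_gives_unit_indirect_effects():
    out, med = _msm_pair({"medium": 0.3, "low": 0.5}, 0.0,
                         {"high": 0.1, "medium": 0.3, "low": 0.5})
    eff = ms.interventional_effects(out, med)
    for lvl in ("medium", "low"):
        c = eff.contrasts[lvl]
        assert c.hr_iie == pytest.approx(1.0, abs=1e-15)
        assert c.hr_total == pytest.approx(c.hr_ide, abs=1e-15)


def test_indirect_effect_closed_form():
    out, med = _msm_pair({"low": 0.0}, math.log(2),
                         {"high": 0.25, "low": 0.5})
    c = ms.interventional_effects(out, med).contrasts["low"]
    assert c.hr_iie == pytest.approx(1.2, abs=1e-12)
    assert c.hr_total == pytest.approx(1.2, abs=1e-12)
    assert c.mediated_fraction == pytest.approx(100.0)


def test_equal_prevalences_give_unit_indirect_effect():
    out, med = _msm_pair({"low": 0.4}, 0.7, {"high": 0.2, "low": 0.2})
    assert ms.interventional_effects(out, med).contrasts["low"].hr_iie == 1.0


def test_mismatched_reference_errors():
    out, med = _msm_pair({"low": 0.4}, 0.7, {"high": 0.2, "low": 0.2})
    with pytest.raises(ms.ValidationError, match="reference"):
        ms.interventional_effects(out, med, reference="low")


@given(st.floats(0.2, 5), st.floats(0.2, 5), st.floats(-1, 1),
       st.floats(0.05, 0.95), st.floats(0.05, 0.95))
def test_decomposition_identity_holds_for_any_fit(b1, b2, bm, p_r, p_a):
    out, med = _msm_pair({"medium": math.log(b1), "low": math.log(b2)}, bm,
                         {"high": p_r, "medium": p_a, "low": p_a})
    eff = ms.interventional_effects(out, med)
    for c in eff.contrasts.values():
        assert c.hr_total == pytest.approx(c.hr_ide * c.hr_iie, abs=1e-10)


# ---------------------------------------------------------------------------
# mediated fraction


@pytest.mark.parametrize("ide,iie,expected", [
    (1.637, 1.010, "2.5"),
    (2.725, 1.041, "6.1"),
    (1.374, 1.019, "6.5"),
    (1.523, 1.042, "11"),
])
def test_mediated_fraction_reproduces_table_cells(ide, iie, expected):
    pm = ms.mediated_fraction(ide, iie)
    assert ms.format_mediated_fraction(pm) == expected


def test_unit_indirect_effect_mediates_nothing():
    assert ms.mediated_fraction(1.8, 1.0) == 0.0


def test_null_direct_effect_mediates_everything():
    assert ms.mediated_fraction(1.0, 1.5) == pytest.approx(100.0)


def test_opposite_pulls_are_undefined():
    assert ms.mediated_fraction(1.5, 0.96) is None
    assert ms.format_mediated_fraction(None) == "-"


def test_null_total_effect_is_undefined():
    assert ms.mediated_fraction(2.0, 0.5) is None


def test_nonpositive_inputs_error():
    with pytest.raises(ValueError):
        ms.mediated_fraction(-1.0, 1.1)
    with pytest.raises(ValueError):
        ms.mediated_fraction(1.1, 0.0)
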