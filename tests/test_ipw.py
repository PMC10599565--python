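"""Inverse-probability weight families and their combination."""

import math

import numpy as np
import pandas as pd
import pytest

import medsurv as ms
from tests_helpers import simple_cohort


def test_exposure_weights_are_inverse_marginal_shares():
    # level shares (0.5, 0.3, 0.2) -> weights 2, 10/3, 5
    cohort = simple_cohort(ses=["high"] * 5 + ["medium"] * 3 + ["low"] * 2)
    w = ms.fit_exposure_weights(cohort, covariates=(), sex_handling="none")
    arr = w.weights.to_numpy()
    assert np.allclose(arr[:5], 2.0, atol=1e-8)
    assert np.allclose(arr[5:8], 10 / 3, atol=1e-8)
    assert np.allclose(arr[8:], 5.0, atol=1e-8)


def test_exposure_weights_match_hand_counted_cell_shares():
    # 12 subjects, binary covariate; saturated fit reproduces cell frequencies
    L = [0] * 6 + [1] * 6
    ses = ["high", "high", "high", "medium", "medium", "low",
           "high", "medium", "low", "low", "low", "medium"]
    cohort = simple_cohort(ses=ses, conf_t1=L)
    w = ms.fit_exposure_weights(cohort, covariates=("conf_t1",), sex_handling="none")
    cells = pd.DataFrame({"L": L, "A": ses})
    for i in range(12):
        share = ((cells.L == L[i]) & (cells.A == ses[i])).sum() / (cells.L == L[i]).sum()
        assert w.weights.iloc[i] == pytest.approx(1 / share, abs=1e-7)


def test_unstabilized_mean_exposure_weight_is_the_level_count():
    d = ms.SimulationDesign(n=10000)
    cohort = ms.generate_cohort(d, seed=4)
    w = ms.fit_exposure_weights(cohort, covariates=("age",), sex_handling="adjust")
    arr = w.weights.to_numpy()
    # E[1/P(A|L)] = K; Monte-Carlo tolerance from the empirical spread
    assert abs(arr.mean() - 3.0) < 3 * arr.std() / math.sqrt(len(arr))


def test_exposure_weights_require_all_levels():
    cohort = simple_cohort(ses=["high"] * 6 + ["medium"] * 6)
    with pytest.raises(ms.ValidationError, match="empty exposure level"):
        ms.fit_exposure_weights(cohort, covariates=(), sex_handling="none")


def test_mediator_weights_inverse_marginal_and_stabilized_mean():
    # prevalence 1/4 in every level -> weights 4 and 4/3
    m = [1, 0, 0, 0] * 3
    ses = (["high"] * 4 + ["medium"] * 4 + ["low"] * 4)
    cohort = simple_cohort(ses=ses, mediator_t2=m)
    w = ms.fit_mediator_weights(cohort, covariates=())
    expected = np.where(np.array(m) == 1, 4.0, 4 / 3)
    assert np.allclose(w.weights.to_numpy(), expected, atol=1e-7)
    ws = ms.fit_mediator_weights(cohort, covariates=(), stabilized=True)
    assert ws.weights.mean() == pytest.approx(1.0, abs=1e-6)


def test_unstabilized_mean_mediator_weight_is_two():
    cohort = ms.generate_cohort(ms.SimulationDesign(n=10000), seed=6)
    w = ms.fit_mediator_weights(cohort)
    arr = w.weights.to_numpy()
    assert abs(arr.mean() - 2.0) < 3 * arr.std() / math.sqrt(len(arr))


def test_mediator_separation_is_reported():
    m = [0, 0, 0, 0] + [1, 0, 1, 0] + [1, 1, 0, 0]
    ses = ["high"] * 4 + ["medium"] * 4 + ["low"] * 4
    cohort = simple_cohort(ses=ses, mediator_t2=m)
    with pytest.raises(ms.SeparationError):
        ms.fit_mediator_weights(cohort, covariates=())


# ---------------------------------------------------------------------------
# censoring weights


def test_no_censoring_gives_unit_weights():
    cohort = simple_cohort(censored_pre_t2=[0] * 12)
    w = ms.fit_censoring_weights(cohort, covariates=(), sex_handling="none")
    assert np.allclose(w.weights.to_numpy(), 1.0)
    assert len(w.weights) == 12


def test_half_censoring_doubles_the_weights():
    cohort = simple_cohort(censored_pre_t2=[0, 1] * 6)
    w = ms.fit_censoring_weights(cohort, covariates=(), sex_handling="none")
    assert len(w.weights) == 6
    assert np.allclose(w.weights.to_numpy(), 2.0, atol=1e-7)


def test_covariate_dependent_censoring_matches_cell_retention():
    # retention 3/4 when L=0 and 1/2 when L=1
    L = [0] * 8 + [1] * 8
    cen = [0, 0, 0, 1, 0, 0, 0, 1] + [0, 1] * 4
    cohort = simple_cohort(n=16, conf_t1=L, censored_pre_t2=cen)
    w = ms.fit_censoring_weights(cohort, covariates=("conf_t1",),
                                 sex_handling="none")
    got = w.weights.to_numpy()
    expect = np.where(np.array(L)[np.array(cen) == 0] == 0, 4 / 3, 2.0)
    assert np.allclose(got, expect, atol=1e-7)


def test_degenerate_censoring_errors():
    cohort = simple_cohort(censored_pre_t2=[1] * 12)
    with pytest.raises(ms.ValidationError, match="all subjects censored"):
        ms.fit_censoring_weights(cohort, covariates=(), sex_handling="none")
    clean = simple_cohort(censored_pre_t2=[0] * 12)
    with pytest.raises(ms.ValidationError, match="degenerate"):
        ms.fit_censoring_weights(clean, covariates=(), sex_handling="none",
                                 stabilized=True)


# ---------------------------------------------------------------------------
# combination and truncation


def _unit_series(n):
    return pd.Series(1.0, index=pd.Index([f"s{i:04d}" for i in range(n)],
                                         name="subject_id"))


def test_combining_unit_factors_gives_unit_products():
    e = m = c = _unit_series(5)
    ws = ms.combine_weights(e, m, c)
    assert np.allclose(ws.combined_outcome_w, 1.0)
    assert np.allclose(ws.combined_mediator_w, 1.0)
    assert ws.n_truncated == 0


def test_combined_weights_are_elementwise_products():
    idx = _unit_series(5).index
    e = pd.Series([1.0, 2.0, 0.5, 3.0, 1.5], index=idx)
    m = pd.Series([2.0, 1.0, 4.0, 0.5, 1.0], index=idx)
    c = pd.Series([1.0, 1.0, 2.0, 1.0, 2.0], index=idx)
    ws = ms.combine_weights(e, m, c)
    assert np.allclose(ws.combined_outcome_w, e * m * c)
    assert np.allclose(ws.combined_mediator_w, e * c)


def test_truncation_clips_the_single_extreme_weight():
    rng = np.random.default_rng(0)
    n = 100
    idx = _unit_series(n).index
    e = pd.Series(rng.uniform(1, 2, n), index=idx)
    e.iloc[17] = 500.0
    ws = ms.combine_weights(e, _unit_series(n), _unit_series(n), truncation=(1, 99))
    hi = np.percentile((e * 1.0).to_numpy(), 99)
    assert ws.combined_outcome_w.iloc[17] == pytest.approx(hi)
    assert ws.n_truncated >= 1
    assert ws.combined_outcome_w.max() <= hi + 1e-12


def test_subject_mismatch_errors():
    e = _unit_series(5)
    m = _unit_series(4)
    with pytest.raises(ms.ValidationError, match="mediator"):
        ms.combine_weights(e, m, None)


def test_diagnostics_report_effective_sample_size():
    e = _unit_series(4)
    ws = ms.combine_weights(e, e.copy(), e.copy())
    diag = ws.diagnostics()
    assert diag.loc["combined_outcome_w", "n_eff"] == pytest.approx(4.0)


# ---------------------------------------------------------------------------
# standardization identity


def test_weighted_prevalence_equals_g_formula_standardization():
    rng = np.random.default_rng(7)
    n = 2000
    L = rng.integers(0, 2, n)
    a = rng.choice(3, n, p=[0.4, 0.35, 0.25])
    pm = 0.15 + 0.1 * a + 0.2 * L
    m = (rng.uniform(size=n) < pm).astype(int)
    levels = ("high", "medium", "low")
    cohort = simple_cohort(n=n, ses=np.asarray(levels, object)[a],
                           mediator_t2=m, conf_t1=L)
    ew = ms.fit_exposure_weights(cohort, covariates=("conf_t1",),
                                 sex_handling="none")
    med = ms.fit_mediator_msm(cohort, ms.combine_weights(ew))
    for k, lvl in enumerate(levels):
        g = sum((L == l).mean() * m[(a == k) & (L == l)].mean() for l in (0, 1))
        assert med.prevalence[lvl] == pytest.approx(g, abs=1e-10)


def test_weights_stable_under_irrelevant_covariate(cohort_factory):
    # adding a covariate independent of the exposure moves the standardized
    # prevalence only within its bootstrap noise
    d = ms.SimulationDesign(n=20000)
    cohort = ms.generate_cohort(d, seed=12)
    noise = np.random.default_rng(1).normal(size=len(cohort))
    cohort.df["noise"] = noise
    ew1 = ms.fit_exposure_weights(cohort, covariates=("age",), sex_handling="none")
    ew2 = ms.fit_exposure_weights(cohort, covariates=("age", "noise"),
                                  sex_handling="none")
    p1 = ms.fit_mediator_msm(cohort, ms.combine_weights(ew1)).prevalence
    p2 = ms.fit_mediator_msm(cohort, ms.combine_weights(ew2)).prevalence
    rng = np.random.default_rng(3)
    boots = []
    a = cohort.col("exposure").to_numpy()
    mvals = cohort.col("mediator").to_numpy(dtype=float)
    w1 = ew1.weights.to_numpy()
    for _ in range(60):
        idx = rng.integers(0, len(a), len(a))
        boots.append(np.average(mvals[idx][a[idx] == "low"],
                                weights=w1[idx][a[idx] == "low"]))
    se = np.std(boots, ddof=1)
    assert abs(p1["low"] - p2["low"]) < 3 * se
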