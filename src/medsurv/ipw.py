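"""Inverse-probability weight estimation and combination.

Three weight families enter the marginal structural models:

* exposure weights, 1 / P(A = a_i | L_i), from a multinomial logit of the
  3-level exposure on baseline covariates (age by default), fitted within
  sex strata or with sex as a covariate;
* mediator weights, 1 / P(M = m_i | A_i, L_i), from a logistic model of the
  binary mediator on the exposure and the T1/T2 covariates;
* censoring weights, 1 / P(uncensored | L_i), from a logistic model of
  remaining under observation at T2 on T1 covariates, applied to the
  retained subjects so estimates refer to the full baseline population.

The outcome model is weighted by the product of all three families; the
mediator model by exposure x censoring weights.  Weights default to the
unstabilized form; stabilization (multiplying by a marginal numerator) and
percentile truncation are available options.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import _fitters
from .cohort_data import CohortTable, ValidationError

logger = logging.getLogger(__name__)

POSITIVITY_FLOOR = 1e-8
SEPARATION_TOL = 1e-10


class PositivityError(RuntimeError):
    """A fitted treatment probability is numerically zero."""


class SeparationError(RuntimeError):
    """A fitted probability of the observed value is 0 or 1."""


@dataclass
class FittedWeights:
    """Per-subject weights for one family, indexed by subject id."""

    weights: pd.Series
    probabilities: pd.Series  # fitted probability of the observed value
    family: str
    stabilized: bool


@dataclass
class WeightSet:
    """Combined per-subject analysis weights with truncation metadata."""

    exposure_w: pd.Series
    mediator_w: pd.Series
    censor_w: pd.Series
    combined_outcome_w: pd.Series
    combined_mediator_w: pd.Series
    truncation: Optional[tuple]
    n_truncated: int
    stabilized: bool

    def diagnostics(self) -> pd.DataFrame:
        rows = {}
        for name in ("exposure_w", "mediator_w", "censor_w",
                     "combined_outcome_w", "combined_mediator_w"):
            w = getattr(self, name).to_numpy(dtype=float)
            rows[name] = {
                "min": w.min(), "mean": w.mean(), "max": w.max(),
                "n_eff": w.sum() ** 2 / (w ** 2).sum(),
            }
        return pd.DataFrame(rows).T

    def write_diagnostics(self, path):
        self.diagnostics().to_csv(path, sep="\t", index_label="family",
                                  float_format="%.6g")


# ---------------------------------------------------------------------------
# design-matrix helpers


def _resolve_columns(cohort: CohortTable, covariates) -> list:
    """Map role names (preferred) or column names to column names."""
    cols = []
    for c in covariates:
        r = cohort.roles
        if hasattr(r, c) and isinstance(getattr(r, c), str) and getattr(r, c) in cohort.df.columns:
            cols.append(getattr(r, c))
        elif c in cohort.df.columns:
            cols.append(c)
        else:
            raise ValidationError(f"unknown covariate role or column {c!r}")
    return cols


def _design_matrix(df: pd.DataFrame, cols) -> np.ndarray:
    X = [np.ones(len(df))]
    for c in cols:
        X.append(pd.to_numeric(df[c], errors="raise").to_numpy(dtype=float))
    return np.column_stack(X)


def _exposure_codes(cohort: CohortTable) -> np.ndarray:
    """Exposure coded 0..K-1 with the reference level as class 0."""
    r = cohort.roles
    order = [r.exposure_reference] + [l for l in r.exposure_levels
                                      if l != r.exposure_reference]
    lut = {lvl: i for i, lvl in enumerate(order)}
    return cohort.col("exposure").map(lut).to_numpy(dtype=int)


def exposure_dummies(cohort: CohortTable) -> tuple:
    """Non-reference dummy matrix and the level order (reference first)."""
    r = cohort.roles
    order = [r.exposure_reference] + [l for l in r.exposure_levels
                                      if l != r.exposure_reference]
    a = _exposure_codes(cohort)
    K = len(order)
    D = np.zeros((len(a), K - 1))
    for k in range(1, K):
        D[:, k - 1] = a == k
    return D, order


# ---------------------------------------------------------------------------
# array kernels (shared with the bootstrap fast path)


def _exposure_weight_kernel(X, a, n_levels, strata=None, stabilized=False):
    """Weights 1/P(A=a_i|X_i) from per-stratum multinomial fits."""
    n = len(a)
    prob = np.empty(n)
    groups = [np.arange(n)] if strata is None else [
        np.flatnonzero(strata == s) for s in np.unique(strata)
    ]
    for idx in groups:
        counts = np.bincount(a[idx], minlength=n_levels)
        if (counts == 0).any():
            raise ValidationError(
                f"empty exposure level (class counts {counts.tolist()})"
            )
        fit = _fitters.fit_multinomial(X[idx], a[idx], n_levels)
        P = _fitters.predict_multinomial(X[idx], fit.params)
        prob[idx] = P[np.arange(len(idx)), a[idx]]
        if stabilized:
            prob[idx] /= (counts / counts.sum())[a[idx]]
    if (prob < POSITIVITY_FLOOR).any():
        raise PositivityError(
            "fitted exposure probability below 1e-8: near-violation of positivity"
        )
    return 1.0 / prob, prob


def _mediator_weight_kernel(X, m, a=None, stabilized=False):
    """Weights 1/P(M=m_i|A_i,L_i); X must already include exposure dummies."""
    if a is not None:
        for k in range(int(a.max()) + 1):
            mk = m[a == k]
            if len(mk) and (mk == mk[0]).all():
                raise SeparationError(
                    f"mediator is constant ({int(mk[0])}) within exposure "
                    f"level {k}: the mediator model separates"
                )
    fit = _fitters.fit_logistic(X, m)
    p1 = _fitters.predict_logistic(X, fit.params)
    if (p1 < SEPARATION_TOL).any() or (p1 > 1 - SEPARATION_TOL).any():
        i = int(np.argmax(np.abs(p1 - 0.5)))
        raise SeparationError(
            f"separation in the mediator model: fitted probability {p1[i]:.3g} "
            f"for covariate pattern at observation {i}"
        )
    p_obs = np.where(m == 1, p1, 1.0 - p1)
    if (p_obs < SEPARATION_TOL).any():
        i = int(np.argmin(p_obs))
        raise SeparationError(
            f"separation in the mediator model: fitted probability "
            f"{p_obs[i]:.3g} for observation {i}"
        )
    w = 1.0 / p_obs
    if stabilized:
        if a is None:
            num = np.where(m == 1, m.mean(), 1.0 - m.mean())
        else:
            lev_mean = np.array([m[a == k].mean() for k in range(a.max() + 1)])
            pm = lev_mean[a]
            num = np.where(m == 1, pm, 1.0 - pm)
        w = w * num
    return w, p_obs


def _censor_weight_kernel(X, uncensored, stabilized=False):
    """Weights 1/P(uncensored|L) for every row (use only the retained)."""
    n_c = int((~uncensored.astype(bool)).sum())
    if n_c == 0:
        if stabilized:
            raise ValidationError("no censoring observed: stabilized censoring "
                                  "weights are degenerate")
        return np.ones(len(uncensored)), np.ones(len(uncensored))
    if n_c == len(uncensored):
        raise ValidationError("all subjects censored before T2")
    fit = _fitters.fit_logistic(X, uncensored.astype(float))
    p = _fitters.predict_logistic(X, fit.params)
    if (p < SEPARATION_TOL).any():
        raise SeparationError("separation in the censoring model")
    w = 1.0 / p
    if stabilized:
        w = w * uncensored.mean()
    return w, p


# ---------------------------------------------------------------------------
# public, cohort-facing API


def _strata(cohort: CohortTable, sex_handling: str):
    if sex_handling == "stratify" and cohort.roles.sex:
        return cohort.col("sex").to_numpy()
    return None


def _with_sex(cohort, cols, sex_handling):
    if sex_handling == "adjust" and cohort.roles.sex and cohort.roles.sex not in cols:
        return cols + [cohort.roles.sex]
    return cols


def fit_exposure_weights(cohort: CohortTable, covariates=("age",),
                         sex_handling="stratify", stabilized=False) -> FittedWeights:
    """Inverse probability of the observed exposure level.

    A multinomial logit of the exposure on ``covariates`` (roles or column
    names; default age), fitted separately per sex (``stratify``) or with
    sex added as a covariate (``adjust``).
    """
    if sex_handling not in ("stratify", "adjust", "none"):
        raise ValueError(f"unknown sex_handling {sex_handling!r}")
    cols = _resolve_columns(cohort, [c for c in covariates if c])
    cols = _with_sex(cohort, cols, sex_handling)
    X = _design_matrix(cohort.df, cols)
    a = _exposure_codes(cohort)
    w, prob = _exposure_weight_kernel(
        X, a, len(cohort.roles.exposure_levels),
        strata=_strata(cohort, sex_handling), stabilized=stabilized,
    )
    idx = pd.Index(cohort.subject_ids, name="subject_id")
    return FittedWeights(pd.Series(w, index=idx), pd.Series(prob, index=idx),
                         "exposure", stabilized)


def default_mediator_covariates(cohort: CohortTable) -> list:
    """Baseline job strain plus all T1/T2 confounders, age and sex."""
    r = cohort.roles
    cols = []
    for c in (r.jobstrain_t1,) + tuple(r.confounders_t1) + tuple(r.confounders_t2):
        if c:
            cols.append(c)
    for c in (r.age, r.sex):
        if c:
            cols.append(c)
    return cols


def fit_mediator_weights(cohort: CohortTable, covariates=None,
                         stabilized=False) -> FittedWeights:
    """Inverse probability of the observed mediator value given exposure
    and covariates (default: baseline job strain, T1/T2 confounders, age, sex)."""
    cols = (default_mediator_covariates(cohort) if covariates is None
            else _resolve_columns(cohort, covariates))
    D, _ = exposure_dummies(cohort)
    X = np.column_stack([_design_matrix(cohort.df, cols), D])
    m = cohort.col("mediator").to_numpy(dtype=float)
    w, p_obs = _mediator_weight_kernel(X, m, a=_exposure_codes(cohort),
                                       stabilized=stabilized)
    idx = pd.Index(cohort.subject_ids, name="subject_id")
    return FittedWeights(pd.Series(w, index=idx), pd.Series(p_obs, index=idx),
                         "mediator", stabilized)


def default_censoring_covariates(cohort: CohortTable) -> list:
    """Age, T1 covariates and baseline job strain (all measured pre-censoring)."""
    r = cohort.roles
    cols = []
    for c in (r.age,) + tuple(r.confounders_t1) + (r.jobstrain_t1,):
        if c:
            cols.append(c)
    return cols


def _censoring_design(cohort: CohortTable, covariates, sex_handling) -> np.ndarray:
    if covariates is None:
        cols = _with_sex(cohort, default_censoring_covariates(cohort), sex_handling)
        D, _ = exposure_dummies(cohort)
        return np.column_stack([_design_matrix(cohort.df, cols), D])
    cols = _with_sex(cohort, _resolve_columns(cohort, covariates), sex_handling)
    return _design_matrix(cohort.df, cols)


def fit_censoring_weights(full_cohort: CohortTable, censored=None, covariates=None,
                          sex_handling="adjust", stabilized=False) -> FittedWeights:
    """Inverse probability of remaining uncensored at T2.

    ``censored`` is a binary column name, Series or array flagging pre-T2
    loss (defaults to the ``censored_pre_t2`` role).  The returned weights
    cover only the retained (uncensored) subjects; censored subjects carry
    no analysis weight.  By default the model regresses on age, the T1
    covariates, baseline job strain and the SES exposure indicators; an
    explicit ``covariates`` list replaces that set exactly.
    """
    if censored is None:
        censored = full_cohort.col("censored_pre_t2")
    elif isinstance(censored, str):
        censored = full_cohort.col(censored)
    cen = np.asarray(censored, dtype=float).astype(int)
    X = _censoring_design(full_cohort, covariates, sex_handling)
    strata = _strata(full_cohort, sex_handling)
    unc = (1 - cen).astype(float)
    n = len(unc)
    w = np.empty(n)
    groups = [np.arange(n)] if strata is None else [
        np.flatnonzero(strata == s) for s in np.unique(strata)
    ]
    for idx_g in groups:
        w[idx_g], _ = _censor_weight_kernel(X[idx_g], unc[idx_g],
                                            stabilized=stabilized)
    keep = unc == 1
    idx = pd.Index(full_cohort.subject_ids[keep], name="subject_id")
    return FittedWeights(pd.Series(w[keep], index=idx),
                         pd.Series(1.0 / w[keep], index=idx),
                         "censoring", stabilized)


def _as_series(w, like: pd.Index) -> pd.Series:
    if isinstance(w, FittedWeights):
        w = w.weights
    if w is None:
        return pd.Series(1.0, index=like)
    return w.astype(float)


def combine_weights(exposure_w, mediator_w=None, censor_w=None,
                    truncation=None) -> WeightSet:
    """Combine the weight families into per-model products.

    The outcome-model weight is exposure x mediator x censoring; the
    mediator-model weight is exposure x censoring.  ``truncation`` is an
    optional percentile pair, e.g. ``(1, 99)``: the combined weights are
    winsorized at those percentiles before use.
    """
    ew = _as_series(exposure_w, None)
    idx = ew.index
    mw = _as_series(mediator_w, idx)
    cw = _as_series(censor_w, idx)
    for name, s in (("mediator", mw), ("censoring", cw)):
        if not s.index.equals(idx):
            # censoring weights may legitimately cover a superset (full cohort)
            if idx.isin(s.index).all():
                s = s.loc[idx]
            else:
                raise ValidationError(f"{name} weights do not cover the "
                                      "exposure-weighted subjects")
        if name == "mediator":
            mw = s
        else:
            cw = s
    for s in (ew, mw, cw):
        arr = s.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)) or (arr <= 0).any():
            raise ValidationError("weights must be positive and finite")
    out_w = ew * mw * cw
    med_w = ew * cw
    n_trunc = 0
    if truncation is not None:
        lo, hi = truncation
        before = out_w.copy()
        for s in (out_w, med_w):
            lo_v, hi_v = np.percentile(s.to_numpy(), [lo, hi])
            s.clip(lower=lo_v, upper=hi_v, inplace=True)
        n_trunc = int((before != out_w).sum())
        logger.info(
            "weight truncation at (%s, %s) pct: outcome weight max %.4g -> %.4g, "
            "mean %.4g -> %.4g (%d subjects truncated)",
            lo, hi, before.max(), out_w.max(), before.mean(), out_w.mean(), n_trunc,
        )
    stab = any(getattr(w, "stabilized", False)
               for w in (exposure_w, mediator_w, censor_w))
    return WeightSet(ew, mw, cw, out_w, med_w, truncation, n_trunc, stab)
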