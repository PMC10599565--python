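"""Marginal structural models and the interventional effect decomposition.

Two weighted marginal structural models (MSMs) are fitted:

* an outcome MSM - a Cox proportional-hazards model of depression onset on
  the exposure dummies and the mediator only, weighted by the product of
  exposure, mediator and censoring weights; deaths and administrative
  censoring are treated as (cause-specific) censoring;
* a mediator MSM - a logistic model of the mediator on the exposure alone
  (saturated in the three levels), weighted by exposure x censoring
  weights, whose fitted values are the interventional mediator prevalences
  p_a per exposure arm.

They combine into randomized-interventional-analogue effects on the
hazard-ratio scale, for each non-reference level a vs the reference r:

    HR_IDE = exp(beta_a)
    HR_IIE = (p_a e^{beta_m} + 1 - p_a) / (p_r e^{beta_m} + 1 - p_r)
    HR_total = HR_IDE * HR_IIE

and the mediated fraction (per cent of the total effect transmitted
through the mediator)

    PM = 100 * HR_IDE (HR_IIE - 1) / (HR_IDE * HR_IIE - 1),

reported as undefined when the indirect effect and the total effect pull
in opposite directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _fitters
from .cohort_data import CohortTable, ValidationError
from .ipw import WeightSet, SeparationError, exposure_dummies

MF_DENOM_TOL = 1e-12


@dataclass
class OutcomeMSM:
    """Weighted Cox MSM of the outcome on exposure dummies and mediator."""

    beta_exposure: dict  # non-reference level -> log-HR
    beta_mediator: float
    reference: object
    n: int
    n_events: int
    converged: bool
    ties: str
    grad_norm: float


@dataclass
class MediatorMSM:
    """Weighted saturated logistic MSM of the mediator on the exposure."""

    prevalence: dict     # level -> p_a in (0, 1)
    coefficients: dict   # intercept + per-level log-odds differences
    reference: object
    n: int


@dataclass
class Contrast:
    level: object
    hr_total: float
    hr_ide: float
    hr_iie: float
    mediated_fraction: Optional[float]
    ci: dict = field(default_factory=dict)  # estimand -> (lo, hi) on HR scale


@dataclass
class EffectEstimates:
    reference: object
    contrasts: dict  # level -> Contrast

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lvl, c in self.contrasts.items():
            rows.append({
                "contrast": f"{lvl} vs {self.reference}",
                "hr_total": c.hr_total, "hr_ide": c.hr_ide, "hr_iie": c.hr_iie,
                "mediated_fraction": c.mediated_fraction,
                **{f"{k}_lo": v[0] for k, v in c.ci.items()},
                **{f"{k}_hi": v[1] for k, v in c.ci.items()},
            })
        return pd.DataFrame(rows)


def _analysis_weights(cohort: CohortTable, weights):
    """Align a WeightSet (or plain Series pair) with the cohort rows."""
    if isinstance(weights, WeightSet):
        w_out, w_med = weights.combined_outcome_w, weights.combined_mediator_w
    else:
        w_out = w_med = weights.astype(float)
    ids = cohort.subject_ids
    keep = ids.isin(w_out.index)
    sub = cohort.subset(keep.to_numpy()) if not keep.all() else cohort
    sid = sub.subject_ids
    return sub, w_out.loc[sid].to_numpy(), w_med.loc[sid].to_numpy()


def fit_outcome_msm(cohort: CohortTable, weights, ties="efron") -> OutcomeMSM:
    """Fit the weighted Cox outcome MSM.

    Only depression counts as the event; deaths and administrative
    censoring enter as censoring (cause-specific hazards).  Ties are
    handled by Efron's method by default.
    """
    sub, w_out, _ = _analysis_weights(cohort, weights)
    D, order = exposure_dummies(sub)
    m = sub.col("mediator").to_numpy(dtype=float)
    X = np.column_stack([D, m])
    time = sub.col("followup_time").to_numpy(dtype=float)
    event = (sub.col("event_status").to_numpy() == "depression")
    if not event.any():
        raise ValidationError("no depression events: outcome MSM is undefined")
    a = sub.col("exposure").to_numpy()
    for lvl in order:
        if not event[a == lvl].any():
            raise ValidationError(f"no depression events in exposure level {lvl!r}")
    fit = _fitters.fit_cox(time, event, X, weights=w_out, ties=ties)
    beta = {lvl: float(fit.params[k - 1]) for k, lvl in enumerate(order) if k}
    return OutcomeMSM(
        beta_exposure=beta, beta_mediator=float(fit.params[-1]),
        reference=order[0], n=len(sub), n_events=int(event.sum()),
        converged=fit.converged, ties=ties, grad_norm=fit.grad_norm,
    )


def fit_mediator_msm(cohort: CohortTable, weights) -> MediatorMSM:
    """Fit the weighted exposure-only (saturated) logistic mediator MSM.

    For a saturated model the weighted maximum-likelihood fitted value in
    each exposure level equals the weighted mediator mean in that level,
    so the fit is computed in closed form; the logistic coefficients are
    recovered as log-odds (differences).
    """
    sub, _, w_med = _analysis_weights(cohort, weights)
    m = sub.col("mediator").to_numpy(dtype=float)
    a = sub.col("exposure")
    r = sub.roles
    order = [r.exposure_reference] + [l for l in r.exposure_levels
                                      if l != r.exposure_reference]
    prev = {}
    for lvl in order:
        sel = (a == lvl).to_numpy()
        if not sel.any():
            raise ValidationError(f"empty exposure level {lvl!r} in mediator MSM")
        p = float(np.average(m[sel], weights=w_med[sel]))
        if not 0.0 < p < 1.0:
            raise SeparationError(
                f"mediator is constant ({p:.0f}) within exposure level {lvl!r}"
            )
        prev[lvl] = p
    ref = order[0]
    logit = lambda p: math.log(p / (1 - p))
    coefs = {"intercept": logit(prev[ref])}
    for lvl in order[1:]:
        coefs[lvl] = logit(prev[lvl]) - logit(prev[ref])
    return MediatorMSM(prevalence=prev, coefficients=coefs, reference=ref, n=len(sub))


def mediated_fraction(hr_ide: float, hr_iie: float) -> Optional[float]:
    """Proportion of the total effect mediated, in per cent.

    PM = 100 * HR_IDE (HR_IIE - 1) / (HR_IDE HR_IIE - 1).  Returns None
    (reported as "-") when the indirect and total effects pull in opposite
    directions or the total effect is null to within 1e-12.
    """
    if hr_ide <= 0 or hr_iie <= 0:
        raise ValueError("hazard ratios must be positive")
    total = hr_ide * hr_iie
    denom = total - 1.0
    if abs(denom) < MF_DENOM_TOL:
        return None
    if hr_iie == 1.0:
        return 0.0
    if (hr_iie - 1.0) * denom < 0:
        return None
    return 100.0 * hr_ide * (hr_iie - 1.0) / denom


def format_mediated_fraction(pm: Optional[float]) -> str:
    """Table-style rendering: one decimal up to 10, integer above, "-" if undefined."""
    if pm is None:
        return "-"
    return f"{pm:.1f}" if pm <= 10 else f"{pm:.0f}"


def interventional_effects(outcome: OutcomeMSM, mediator: MediatorMSM,
                           reference=None) -> EffectEstimates:
    """Combine the two MSMs into interventional effect estimates."""
    ref = outcome.reference if reference is None else reference
    if ref not in mediator.prevalence:
        raise ValidationError(f"reference level {ref!r} absent from the mediator MSM")
    if ref != mediator.reference or ref != outcome.reference:
        raise ValidationError(
            "outcome and mediator MSMs must share the requested reference level"
        )
    ebm = math.exp(outcome.beta_mediator)
    p_r = mediator.prevalence[ref]
    contrasts = {}
    for lvl, b in outcome.beta_exposure.items():
        p_a = mediator.prevalence[lvl]
        hr_ide = math.exp(b)
        hr_iie = (p_a * ebm + 1 - p_a) / (p_r * ebm + 1 - p_r)
        contrasts[lvl] = Contrast(
            level=lvl, hr_total=hr_ide * hr_iie, hr_ide=hr_ide, hr_iie=hr_iie,
            mediated_fraction=mediated_fraction(hr_ide, hr_iie),
        )
    return EffectEstimates(reference=ref, contrasts=contrasts)
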