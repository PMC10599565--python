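# Methods

## Estimand and model

The target quantities are randomized interventional analogues of natural
direct and indirect effects on the hazard-ratio scale. Write A for the
3-level exposure (reference r = the most advantaged level), M for the
binary mediator measured after A, Y for time to the event of interest,
and L for measured confounders, some of which are affected by A. Under
the interventional interpretation, the "direct" arm assigns each subject
the mediator drawn from its counterfactual distribution at the reference
exposure, and the "indirect" contrast moves only that mediator
distribution from the reference arm's to the index arm's. Unlike natural
effects, these quantities stay identifiable when a mediator-outcome
confounder (here baseline job strain) is itself a consequence of the
exposure.

Estimation combines two inverse-probability-weighted marginal structural
models:

* outcome MSM: Cox proportional hazards, λ(t|a,m) = λ0(t)·exp(β_a + β_m m),
  fitted by weighted partial likelihood with weights
  w_i = w^A_i · w^M_i · w^C_i;
* mediator MSM: logistic model of M on A alone (saturated in the three
  levels), weighted by w^A_i · w^C_i, whose fitted values are the
  interventional mediator prevalences p_a.

They combine, per non-reference level a, as

    HR_IDE(a) = exp(β_a),
    HR_IIE(a) = (p_a e^{β_m} + 1 − p_a) / (p_r e^{β_m} + 1 − p_r),
    HR_total(a) = HR_IDE(a) · HR_IIE(a),

with mediated fraction PM = 100·HR_IDE(HR_IIE − 1)/(HR_IDE·HR_IIE − 1),
undefined (reported "-") when the indirect and total effects have
opposite directions or the total effect is null to 1e-12. The indirect
factor is a ratio of mediator-prevalence-averaged relative hazards. For a
mixture population this ratio is exact at baseline but is not a constant
hazard ratio over follow-up; with the rare events typical of the setting
(cumulative incidence well under 10%) the time-variation is far below
estimation noise. This hazard-averaging subtlety is a known limitation of
hazard-scale mediation measures, acknowledged rather than resolved.

The outcome fit treats only the event of interest as an event; deaths and
administrative censoring enter as censoring, i.e. the cause-specific
hazard is modelled.

## Weight families

* **Exposure weights** 1/P̂(A=a_i|L_i): multinomial logit of A on baseline
  covariates (default: age), fitted within sex strata
  (`sex_handling="stratify"`, the default, mirroring sex-specific
  reporting) or with sex as a covariate (`"adjust"`).
* **Mediator weights** 1/P̂(M=m_i|A_i,L_i): logistic model of M on the
  exposure dummies plus baseline job strain, the T1 and T2 confounders,
  age and sex.
* **Censoring weights** 1/P̂(uncensored|L_i): logistic model of remaining
  under observation at the second wave on age, the T1 covariates,
  baseline job strain and the exposure indicators; only retained subjects
  carry weights, making estimates refer to the full baseline population.
  Censoring weights enter both MSMs (every fit on the post-T2 sample).

Weights default to the unstabilized form. Stabilization (multiplying by a
marginal numerator) is available; the stabilized mean-1 identity is exact
only when the denominator model is saturated in discrete cells, which is
how the tests exercise it. Percentile truncation of the combined weights
(e.g. (1, 99)) is off by default and available for small-sample runs
where unstabilized weights can explode. Fitted exposure probabilities
below 1e-8 raise a positivity error; fitted mediator probabilities within
1e-10 of 0/1, or a mediator constant within an exposure level, raise a
separation error.

## Inference

Standard errors are nonparametric bootstrap over subjects: each replicate
resamples subjects with replacement (within sex strata when stratified)
and re-runs the entire chain — censoring, exposure and mediator weights,
both MSMs, and the effect combination. The SE of each log effect is the
standard deviation over converged replicates; replicates that fail
(non-convergence, separation, an empty exposure level) are dropped and
counted, with more than 20% failures an error. Confidence intervals are
normal on the log-HR scale (percentile intervals are available for
single-dataset runs). Defaults are B = 100 per imputed dataset and
B = 2000 for a single complete-case run, both overridable.

With m pre-imputed datasets the pipeline estimates each dataset
separately (bootstrap within imputation) and pools with Rubin's rules:
pooled point = mean of log estimates, total variance = within +
(1 + 1/m)·between; with m = 1 the between term is 0 by convention.
Mediated-fraction CIs are not computed; the fraction is reported as a
point value from the pooled hazard ratios.

## Synthetic cohort generator

`SimulationDesign` parameterizes a cohort with the study's causal
ordering: exposure (exogenous categorical) → binary T1 covariate →
baseline job strain → binary T2 covariate → mediator → outcome. Event
times are exponential by default (optional Weibull shape), with hazard
λ0·exp(β_a + β_m m + β_L L); death is an independent exponential
competing risk; a logistic pre-T2 selection model on T1 variables flags
subjects censored before the mediator wave (their post-T2 columns are
still generated — they are synthetic ground truth, used only by the
censoring-weight machinery); administrative censoring falls at 1095 days.

Because all mediator-model covariates are discrete, the marginal mediator
prevalence per arm — and hence the true interventional effects on the
ratio-of-averaged-hazards scale — is computed by exact enumeration
(`true_effects`; a Monte-Carlo integration path exists for continuous
extensions). The closed-form truth HR_IDE = exp(β_a) is exact when the
confounders carry no direct outcome effect; the default scenario
therefore sets the confounder→outcome log-HRs to zero and places the
confounding burden on the mediator side, while the confounding stress
scenario (`confounded_design`) turns on a strong baseline-job-strain →
outcome effect (log-HR 1.0) and a strong job-strain → mediator effect
(1.5) to demonstrate that the unweighted indirect estimate is biased
where the weighted one is not.

Default scenario values were chosen once to echo a realistic white-collar
cohort: equal exposure arms, mediator prevalence ≈ 0.14–0.27 per arm
(≈ 0.20 overall), depression rate 22 per 1000 person-years at the
linear-predictor origin, death rate 4 per 1000 person-years, ≈ 29% pre-T2
selection, direct-effect HRs 1.2 and 1.5, mediator HR 1.5, indirect HRs
≈ 1.026 and 1.058. These are scenario defaults, not estimates from any
dataset. What the generator does **not** emulate: questionnaire items for
the mediator (scores are drawn directly; the scoring module is exercised
on its own inputs), informative censoring beyond measured T1 variables,
time-varying exposure, seasonality or calendar effects, and realistic
missingness (only pre-imputed complete tables enter the pipeline).
Passing recovery tests therefore show the estimator is consistent and
calibrated under the assumed data-generating law, not that any particular
real-world dataset satisfies those assumptions.

## Numerical choices

* All inner fits (logistic, multinomial logit, weighted Cox) are compact
  Newton-Raphson routines with step-halving: the bootstrap and the
  recovery study re-fit every model tens of thousands of times, so
  per-fit overhead dominates runtime. Coefficients are cross-checked in
  the tests against statsmodels (GLM, MNLogit) and lifelines (Cox) at
  1e-5 or better.
* Convergence: gradient below 1e-10 × (total weight) or Newton step below
  1e-10 relative; step-halving tolerates rounding noise of order
  1e-11·|loglik|, which matters near the optimum of large weighted
  partial likelihoods.
* Cox ties: Efron's method by default, in the same weighted convention as
  lifelines/R (tie multiplicity = number of tied rows). Under this
  convention an integer-weighted fit is *not* identical to duplicating
  rows (the duplicated data have larger tie sets); under Breslow the
  identity is exact, so the duplication oracle in the tests runs both
  sides with Breslow ties. Analysis event times are continuous, where the
  two methods coincide; bootstrap resamples do create ties, handled by
  the vectorized Efron corrections.
* Mediator MSM: for a saturated weighted logistic model the MLE fitted
  value per level equals the weighted mean, so the fit is closed-form;
  the identity is verified against a weighted GLM in the tests.
* Combined-SES tertiles: rank-based thirds with ties broken by stable
  subject order (sizes differ by at most 1); PCA on the Pearson
  correlation matrix of the ordinal codes, component sign fixed so higher
  score = higher SES.
* Calendar arithmetic in whole days: prevalence window 365 days
  (half-open, inclusive at the wave date), follow-up horizon 1095 days; a
  same-day depression claim and death count as depression; ICD-9 codes
  compared as strings with dots stripped, "296" as a prefix match.
* Exclusion reasons are applied in a fixed order of precedence (death
  before T2, prevalent depression, not working, no linkage, no
  second-wave participation) so each subject gets exactly one reason.

## Study sizes used in the test suite

The recovery study runs 200 cohorts of n = 5000 with B = 100 bootstrap
replicates each (the per-dataset bootstrap size used with multiple
imputation); the confounding demonstration uses a single cohort of
n = 20000; the null-behavior check uses n = 10000. These sizes give
Monte-Carlo error comfortably inside the asserted tolerances (mean log
effects within 0.02 of truth; CI coverage at least 90%).

## Known limitations

* Single-visit exposure and mediator: no product-over-time treatment
  weights; the design has one exposure point and one mediator point.
* No exposure × mediator interaction in the outcome MSM (by design); an
  interaction-capable extension is out of scope.
* The mediated fraction is a point summary only, and is undefined
  whenever direct and indirect effects act in opposite directions.
* Natural (non-interventional) effects, continuous mediators,
  accelerated-failure-time and additive-hazard outcome models are out of
  scope.
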