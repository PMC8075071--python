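# Methods

`copdwatch` is a simulation-and-analysis workbench for a pre-post
evaluation of app-based COPD telemonitoring. It bundles four pieces of
machinery: a synthetic cohort generator, the deterministic monitoring
("zone") rule engine, the pre-post count-regression analysis, and the
paired-means planning arithmetic. This note records the models, the
defaults and why they were chosen, the numerical conventions, and what
the simulator does and does not emulate.

## The generative cohort model

Each patient is drawn independently from a configured population
(`SimConfig`). Baseline covariates are simple parametric marginals
calibrated to a real 29-patient telemonitoring cohort: age ~
N(67.4, 8.0²) years, 45% women, FEV₁ ~ N(45.5, 17.7²) %predicted
(clipped to [10, 120]), GOLD category drawn from (A, B, C, D, missing)
with probabilities (0, 1/29, 1/29, 21/29, 6/29), and inhaled-
corticosteroid use with probability 0.55 (mono plus combination
inhalers). Covariates are sampled independently; real covariates are
correlated (e.g. GOLD D patients have lower FEV₁), so adjusted models
on synthetic data exercise the estimation code, not confounding
structure.

**Events.** Exacerbations follow a homogeneous Poisson process at rate
λ = 2.4 events/person-year in the 365-day pre period and λ·ρ_e in the
post period, where ρ_e = 0.310 is the generative post/pre rate ratio
for total exacerbations. λ = 2.4 makes the pre-period count median 2,
matching the calibration cohort. Severity is multinomial
(mild 0.05, moderate 0.10, severe 0.85) — the calibration cohort's
exacerbations were almost all hospitalizations. Each severe event
carries `1 + Poisson(m − 1)` hospital days with m = 4 pre-intervention
(guaranteeing ≥ 1 day per admission and a pre-period hospital-day
median near 8); in the post period m is scaled by ρ_h/ρ_e with
ρ_h = 0.210 so that the cohort-level hospital-days rate ratio equals
ρ_h while the event-count ratio stays ρ_e. By default patients share
one rate (counts are Poisson); `rate_dispersion` switches on a gamma
frailty, giving negative-binomial counts for sensitivity work.

**Follow-up and mortality.** Post follow-up is drawn from a two-piece
uniform, U(157, 587) or U(587, 601) with equal probability, which
matches the calibration quantiles (median 587, IQR 372–594) exactly.
That distribution is left-skewed — most patients reach near-maximal
follow-up, a minority enrol late or die — which no right-skewed
parametric family can reproduce from those three quantiles. Ten
percent of patients die; deaths resample follow-up from the lower
piece, truncating exposure without otherwise altering event rates.

**Daily logs.** One record per follow-up day. The daily symptom
question is answered with probability 0.43 (so 587 days of follow-up
yield a median of ~252 answered days). Answers report worsening with
probability 0.85 inside a symptom window spanning 3 days before to 7
days after each event onset (a plausible prodrome that lets the 3-day
escalation rule fire) and 0.08 otherwise; the background rate was set
so the median number of "yes" answers lands in the observed range
(~26 per patient). On symptomatic days the on-demand severity question
is answered with probability 0.5, with 8% orange-class and 8%
red-class answers. Steps are observed on 90% of days around a
patient-specific habitual mean (N(2600, 1200²), floored at 200), with
15% day-to-day noise and a 35% decline inside event windows — deep
enough to cross the 20% alert threshold on most window days.
Health-status (CCQ) scores appear on the thrice-weekly schedule, with
patient-level mean N(3.0, 1.2²) and no built-in time trend.

All randomness derives from one integer seed via per-patient,
per-purpose substreams (`SeedSequence((seed, patient_id, stream))`), so
cohorts are bit-reproducible and any patient can be regenerated alone.

## The zone engine

The monitoring state machine has two components, combined as
`overall = max(symptom, activity)`:

* **Symptom pathway.** An answered "worse" day moves GREEN → YELLOW;
  three consecutive worse days (counted over *answered* days) move to
  ORANGE; any improvement answer returns to GREEN and resets the
  counter. Unanswered days freeze the counter — absence of an answer
  is not evidence of improvement, and it cannot advance the escalation
  either. The on-demand question raises the symptom zone to a floor
  (orange-class → ORANGE, red-class → RED) and never lowers it; RED
  reached this way carries the call-an-ambulance advice. A subsequent
  improvement answer de-escalates even from RED — the alternative
  (requiring clinical reset) is defensible but unverifiable here, and
  self-report de-escalation matches the yellow-zone rule's wording.
* **Activity pathway.** Days 0–20 (three weeks) form the baseline; the
  step goal is `goal_factor` × the mean of observed baseline days
  (goal_factor defaults to 1.0 because the clinician-set goal is not
  quantified; it is a parameter). From day 21, steps ≤ 80% of goal →
  ORANGE, ≤ 60% → RED, otherwise GREEN — thresholds are inclusive (a
  tie goes to the more severe zone) and there is no yellow activity
  zone. The step zone persists between step observations. If all
  baseline days are missing the engine runs symptom-only.

One buddy alert is emitted per change of the end-of-day overall zone,
carrying the destination zone's advice code (adapt medication /
emergency medication or contact a professional / call an ambulance;
de-escalations carry no advice). The CCQ schedule is fixed at days
{0, 2, 4} mod 7 from inclusion — "three times a week" pinned to a
concrete grid.

## Pre-post rate-ratio analysis

The analysis unit is the patient-period: each patient contributes a
365-day pre row and a follow-up-length post row with event counts.
The intervention effect is the incidence rate ratio from a log-linear
count model with fixed log-exposure offset, estimated by GEE with
patient clusters and robust sandwich SEs. The covariate ladder is:
(1) intervention only; (2) + sex (reference male) and age in years,
untransformed; (3) + GOLD category; (4) + ICS use. Models 3–4 exclude
patients with missing GOLD. Confidence intervals are Wald on the log
scale, exp(β ± 1.96·SE); the method is a documented choice, as is the
exchangeable working correlation (natural for two exchangeable repeat
measures; robust SEs make the results insensitive to it, and an
independence option is provided, under which point estimates coincide
with an ordinary Poisson GLM — for the intervention-only model, with
the ratio of pooled post to pooled pre rates).

Family choice: a Poisson GLM of the outcome on intervention (with
offset) is fitted first and the Pearson χ²/df computed; dispersion
above 1.5 selects the negative-binomial family. The threshold is a
simple, testable operationalization of "check Poisson vs negative
binomial": simulated Poisson counts sit near 1, genuinely
overdispersed counts far above 1.5. Note that under the default
generator total exacerbation counts are Poisson but hospital-day
totals are a compound Poisson sum and therefore overdispersed, so the
selector legitimately picks the negative binomial for that outcome;
the parameter-recovery results use the Poisson GEE whose robust SEs do
not require the variance model to be correct.

Numerical safeguards: the small-sample moment estimate of the
exchangeable correlation can exceed 1 with two observations per
cluster, making the working covariance non-positive-definite, so it is
clamped to [−0.95, 0.95]; a numerically zero sandwich variance (e.g.
perfectly symmetric pre/post data) degenerates the CI to the point
estimate with a warning rather than failing.

The CCQ trend is a Gaussian GEE of score on day with patient clusters,
reported as slope per 30 days with its robust two-sided p-value;
all-constant input short-circuits to slope 0 with a degenerate-variance
warning.

## Planning arithmetic

Expected hospital days per person-year = P(admitted) × mean stay
(0.25 × 6.0 = 1.5); a 25% reduction targets 1.125. The paired-means
sample size uses σ_d = √(σ₁² + σ₂² − 2ρσ₁σ₂) = 0.735 and the
standardized effect d = 0.375/σ_d = 0.510. The default convention
solves iteratively for the smallest n with
power(n) = Φ(√n·d − t_{1−α/2, n−1}) ≥ 0.80 — the t critical value with
a normal approximation to the alternative distribution, a common
textbook/software convention — giving n = 32 completers, then divides
by (1 − dropout) and rounds up: ⌈32/0.8⌉ = 40. The plain-z closed form
gives 31 → 39, and the exact noncentral-t power function gives
33 → 42; all three are within the usual software-to-software spread
for this calculation, and the t-approximation is the default. The
outcome (days in hospital) is a count, so a means-based calculation is
itself an approximation; count-model alternatives are out of scope.

## Problem sizes and what the tests show

Parameter recovery uses 50 replicate cohorts of 500 patients — large
enough that the mean model-1 IRR estimate pins the generative ratio to
well under ±0.03 and CI coverage is estimated to ~±3% — and the rule
engine is checked against an independent brute-force day-walker on
1,000 random logs. Passing these shows the estimator is consistent and
nearly unbiased *under the generator's assumptions* (independent
patients, homogeneous Poisson events, non-informative follow-up
truncation) and that the rule engine implements the stated rules
exactly. It does not validate the causal interpretation of a pre-post
contrast on real data: regression to the mean, selection of motivated
patients, seasonal exacerbation patterns and EHR under-capture of mild
events are all outside the generative model by design.

## Known limitations

* Covariates are mutually independent; adjusted models are exercised
  for correctness, not for confounding control.
* No seasonality, no within-patient rate drift, no adherence decay
  over time (observed cohorts show declining engagement).
* The activity pathway's "sticky" step zone means a single bad step day
  can hold ORANGE until the next wear day.
* Event-day sampling is uniform within period; clustering of
  exacerbations (relapses) is not modelled beyond the symptom window.
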