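# Methods

`colonsurv` implements a comparative-effectiveness analysis of
post-treatment surveillance testing in stage II/III colon cancer, of the
kind run on registry-linked administrative claims: exposure (how fully a
patient's received surveillance tests meet guideline minima) is derived
from dated claims, confounding by indication is addressed with
boosted-model propensity scores and inverse probability of treatment
weighting (IPTW), and mortality is analysed with weighted cause-specific
survival models. Because real registry-claims data of this kind are
access-restricted, the package ships a synthetic-claims generator that
reproduces the structural features the analysis depends on, and the test
suite exercises the pipeline end to end on those cohorts.

## Claims processing

**Final treatment date.** Follow-up is anchored at the end of primary
treatment. Surgery-only patients are anchored at the surgery date. For
chemotherapy recipients the course is walked from the first chemotherapy
claim, extending while consecutive claim gaps are ≤ 90 days ("sequential"
chemotherapy); if the course spans more than 6 months the anchor is capped
at 183 days after the first chemotherapy claim. "6 months" is rendered as
183 days and a follow-up "year" as a fixed 365 days with half-open windows
`[start, start + 365)`; fixed integer day counts keep every boundary exact
and testable. Chemotherapy claims that resume after a > 90-day break do not
re-anchor the final treatment date — the single-course reading.

**Test deduplication.** Within each patient, claims of one modality
(CEA; CT pooled with PET into one imaging stream; colonoscopy) are
deduplicated greedily left to right: keep the first claim, then each
subsequent claim only if it falls ≥ 30 days after the last kept claim.
Greedy-from-first is the canonical claims convention and is
order-deterministic; the test suite checks it against a brute-force
enumeration oracle on small instances. Deduplication runs on the full
post-treatment stream *before* year windowing, since the 30-day rule is
about duplicate billing, not about years; a kept/dropped decision may
therefore straddle a year boundary.

**Completeness.** Year *k* (1-based, up to 3) is complete iff follow-up
(min of death and administrative censoring) reaches `final + 365·k`.

## Adherence classification

Guideline minima per follow-up year: ≥ 2 CEA tests, ≥ 1 CT, ≥ 1
colonoscopy, with a colonoscopy in the prior year carrying over to satisfy
the colonoscopy recommendation in years 2–3. Each complete year is
labelled by the canonical rule: a modality is *active* if it has ≥ 1
deduplicated test that year (colonoscopy also via carry-over);
**Nonadherent** = no tests and no carry-over; **More Adherent** = ≥ 2
active modalities; **Less Adherent** = exactly 1. This reconstruction
reproduces every legible row of the published per-year scheme (full
adherence, the partial-CEA More rows, all single-modality Less rows, the
all-zero Nonadherent row, and the carry-over column of years 2–3), and
`RuleTable` accepts explicit tuple→label overrides so an exact enumerated
scheme can be substituted without code change.

Overall classification over the complete years: no complete year, or
Nonadherent in *every* complete year, excludes the patient (only a fully
test-free assessment period triggers exclusion); one complete year stands
alone; with two or three years, Nonadherent years count as Less and the
overall label is More iff strictly more More-years than Less-years — ties
break to Less, the conservative reading of "missing at least one
recommended test without additional testing". The combination rule is
likewise override-able.

Classification is monotone: adding any test to any year never demotes the
yearly label (property-tested over the count lattice).

## Propensity model and weighting

The exposure contrast is More vs. Less Adherent overall classification.
The propensity of being More Adherent is estimated with gradient-boosted
classification trees on the pre-treatment covariate indicators (age group,
race, sex, marital status, diagnosis-year group, state buy-in, census-tract
poverty, urban–rural, region, substage, grade, tumor location, chemotherapy
receipt, and the individual comorbid-condition flags; every category,
including "unknown", is its own indicator). Hyper-parameters: interaction
depth 3, learning rate 0.01, 50% subsampling, at most 5000 trees —
conventional values in the balance-stopping boosted-propensity literature.

The number of boosting iterations is *balance-driven*: the ensemble grows
100 trees at a time; at each checkpoint the mean absolute standardized mean
difference (ASMD) of the implied ATE weights is evaluated (checkpoint 0 is
the intercept-only model, i.e. the marginal treatment rate), and the
checkpoint with the smallest mean ASMD wins. Fitting stops early once the
mean ASMD has not improved for five consecutive checkpoints. This can
never end worse than intercept-only weighting. Propensities are clipped to
`[1e-3, 1 - 1e-3]` to bound weights; no other trimming is applied.

Weights target the average treatment effect: `w = T/e + (1−T)/(1−e)`.
Balance is reported per covariate indicator as
`ASMD_g = |m̄_g − m̄_pop| / s_pop` for each group against the *unweighted*
study-population mean and standard deviation — the population reference
stays fixed whether or not group means are weighted — and ASMD ≥ 0.20
flags imbalance.

## Survival analysis

Outcomes are measured in days from the final treatment date with
administrative censoring at 5 years (1825 days): cancer-specific mortality
(noncancer deaths censored at death), noncancer-specific mortality
restricted to years 2–5, and overall mortality. "Years 2–5" is implemented
as delayed entry (left truncation) at day 365 — the standard rendering of
restricting an analysis to follow-up beyond the first year. Because
analyzable patients need ≥ 1 complete surveillance year, no death can occur
before day 365 in the analysis set; this is a design feature of the
exposure-assessment window, not a bug. The colon-cancer-specific vs.
any-cancer-specific distinction is collapsed to a single "cancer-specific"
outcome, and surgery-only and chemotherapy strata are pooled; both remain
definable through `OutcomeSpec`.

The weighted Kaplan-Meier and weighted log-rank statistics are implemented
in-package with weighted event and at-risk masses (supporting delayed
entry) and reduce exactly to their classical forms at unit weights; the
log-rank variance treats weights as frequencies, so with IPTW weights the
robust Cox Wald test is the primary inference. The weighted Cox model is
fit by partial likelihood with case weights, Efron tie handling, delayed
entry, and a cluster-robust sandwich variance by patient (weights induce
heteroscedasticity; the sandwich is the standard remedy). The hazard ratio
is reported for Less vs. More Adherent (More = reference). Proportional
hazards are checked graphically (log(−log S) vs. log t curve pairs, which
under proportionality are parallel with vertical offset log HR) and by a
score test of the group × log(time) interaction via scaled Schoenfeld
residuals. Median follow-up uses reverse Kaplan-Meier (censoring as the
event); quantile confidence intervals use confidence-band crossing of the
log(−log) Greenwood interval.

## Synthetic cohort generator

The generator emulates the structure of an elderly (66–84) stage II/III
colon cancer registry-claims cohort:

* **Covariate margins** follow the overall distribution of such a
  population (age, race, sex, marital status, diagnosis-year group, state
  buy-in, poverty, urban–rural, region, substage, grade, tumor site);
  individual comorbid conditions are independent Bernoulli flags whose sum
  is the comorbidity burden. Chemotherapy receipt is logistic in stage,
  age and comorbidity.
* **Confounding by indication.** A latent "surveillance intensity" class
  (high/low) is drawn from a logistic model in which stage III, high
  grade and chemotherapy raise intensity while age 80–84, Medicaid buy-in
  and comorbidity lower it. The coefficients are sized so the analyzable
  cohort splits roughly 65/35 More/Less Adherent and the *unweighted*
  Less-vs-More cancer hazard ratio is biased to ≈ exp(−0.34) despite a
  true null effect — the magnitude implied by the large stage/chemotherapy
  group contrasts such studies report. The latent class drives per-year
  Poisson counts of CEA/CT(+PET)/colonoscopy claims (days uniform within
  the year, passed through the real deduplication code, truncated at
  death), so the observed adherence label emerges from the classifier
  rather than being injected.
* **Mortality.** Two independent latent cause-specific hazards
  (exponential by default, Weibull configurable): cancer mortality driven
  by stage, grade and chemotherapy plus the configurable true group
  effect (`true_group_effect_cancer`, default 0 — surveillance intensity
  has no causal effect on cancer death); noncancer mortality driven by
  age and comorbidity count. Baseline rates are calibrated so ≈ 32% die
  within 5 years of treatment with ≈ 56% of deaths from cancer.
  The observed cause is the argmin of the two latent times;
  administrative censoring at 10 years.
* **Chemotherapy claim sequences** start 14–60 days post-surgery with
  4–12 cycles at 14–28 day gaps, so both the > 6-month cap and the
  > 90-day break paths of the anchoring rule occur in every large cohort.

What the generator does **not** emulate: real ICD/CPT coded claims,
Medicare enrollment gaps (continuous enrollment assumed), dependence
between the competing causes, unmeasured confounding (off by default;
`latent_risk_sd` adds cancer-hazard frailty not seen by the propensity
model), recurrence-driven testing, or calendar-time trends. Passing tests
therefore show that the pipeline correctly removes *measured* confounding
of the configured form, not that IPTW would remove unmeasured confounding
in real data.

## Numerical and design choices

* Dates are integer day offsets from a nominal diagnosis epoch.
* Greedy deduplication tie-breaks: the earliest claim always wins.
* Weighted KM at-risk convention `entry < t ≤ time`, matching the
  classical estimator at zero entry.
* Cox solved to coefficient precision 1e-11 so unit-weight fits agree with
  independent implementations to ≤ 1e-6.
* Problem sizes: the default synthetic cohort is n = 2000; the replicate
  study of null-effect recovery in the test suite uses 100 replicates at
  n = 2000 (coverage of HR = 1 is asserted in the 90–99% band), and the
  acceptance script uses 60 replicates, with the replicate count recorded
  next to each reported value.
* Degenerate inputs: constant covariate indicators are dropped with a
  warning; zero population SD yields ASMD 0 with a warning; eventless
  groups make the Cox stage refuse rather than return garbage; empty
  claims streams classify as Nonadherent and are excluded with a recorded
  reason.

## Known limitations

* The overall-combination scheme beyond the published prose (majority
  rule, Nonadherent-as-Less, tie → Less) is a declared reconstruction;
  an exact enumerated table can be supplied via `RuleTable` overrides.
* The weighted log-rank p-value treats weights as frequencies rather than
  using a replication-robust variance.
* The IPTW confidence intervals ignore the uncertainty of the estimated
  propensity scores, which in practice makes them mildly conservative.
* Exposure is a fixed classification over up to 3 post-treatment years
  while survival is measured from the final treatment date; patients dying
  during the assessment window are classified on fewer years. This mirrors
  the design the package implements and induces a small association
  between label and follow-up length that weighting cannot remove.
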