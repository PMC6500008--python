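# colonsurv

Comparative-effectiveness analysis of post-treatment surveillance testing
in stage II/III colon cancer, as run on registry-linked administrative
claims: how does survival compare between patients who are **More
Adherent** vs. **Less Adherent** to surveillance guidelines (CEA blood
tests, CT imaging, colonoscopy) after curative treatment, once
confounding by indication — sicker patients get more testing — is removed
by propensity weighting?

The package is written for biostatisticians and health-services
researchers. It provides, as a tested pipeline:

1. **Claims processing** (`colonsurv.claims_engine`) — anchors follow-up
   at the final treatment date (surgery, or the end of sequential
   chemotherapy with gaps ≤ 90 days, capped at 183 days after the first
   chemotherapy claim), deduplicates surveillance claims at ≥ 30 days
   (CT and PET pooled), and counts tests per 365-day post-treatment year.
2. **Adherence classification** (`colonsurv.adherence`) — per-year labels
   from guideline minima (CEA ≥ 2/yr, CT ≥ 1/yr, colonoscopy ≥ 1 with
   prior-year carry-over): More Adherent (≥ 2 active modalities), Less
   Adherent (exactly 1), Nonadherent (none); yearly labels combine into an
   overall classification, and patients with no tests in any complete year
   are excluded.
3. **IPTW** (`colonsurv.weighting`) — gradient-boosted propensity scores
   e(x) = P(More Adherent | covariates) with balance-driven iteration
   selection, average-treatment-effect weights `w = T/e + (1−T)/(1−e)`,
   and covariate balance via the absolute standardized mean difference
   ASMD = |m̄_g − m̄_pop| / s_pop against the study-population mean
   (imbalance flagged at ASMD ≥ 0.20).
4. **Weighted survival analysis** (`colonsurv.survival`) — IPTW
   Kaplan-Meier curves, weighted log-rank tests, and weighted Cox models
   (Efron ties, delayed entry, robust sandwich variance) for 5-year
   cancer-specific, noncancer-specific (years 2–5, via left truncation at
   day 365) and overall mortality, reported as HR (95% CI) for Less vs.
   More Adherent.
5. **Synthetic cohorts** (`colonsurv.cohort_synth`) — seeded generators of
   patient/claims tables with realistic covariate margins, confounding by
   indication, and competing cancer/noncancer mortality, with ground truth
   retained for recovery tests (real registry-claims data are
   access-restricted and are not an input).
6. **Reporting** (`colonsurv.reporting`) — descriptive group comparison
   with chi-square tests and Kaplan-Meier follow-up summaries, HR tables,
   and the one-command pipeline runner.

## Worked example

Run the whole pipeline on a default synthetic cohort of 2000 patients:

```python
from colonsurv import default_config, run_pipeline

manifest = run_pipeline(default_config(n_patients=2000, seed=7), "artifacts")
print(manifest["label_counts"])
print(manifest["max_weighted_asmd"])
for name, fit in manifest["hazard_ratios"].items():
    print(name, round(fit["hr"], 2), (round(fit["ci_lower"], 2), round(fit["ci_upper"], 2)))
```

prints

```
{'MORE': 1128, 'LESS': 579, 'EXCLUDED': 293}
0.08092423884877753
cancer_specific 0.84 (0.62, 1.15)
noncancer_specific 0.89 (0.64, 1.26)
overall 0.86 (0.69, 1.08)
```

Reading this: of 2000 simulated patients, 293 are excluded (no complete
follow-up year, or no surveillance tests at all), and the rest split
roughly 2:1 More vs. Less Adherent. After boosted-model weighting the
largest covariate ASMD is 0.08 — far below the 0.20 imbalance threshold,
so the groups are balanced on everything the propensity model saw. The
generator's true surveillance effect on cancer mortality is null, and the
IPTW cancer-specific hazard ratio duly has a confidence interval covering
1.0 — while unweighted estimates on such cohorts are systematically biased
downward (hazard ratios around 0.7) because higher-risk patients receive
more surveillance. The same
analysis can be driven from the shell:

```bash
colonsurv run --seed 7 --n 2000 --out artifacts/
colonsurv synth --seed 42 --n 500 --out cohort/        # stage by stage
colonsurv classify --patients cohort/patients.csv --claims cohort/claims.csv --out cohort/
```

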