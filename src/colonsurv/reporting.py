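"""Descriptive tables, hazard-ratio summaries, and the pipeline runner.

The descriptive comparison mirrors the familiar "Table 1" of a
comparative-effectiveness study: counts and column percentages per
surveillance group for every characteristic, Pearson chi-square tests,
median follow-up by reverse Kaplan-Meier, and the time by which 25% of
each group has died of cancer. ``run_pipeline`` chains the whole analysis
— simulate (or load) -> claims processing -> adherence classification ->
boosted IPTW -> weighted survival models -> report files — and writes a
manifest recording the seed and every exclusion step.
"""

from __future__ import annotations

import json
import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from . import adherence, claims_engine, cohort_synth, weighting
from . import survival as surv
from .claims_engine import YEAR_DAYS
from .config import SynthConfig, default_config
from .survival import OutcomeSpec, SurvivalFit
from .weighting import PropensityParams

__all__ = ["descriptive_table", "hr_summary", "run_pipeline", "format_p", "format_hr_ci"]

#: Characteristics reported in the descriptive table, in print order.
DESCRIPTIVE_COVARIATES = [
    "age_group", "race", "sex", "marital_status", "dx_year_group", "buyin",
    "poverty", "urban_rural", "region", "substage", "grade", "tumor_site", "chemo",
]

GROUPS = [("MORE", "more_adherent"), ("LESS", "less_adherent")]


def format_p(p: float) -> str:
    """Render a p-value, collapsing anything below 1e-3 to "< 0.001"."""
    return "< 0.001" if p < 1e-3 else f"{p:.3f}"


def format_hr_ci(hr: float, lo: float, hi: float) -> str:
    """Render "HR (lo-hi)" with two decimals, e.g. ``0.83 (0.76-0.90)``."""
    return f"{hr:.2f} ({lo:.2f}–{hi:.2f})"


def percentages(counts: Sequence[float]) -> list[float]:
    """Column percentages to one decimal for a vector of counts."""
    total = float(sum(counts))
    if total == 0:
        raise ValueError("cannot take percentages of an all-zero column")
    return [round(100.0 * c / total, 1) for c in counts]


def _chi_square(table: pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on a count cross-tab."""
    arr = table.to_numpy(float)
    arr = arr[arr.sum(axis=1) > 0][:, arr.sum(axis=0) > 0]
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        return 0.0, 0, 1.0
    res = stats.chi2_contingency(arr, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def _km_quantile_with_ci(
    time: np.ndarray, event: np.ndarray, q: float
) -> tuple[float | None, float | None, float | None]:
    """KM quantile with a confidence-band crossing (Brookmeyer-Crowley) CI.

    Returns (estimate, ci_lower, ci_upper) in the input time unit; ``None``
    entries mean the corresponding crossing is not reached.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    level = 1.0 - q

    def first_crossing(series: pd.Series) -> float | None:
        hit = series[series <= level]
        return None if hit.empty else float(hit.index[0])

    est = first_crossing(kmf.survival_function_.iloc[:, 0])
    ci = kmf.confidence_interval_survival_function_
    lo = first_crossing(ci.iloc[:, 0])  # lower confidence limit crosses first
    hi = first_crossing(ci.iloc[:, 1])
    return est, lo, hi


def _followup_rows(analysis: pd.DataFrame) -> list[dict]:
    """Median follow-up (reverse KM) and 25% cancer-death time per group."""
    rows = []
    for measure, event_col in (
        ("median_followup_years", "censoring"),
        ("cancer_death_25pct_years", "cancer_event"),
    ):
        q = 0.5 if measure == "median_followup_years" else 0.25
        cells = {}
        for label, col in GROUPS:
            sub = analysis[analysis["overall_label"] == label]
            est, lo, hi = _km_quantile_with_ci(
                sub["followup_days"].to_numpy() / YEAR_DAYS,
                sub[event_col].to_numpy(int),
                q,
            )
            fmt = lambda v: "NR" if v is None else f"{v:.1f}"
            cells[col] = f"{fmt(est)} ({fmt(lo)}–{fmt(hi)})"
        _, logrank_p = surv.weighted_logrank(
            analysis["followup_days"].to_numpy() / YEAR_DAYS,
            analysis[event_col].to_numpy(int),
            (analysis["overall_label"] == "MORE").to_numpy(int),
        )
        rows.append(
            {
                "characteristic": measure,
                "category": "(years, 95% CI)",
                "more_adherent": cells["more_adherent"],
                "less_adherent": cells["less_adherent"],
                "p_value": format_p(logrank_p),
            }
        )
    return rows


def descriptive_table(
    patients: pd.DataFrame, counts: pd.DataFrame, profiles: pd.DataFrame
) -> pd.DataFrame:
    """Group-wise descriptive comparison of the analyzable study population.

    One row per characteristic category with "count (percent)" cells per
    surveillance group and a chi-square p-value per characteristic; plus
    5-year vital status, cause of death among the 5-year deceased,
    follow-up medians, and the 25% cancer-death time.
    """
    analysis = (
        patients.merge(profiles[["patient_id", "overall_label"]], on="patient_id")
        .merge(counts[["patient_id", "final_treatment_day", "last_followup_day"]], on="patient_id")
    )
    analysis = analysis[analysis["overall_label"].isin(["MORE", "LESS"])].copy()
    for label, _ in GROUPS:
        if (analysis["overall_label"] == label).sum() == 0:
            raise ValueError(f"empty surveillance group {label}")

    analysis["followup_days"] = analysis["last_followup_day"] - analysis["final_treatment_day"]
    died = analysis["death_day"].notna()
    died_5y = died & (analysis["followup_days"] <= surv.FIVE_YEARS)
    analysis["vital_status_5y"] = np.where(died_5y, "deceased", "alive")
    analysis["censoring"] = (~died).astype(int)
    analysis["cancer_event"] = (died & (analysis["death_cause"] == "cancer")).astype(int)

    rows: list[dict] = []
    n_tot = {}
    for label, col in GROUPS:
        n_tot[col] = int((analysis["overall_label"] == label).sum())
    shares = percentages([n_tot["more_adherent"], n_tot["less_adherent"]])
    rows.append(
        {
            "characteristic": "study_population",
            "category": "",
            "more_adherent": f"{n_tot['more_adherent']} ({shares[0]})",
            "less_adherent": f"{n_tot['less_adherent']} ({shares[1]})",
            "p_value": "",
        }
    )
    rows.extend(_followup_rows(analysis))

    def add_block(frame: pd.DataFrame, characteristic: str, column: str):
        tab = pd.crosstab(frame[column].astype(str), frame["overall_label"])
        for label, _ in GROUPS:
            if label not in tab.columns:
                tab[label] = 0
        tab = tab[[g for g, _ in GROUPS]]
        chi2, dof, p = _chi_square(tab)
        pcts = {g: percentages(tab[g].tolist()) for g, _ in GROUPS}
        for i, category in enumerate(tab.index):
            rows.append(
                {
                    "characteristic": characteristic,
                    "category": str(category),
                    "more_adherent": f"{int(tab['MORE'].iloc[i])} ({pcts['MORE'][i]})",
                    "less_adherent": f"{int(tab['LESS'].iloc[i])} ({pcts['LESS'][i]})",
                    "p_value": format_p(p) if i == 0 else "",
                }
            )

    add_block(analysis, "vital_status_5y", "vital_status_5y")
    deceased = analysis[died_5y].assign(
        cause=lambda d: d["death_cause"].replace({"noncancer": "other"})
    )
    if not deceased.empty:
        add_block(deceased, "cause_of_death_5y", "cause")
    for cov in DESCRIPTIVE_COVARIATES:
        if cov in analysis.columns:
            add_block(analysis, cov, cov)
    return pd.DataFrame(rows)


def hr_summary(fits: Sequence[SurvivalFit | None], names: Sequence[str] | None = None) -> pd.DataFrame:
    """One formatted row per outcome: HR (95% CI), p, unweighted events."""
    rows = []
    for i, fit in enumerate(fits):
        if fit is None:
            rows.append(
                {
                    "outcome": names[i] if names else f"outcome_{i}",
                    "hr_ci": "unavailable",
                    "p_value": "",
                    "n_events": "",
                    "reference": "more_adherent",
                }
            )
            continue
        rows.append(
            {
                "outcome": fit.outcome,
                "hr_ci": format_hr_ci(fit.hr, fit.ci_lower, fit.ci_upper),
                "p_value": format_p(fit.p_value),
                "n_events": fit.n_events,
                "reference": "more_adherent",
            }
        )
    return pd.DataFrame(rows, columns=["outcome", "hr_ci", "p_value", "n_events", "reference"])


def run_pipeline(
    config: SynthConfig | None = None,
    outdir: str | os.PathLike = "artifacts",
    propensity_params: PropensityParams | None = None,
    input_dir: str | os.PathLike | None = None,
) -> dict:
    """Run the full analysis end to end and persist every stage's output.

    Either simulates a cohort from ``config`` or loads one from
    ``input_dir`` (fixture CSVs). Returns the manifest, which is also
    written to ``manifest.json`` along with: patients/claims tables, the
    per-year counts table, adherence profiles, weights and balance tables,
    survivor curves, fit JSONs, the descriptive table and the HR summary.
    """
    os.makedirs(outdir, exist_ok=True)
    stage = "simulate"
    try:
        if input_dir is not None:
            patients, claims = cohort_synth.read_fixture(input_dir)
            seed = None
        else:
            config = config or default_config()
            patients, claims, truth = cohort_synth.simulate_cohort(config)
            seed = config.seed
            cohort_synth.write_fixture(patients, claims, outdir, truth)

        stage = "claims_engine"
        counts = claims_engine.build_counts(patients, claims)
        counts.to_csv(os.path.join(outdir, "surveillance_counts.csv"), index=False)

        stage = "adherence"
        profiles = adherence.build_profiles(counts)
        profiles.to_csv(os.path.join(outdir, "adherence_profiles.csv"), index=False)

        stage = "weighting"
        cohort = weighting.weight_cohort(patients, profiles, propensity_params)
        cohort.table.to_csv(os.path.join(outdir, "weights.csv"), index=False)
        cohort.balance_unweighted.assign(stage="unweighted").pipe(
            lambda a: pd.concat([a, cohort.balance_weighted.assign(stage="weighted")])
        ).to_csv(os.path.join(outdir, "balance.csv"), index=False)

        stage = "survival"
        fits = []
        for spec in (OutcomeSpec.cancer_specific(), OutcomeSpec.noncancer_specific(), OutcomeSpec.overall()):
            table = surv.build_outcome(patients, counts, cohort.table, spec)
            fit = surv.weighted_cox(table, outcome_name=spec.name)
            fits.append(fit)
            for grp, curve in fit.curves.items():
                curve.assign(group=grp).to_csv(
                    os.path.join(outdir, f"km_{spec.name}_{grp}.csv"), index=False
                )
            with open(os.path.join(outdir, f"fit_{spec.name}.json"), "w") as fh:
                json.dump(fit.to_dict(), fh, indent=1)

        stage = "reporting"
        desc = descriptive_table(patients, counts, profiles)
        desc.to_csv(os.path.join(outdir, "descriptive_table.csv"), index=False)
        hr_summary(fits).to_csv(os.path.join(outdir, "hr_summary.csv"), index=False)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    label_counts = profiles["overall_label"].value_counts().to_dict()
    excl = profiles["exclusion_reason"].value_counts().to_dict()
    manifest = {
        "seed": seed,
        "n_simulated": int(len(patients)),
        "n_claims": int(len(claims)),
        "exclusions": {
            "no_complete_year": int(excl.get("no_complete_year", 0)),
            "nonadherent_all_years": int(excl.get("nonadherent_all_years", 0)),
        },
        "n_analyzed": int(label_counts.get("MORE", 0) + label_counts.get("LESS", 0)),
        "label_counts": {k: int(v) for k, v in label_counts.items()},
        "propensity_best_iteration": int(cohort.best_iteration),
        "max_weighted_asmd": float(cohort.balance_weighted["asmd"].max()),
        "hazard_ratios": {f.outcome: f.to_dict() for f in fits},
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
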