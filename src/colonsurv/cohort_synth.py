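"""Seeded synthetic patient and claims tables with confounding by indication.

The generator draws, per patient: categorical covariates from configured
margins; independent comorbid-condition flags; chemotherapy receipt from a
logistic model; a latent surveillance-intensity class ("high"/"low") from a
logistic propensity model on prognostic covariates; a surgery claim, a
chemotherapy claim sequence for chemotherapy recipients, and per-modality
surveillance claims whose yearly Poisson means depend on the latent class;
and competing cancer/noncancer death times from two independent
cause-specific hazards (exponential by default, Weibull configurable), the
observed cause being whichever fires first, with administrative censoring.

The latent intensity class is the generator's treatment variable; the
observed More/Less Adherent label emerges downstream from the claims
classifier, so pipeline tests exercise the full classification path rather
than injected labels.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .claims_engine import YEAR_DAYS, final_treatment_date
from .config import GroundTruth, SynthConfig

__all__ = ["simulate_cohort", "write_fixture", "read_fixture"]

PATIENT_FILE = "patients.csv"
CLAIMS_FILE = "claims.csv"
TRUTH_FILE = "ground_truth.json"


def _linear_predictor(patients: pd.DataFrame, coefficients: dict[str, float]) -> np.ndarray:
    """Evaluate an "intercept" + sum(coef * indicator) model on the table.

    Keys: ``"col=value"`` indicator of a categorical level, a bare column
    name for numeric/0-1 columns (``"chemo"``, ``"comorbidity_count"``),
    or ``"intercept"``.
    """
    lp = np.full(len(patients), float(coefficients.get("intercept", 0.0)))
    for key, coef in coefficients.items():
        if key == "intercept":
            continue
        if "=" in key:
            col, val = key.split("=", 1)
            x = (patients[col].astype(str) == val).to_numpy(float)
        else:
            x = patients[key].to_numpy(float)
        lp += coef * x
    return lp


def _draw_event_times(
    rng: np.random.Generator, rates_per_year: np.ndarray, dist: str, shape: float
) -> np.ndarray:
    """Event times in days for a proportional-hazards exponential/Weibull."""
    u = rng.uniform(size=len(rates_per_year))
    if dist == "exponential":
        t_years = -np.log(u) / rates_per_year
    else:  # Weibull with scale chosen so the rate parameter is the yearly scale rate
        t_years = (-np.log(u) / rates_per_year) ** (1.0 / shape)
    return t_years * YEAR_DAYS


def _chemo_schedule(rng: np.random.Generator, surgery_day: int) -> list[int]:
    """One adjuvant chemotherapy claim sequence.

    Courses start 14-60 days post-surgery with 4-12 cycles at 14-28 day
    gaps, so long courses exceed the 183-day cap; a minority of courses are
    interrupted by a > 90-day break (claims after the break belong to a
    resumed course the anchoring rule ignores).
    """
    start = surgery_day + int(rng.integers(14, 61))
    n_cycles = int(rng.integers(4, 13))
    gaps = rng.integers(14, 29, size=n_cycles - 1)
    if n_cycles >= 4 and rng.uniform() < 0.12:
        gaps[rng.integers(1, n_cycles - 1)] = int(rng.integers(100, 220))
    return (start + np.concatenate([[0], np.cumsum(gaps)])).astype(int).tolist()


def simulate_cohort(config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw one cohort: (patient table, claims table, ground truth).

    Deterministic in ``(config, config.seed)``. Raises if either latent
    intensity class ends up with fewer than two patients.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    patients = pd.DataFrame({"patient_id": [f"P{i:06d}" for i in range(n)]})
    for cov, margins in config.covariate_margins.items():
        cats = list(margins)
        probs = np.array([margins[c] for c in cats], dtype=float)
        patients[cov] = rng.choice(cats, size=n, p=probs / probs.sum())
    for cond, prev in config.comorbidity_prevalence.items():
        patients[cond] = (rng.uniform(size=n) < prev).astype(int)
    cond_cols = list(config.comorbidity_prevalence)
    patients["comorbidity_count"] = patients[cond_cols].sum(axis=1) if cond_cols else 0

    p_chemo = 1.0 / (1.0 + np.exp(-_linear_predictor(patients, config.chemo_coefficients)))
    patients["chemo"] = (rng.uniform(size=n) < p_chemo).astype(int)

    true_propensity = 1.0 / (
        1.0 + np.exp(-_linear_predictor(patients, config.propensity_coefficients))
    )
    high = rng.uniform(size=n) < true_propensity
    if high.sum() < 2 or (~high).sum() < 2:
        raise ValueError("need at least 2 patients per latent intensity class")

    # -- treatment claims --------------------------------------------------
    surgery_days = rng.integers(0, 28, size=n)
    claim_pid: list[str] = []
    claim_type: list[str] = []
    claim_day: list[int] = []
    final_days = np.empty(n, dtype=int)
    for i in range(n):
        pid = patients.at[i, "patient_id"]
        claim_pid.append(pid)
        claim_type.append("surgery")
        claim_day.append(int(surgery_days[i]))
        chemo_days: list[int] = []
        if patients.at[i, "chemo"]:
            chemo_days = _chemo_schedule(rng, int(surgery_days[i]))
            claim_pid.extend([pid] * len(chemo_days))
            claim_type.extend(["chemo"] * len(chemo_days))
            claim_day.extend(chemo_days)
        final_days[i] = final_treatment_date(int(surgery_days[i]), chemo_days).final_treatment_day

    # -- competing cause-specific death times ------------------------------
    cz = config.cancer_hazard
    nz = config.noncancer_hazard
    log_cancer = np.log(cz.base_rate) + _linear_predictor(patients, cz.coefficients)
    log_cancer += config.true_group_effect_cancer * high.astype(float)
    if config.latent_risk_sd > 0:
        log_cancer += rng.normal(0.0, config.latent_risk_sd, size=n)
    log_noncancer = np.log(nz.base_rate) + _linear_predictor(patients, nz.coefficients)
    t_cancer = _draw_event_times(rng, np.exp(log_cancer), cz.dist, cz.shape)
    t_noncancer = _draw_event_times(rng, np.exp(log_noncancer), nz.dist, nz.shape)

    t_death = np.minimum(t_cancer, t_noncancer)
    cause = np.where(t_cancer <= t_noncancer, "cancer", "noncancer")
    horizon = int(round(config.admin_censor_years * YEAR_DAYS))
    censor_day = final_days + horizon
    death_day = final_days + np.maximum(np.round(t_death).astype(int), 1)
    died = death_day < censor_day
    patients["death_day"] = pd.array(
        np.where(died, death_day, -1), dtype="Int64"
    )
    patients.loc[~died, "death_day"] = pd.NA
    patients["death_cause"] = np.where(died, cause, "")
    patients["censor_day"] = censor_day
    last_day = np.where(died, death_day, censor_day)

    # -- surveillance claims ----------------------------------------------
    class_names = np.where(high, "high", "low")
    modality_event = {"cea": "CEA", "ct": "CT", "scope": "colonoscopy"}
    for modality, class_rates in config.test_rate_params.items():
        n_years = len(next(iter(class_rates.values())))
        for k in range(n_years):
            means = np.array([class_rates[c][k] for c in class_names])
            counts = rng.poisson(means)
            for i in np.nonzero(counts)[0]:
                start = final_days[i] + k * YEAR_DAYS
                days = start + rng.integers(0, YEAR_DAYS, size=counts[i])
                days = days[days < last_day[i]]
                for d in np.sort(days):
                    etype = modality_event[modality]
                    if modality == "ct" and rng.uniform() < config.ct_pet_fraction:
                        etype = "PET"
                    claim_pid.append(patients.at[i, "patient_id"])
                    claim_type.append(etype)
                    claim_day.append(int(d))

    claims = (
        pd.DataFrame({"patient_id": claim_pid, "event_type": claim_type, "service_day": claim_day})
        .sort_values(["patient_id", "service_day", "event_type"], kind="mergesort")
        .reset_index(drop=True)
    )
    truth = GroundTruth(
        per_patient=pd.DataFrame(
            {
                "patient_id": patients["patient_id"],
                "high_intensity": high.astype(int),
                "true_propensity": true_propensity,
            }
        ),
        true_group_effect_cancer=config.true_group_effect_cancer,
        cancer_hazard=cz,
        noncancer_hazard=nz,
    )
    return patients, claims, truth


# -- fixture round trip ----------------------------------------------------

def write_fixture(
    patients: pd.DataFrame,
    claims: pd.DataFrame,
    path: str | os.PathLike,
    truth: GroundTruth | None = None,
) -> None:
    """Write the cohort as CSVs (plus optional ground-truth JSON) under ``path``."""
    os.makedirs(path, exist_ok=True)
    patients.to_csv(os.path.join(path, PATIENT_FILE), index=False)
    claims.to_csv(os.path.join(path, CLAIMS_FILE), index=False)
    if truth is not None:
        truth.to_json(os.path.join(path, TRUTH_FILE))


def read_fixture(path: str | os.PathLike) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a cohort written by :func:`write_fixture`, validating row types.

    Malformed rows are reported with their (0-based) row numbers.
    """
    patients = pd.read_csv(
        os.path.join(path, PATIENT_FILE), dtype={"patient_id": str}, keep_default_na=False,
        na_values=[""],
    )
    if "death_day" in patients.columns:
        patients["death_day"] = pd.array(patients["death_day"], dtype="Int64")
    if "death_cause" in patients.columns:
        patients["death_cause"] = patients["death_cause"].fillna("")
    claims = pd.read_csv(os.path.join(path, CLAIMS_FILE), dtype={"patient_id": str})
    bad = claims.index[
        pd.to_numeric(claims["service_day"], errors="coerce").isna()
    ].tolist()
    if bad:
        raise ValueError(f"claims rows with non-numeric service_day: {bad}")
    claims["service_day"] = claims["service_day"].astype(int)
    from .config import EVENT_TYPES

    bad = claims.index[~claims["event_type"].isin(EVENT_TYPES)].tolist()
    if bad:
        raise ValueError(f"claims rows with unknown event_type: {bad}")
    return patients, claims
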