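"""IPTW-weighted survival analysis: Kaplan-Meier, log-rank, cause-specific Cox.

Outcomes are defined from the final treatment date: 5-year cancer-specific
mortality (noncancer deaths censored at death), 5-year noncancer-specific
mortality restricted to years 2-5 (delayed entry at day 365), and 5-year
overall mortality. All estimators take per-patient case weights and reduce
exactly to their classical forms at unit weights.

The weighted Cox model is fit by partial likelihood with case weights
(Efron ties, delayed entry) and a robust cluster sandwich variance for the
confidence interval; the hazard ratio is reported for Less vs. More
Adherent (More Adherent is the reference group).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test
from scipy import stats

from .claims_engine import YEAR_DAYS

__all__ = [
    "OutcomeSpec",
    "SurvivalFit",
    "build_outcome",
    "weighted_km",
    "weighted_logrank",
    "weighted_cox",
    "ph_check",
    "km_quantile",
    "reverse_km_median",
]

FIVE_YEARS = 5 * YEAR_DAYS


@dataclass(frozen=True)
class OutcomeSpec:
    """One outcome definition: which causes are events, entry, horizon."""

    name: str
    event_causes: frozenset[str]
    entry_day: int = 0
    horizon_day: int = FIVE_YEARS

    def __post_init__(self):
        if not self.entry_day < self.horizon_day:
            raise ValueError("entry must precede the horizon")

    @staticmethod
    def cancer_specific() -> "OutcomeSpec":
        return OutcomeSpec("cancer_specific", frozenset({"cancer"}))

    @staticmethod
    def noncancer_specific() -> "OutcomeSpec":
        """Noncancer mortality for years 2-5 (delayed entry at day 365)."""
        return OutcomeSpec("noncancer_specific", frozenset({"noncancer"}), entry_day=YEAR_DAYS)

    @staticmethod
    def overall() -> "OutcomeSpec":
        return OutcomeSpec("overall", frozenset({"cancer", "noncancer"}))


@dataclass
class SurvivalFit:
    """Hazard ratio and weighted survivor curves for one outcome."""

    outcome: str
    hr: float
    ci_lower: float
    ci_upper: float
    se_log_hr: float
    p_value: float
    n_events: int  # unweighted event count
    curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "hr": self.hr,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "se_log_hr": self.se_log_hr,
            "p_value": self.p_value,
            "n_events": self.n_events,
            "converged": self.converged,
        }


def build_outcome(
    patients: pd.DataFrame,
    counts: pd.DataFrame,
    weighted: pd.DataFrame,
    spec: OutcomeSpec,
) -> pd.DataFrame:
    """Assemble the (time, event, group, weight) analysis table.

    Times are days from the final treatment date. Deaths after the horizon
    and deaths from causes outside the event rule are censored; patients
    whose follow-up ends at or before the entry day are dropped (they never
    enter the risk set). ``weighted`` is the per-patient table of the
    weighting stage (patient_id, treatment, weight) and already excludes
    non-analyzable patients.
    """
    df = weighted.merge(
        counts[["patient_id", "final_treatment_day", "last_followup_day"]],
        on="patient_id",
        validate="one_to_one",
    ).merge(patients[["patient_id", "death_day", "death_cause"]], on="patient_id")

    time = (df["last_followup_day"] - df["final_treatment_day"]).to_numpy(int)
    died = df["death_day"].notna().to_numpy()
    cause = df["death_cause"].fillna("").to_numpy()
    if (time <= 0).any():
        raise ValueError("follow-up must extend beyond the final treatment date")

    event = died & np.isin(cause, list(spec.event_causes)) & (time <= spec.horizon_day)
    time = np.minimum(time, spec.horizon_day)
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "time": time,
            "event": event.astype(int),
            "entry": spec.entry_day,
            "group": df["treatment"].astype(int),  # 1 = More Adherent
            "weight": df["weight"].astype(float),
        }
    )
    return out[out["time"] > spec.entry_day].reset_index(drop=True)


def weighted_km(
    time: np.ndarray,
    event: np.ndarray,
    weights: np.ndarray | None = None,
    entry: np.ndarray | None = None,
) -> pd.DataFrame:
    """Weighted product-limit survivor curve with optional delayed entry.

    At each distinct event time ``t`` the at-risk mass sums the weights of
    subjects with ``entry < t <= time``; the curve multiplies
    ``1 - d(t)/n(t)`` over event times. At unit weights this is the
    classical Kaplan-Meier estimator. Returns columns ``time``,
    ``survival``, ``at_risk``, ``events`` (a right-continuous step
    function; survival is 1 before the first event time).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    w = np.ones_like(time) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    ent = np.zeros_like(time) if entry is None else np.asarray(entry, dtype=float)

    event_times = np.unique(time[event == 1])
    if event_times.size == 0:
        warnings.warn("no events; survivor curve is flat at 1")
    surv = 1.0
    rows = []
    for t in event_times:
        at_risk = w[(ent < t) & (time >= t)].sum()
        d = w[(time == t) & (event == 1)].sum()
        surv *= 1.0 - d / at_risk
        rows.append({"time": t, "survival": surv, "at_risk": at_risk, "events": d})
    return pd.DataFrame(rows, columns=["time", "survival", "at_risk", "events"])


def weighted_logrank(
    time: np.ndarray,
    event: np.ndarray,
    group: np.ndarray,
    weights: np.ndarray | None = None,
    entry: np.ndarray | None = None,
) -> tuple[float, float]:
    """Two-group log-rank test on weighted risk sets: (chi2 statistic, p).

    Observed-minus-expected events in group 1 are accumulated over event
    times with weighted counts and the hypergeometric variance; at unit
    weights this is the classical log-rank test. With IPTW weights the
    statistic treats weights as frequencies — the robust Cox Wald test of
    :func:`weighted_cox` is the primary inference.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=int)
    if len(np.unique(group)) < 2:
        raise ValueError("log-rank test needs two groups")
    w = np.ones_like(time) if weights is None else np.asarray(weights, dtype=float)
    ent = np.zeros_like(time) if entry is None else np.asarray(entry, dtype=float)

    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = (ent < t) & (time >= t)
        n = w[at_risk].sum()
        n1 = w[at_risk & (group == 1)].sum()
        dying = (time == t) & (event == 1)
        d = w[dying].sum()
        d1 = w[dying & (group == 1)].sum()
        if n <= 1 or d == 0:
            continue
        o_minus_e += d1 - d * n1 / n
        var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def weighted_cox(table: pd.DataFrame, outcome_name: str = "") -> SurvivalFit:
    """Weighted Cox model for Less vs. More Adherent with robust variance.

    Fits the partial likelihood with case weights (Efron ties, delayed
    entry when the table carries a positive ``entry``) and a cluster-robust
    sandwich variance by patient. The single covariate is the indicator of
    the Less Adherent group, so the reported HR is Less vs. More (More =
    reference).
    """
    for g in (0, 1):
        if table.loc[table["group"] == g, "event"].sum() < 1:
            raise ValueError("each group needs at least one event")
    df = pd.DataFrame(
        {
            "time": table["time"].astype(float),
            "event": table["event"].astype(int),
            "less_adherent": (1 - table["group"]).astype(int),
            "weight": table["weight"].astype(float),
            "cluster": np.arange(len(table)),
        }
    )
    use_entry = "entry" in table.columns and (np.asarray(table["entry"]) > 0).any()
    if use_entry:
        df["entry"] = table["entry"].astype(float)

    cph = CoxPHFitter()
    fit_kwargs = dict(
        duration_col="time",
        event_col="event",
        weights_col="weight",
        cluster_col="cluster",
        robust=True,
        formula="less_adherent",
        fit_options={"precision": 1e-11},
    )
    if use_entry:
        fit_kwargs["entry_col"] = "entry"
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, **fit_kwargs)
        except Exception as err:  # monotone likelihood / non-convergence
            raise RuntimeError(f"weighted Cox fit failed: {err}") from err

    beta = float(cph.params_["less_adherent"])
    se = float(cph.standard_errors_["less_adherent"])
    z = beta / se
    curves = {}
    for label, g in (("more_adherent", 1), ("less_adherent", 0)):
        sub = table[table["group"] == g]
        curves[label] = weighted_km(
            sub["time"], sub["event"], sub["weight"],
            entry=sub["entry"] if "entry" in sub.columns else None,
        )
    return SurvivalFit(
        outcome=outcome_name,
        hr=float(np.exp(beta)),
        ci_lower=float(np.exp(beta - 1.959963984540054 * se)),
        ci_upper=float(np.exp(beta + 1.959963984540054 * se)),
        se_log_hr=se,
        p_value=float(2 * stats.norm.sf(abs(z))),
        n_events=int(table["event"].sum()),
        curves=curves,
        converged=converged,
    )


def ph_check(table: pd.DataFrame) -> dict:
    """Proportional-hazards diagnostics for the surveillance-group effect.

    Returns the score test for a group x log(time) interaction (via scaled
    Schoenfeld residuals against log time) and the log(-log S) vs. log(t)
    curve pairs used for the graphical check.
    """
    df = pd.DataFrame(
        {
            "time": table["time"].astype(float),
            "event": table["event"].astype(int),
            "less_adherent": (1 - table["group"]).astype(int),
            "weight": table["weight"].astype(float),
        }
    )
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(
            df, duration_col="time", event_col="event", weights_col="weight",
            formula="less_adherent",
        )
        res = proportional_hazard_test(cph, df, time_transform="log")
    loglog = {}
    for label, g in (("more_adherent", 1), ("less_adherent", 0)):
        sub = table[table["group"] == g]
        curve = weighted_km(sub["time"], sub["event"], sub["weight"])
        ok = (curve["survival"] > 0) & (curve["survival"] < 1)
        loglog[label] = pd.DataFrame(
            {
                "log_time": np.log(curve.loc[ok, "time"]),
                "log_neg_log_survival": np.log(-np.log(curve.loc[ok, "survival"])),
            }
        )
    return {
        "interaction_p": float(np.asarray(res.p_value).reshape(-1)[0]),
        "interaction_stat": float(np.asarray(res.test_statistic).reshape(-1)[0]),
        "loglog_curves": loglog,
    }


def km_quantile(curve: pd.DataFrame, q: float) -> float | None:
    """Smallest time at which the survivor curve drops to ``1 - q``.

    ``None`` means the quantile was not reached within follow-up.
    """
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    hit = curve[curve["survival"] <= 1 - q]
    return None if hit.empty else float(hit["time"].iloc[0])


def reverse_km_median(
    time: np.ndarray, death: np.ndarray, weights: np.ndarray | None = None
) -> float | None:
    """Median follow-up by reverse Kaplan-Meier (censoring as the event)."""
    censored = 1 - np.asarray(death, dtype=int)
    curve = weighted_km(time, censored, weights)
    return km_quantile(curve, 0.5) if not curve.empty else None
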