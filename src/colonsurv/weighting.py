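"""Boosted-model propensity scores, ATE inverse-probability weights, balance.

The exposure is the overall surveillance label (1 = More Adherent, 0 =
Less Adherent). Propensity scores come from gradient-boosted classification
trees; the number of boosting iterations is chosen to minimise the mean
absolute standardized mean difference (ASMD) of the implied ATE weights —
balance-driven stopping in the style of the boosted-propensity literature.
Balance is assessed per covariate indicator for each group against the
*unweighted study-population* mean, in units of the unweighted population
standard deviation; ASMD >= 0.20 flags imbalance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier

__all__ = [
    "PropensityParams",
    "WeightedCohort",
    "build_covariate_matrix",
    "fit_propensity",
    "compute_iptw",
    "balance_table",
    "weight_cohort",
]

#: ASMD at or above which a covariate is flagged as imbalanced.
IMBALANCE_THRESHOLD = 0.20

#: Patient-table columns expanded into the default covariate matrix.
CATEGORICAL_COVARIATES = [
    "age_group", "race", "sex", "marital_status", "dx_year_group", "buyin",
    "poverty", "urban_rural", "region", "substage", "grade", "tumor_site",
]
FLAG_COVARIATES = ["chemo", "chf", "copd", "diabetes", "mi", "pvd", "cvd", "renal", "dementia"]


@dataclass
class PropensityParams:
    """Boosting hyper-parameters and the balance-stopping schedule.

    Defaults: interaction depth 3, learning rate 0.01, 50% subsampling, at
    most 5000 trees with balance evaluated every 100; fitting stops early
    once the mean ASMD has not improved for ``patience`` consecutive
    evaluations. Propensities are clipped to ``[eps, 1 - eps]``.
    """

    max_trees: int = 5000
    learning_rate: float = 0.01
    max_depth: int = 3
    subsample: float = 0.5
    eval_every: int = 100
    patience: int = 5
    eps: float = 1e-3
    seed: int = 0


@dataclass
class WeightedCohort:
    """Per-patient exposure, propensity and ATE weight plus balance tables."""

    table: pd.DataFrame  # patient_id, treatment, propensity, weight
    balance_unweighted: pd.DataFrame
    balance_weighted: pd.DataFrame
    best_iteration: int = 0
    mean_asmd_path: list[tuple[int, float]] = field(default_factory=list)

    @property
    def weights(self) -> np.ndarray:
        return self.table["weight"].to_numpy()


def build_covariate_matrix(
    patients: pd.DataFrame,
    categorical: Sequence[str] = CATEGORICAL_COVARIATES,
    flags: Sequence[str] = FLAG_COVARIATES,
) -> pd.DataFrame:
    """Expand pre-treatment covariates to a 0/1 indicator matrix.

    Every category — including any "unknown" level — gets its own
    indicator; 0/1 flag columns pass through. Constant columns are dropped
    with a warning (they carry no balancing information).
    """
    pieces = []
    cats = [c for c in categorical if c in patients.columns]
    if cats:
        dummies = pd.get_dummies(patients[cats].astype(str), prefix_sep="=").astype(int)
        pieces.append(dummies)
    present_flags = [c for c in flags if c in patients.columns]
    if present_flags:
        pieces.append(patients[present_flags].astype(int))
    if not pieces:
        raise ValueError("no recognised covariate columns in patient table")
    X = pd.concat(pieces, axis=1)
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping constant covariate indicators: {constant}")
        X = X.drop(columns=constant)
    return X


def compute_iptw(e: np.ndarray, T: np.ndarray, stabilize: bool = False) -> np.ndarray:
    """ATE weights: ``w = T/e + (1-T)/(1-e)``.

    With ``stabilize``, weights are normalised to mean 1 within each
    treatment group (off by default).
    """
    e = np.asarray(e, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any((e <= 0) | (e >= 1)):
        raise ValueError("propensities must lie strictly inside (0, 1)")
    w = T / e + (1 - T) / (1 - e)
    if stabilize:
        for t in (0, 1):
            mask = T == t
            w[mask] /= w[mask].mean()
    return w


def balance_table(
    X: pd.DataFrame, T: np.ndarray, weights: np.ndarray | None = None
) -> pd.DataFrame:
    """ASMD of each covariate indicator, per group, vs. the population mean.

    The reference mean and SD are always those of the *unweighted* full
    study population; ``weights`` (if given) enter only the group means.
    Returns one row per (covariate, group) with the ASMD and an imbalance
    flag at 0.20. A zero-variance covariate yields ASMD 0 with a warning.
    """
    T = np.asarray(T, dtype=int)
    if len(X) != len(T):
        raise ValueError("X and T length mismatch")
    w = np.ones(len(X)) if weights is None else np.asarray(weights, dtype=float)
    if len(w) != len(X):
        raise ValueError("weights length mismatch")

    vals = X.to_numpy(float)
    pop_mean = vals.mean(axis=0)
    pop_sd = vals.std(axis=0, ddof=1)
    zero_sd = pop_sd == 0
    if zero_sd.any():
        warnings.warn("zero-variance covariates; their ASMD is reported as 0")

    rows = []
    for t, group in ((1, "more_adherent"), (0, "less_adherent")):
        mask = T == t
        gw = w[mask]
        gmean = (vals[mask] * gw[:, None]).sum(axis=0) / gw.sum()
        with np.errstate(invalid="ignore"):
            asmd = np.abs(gmean - pop_mean) / pop_sd
        asmd[zero_sd] = 0.0
        for j, cov in enumerate(X.columns):
            rows.append(
                {
                    "covariate": cov,
                    "group": group,
                    "group_mean": gmean[j],
                    "population_mean": pop_mean[j],
                    "asmd": asmd[j],
                    "imbalanced": bool(asmd[j] >= IMBALANCE_THRESHOLD),
                }
            )
    return pd.DataFrame(rows)


def _mean_asmd(X: pd.DataFrame, T: np.ndarray, weights: np.ndarray) -> float:
    tbl = balance_table(X, T, weights)
    return float(tbl["asmd"].mean())


def fit_propensity(
    X: pd.DataFrame, T: np.ndarray, params: PropensityParams | None = None
) -> tuple[np.ndarray, int, list[tuple[int, float]]]:
    """Gradient-boosted propensity with balance-driven stopping.

    Grows the boosted ensemble ``eval_every`` trees at a time, evaluating
    the mean ASMD of the implied ATE weights at each checkpoint (iteration
    0 = the marginal treatment rate, i.e. an intercept-only model), and
    returns the propensities of the best checkpoint, clipped to
    ``[eps, 1-eps]``: ``(e, best_iteration, [(iteration, mean_asmd), ...])``.
    """
    params = params or PropensityParams()
    T = np.asarray(T, dtype=int)
    if T.min() == T.max():
        raise ValueError("both treatment groups must be non-empty")

    # checkpoint 0: intercept-only propensity = marginal treatment rate
    e0 = np.full(len(T), T.mean())
    best_e = e0
    best_iter = 0
    path = [(0, _mean_asmd(X, T, compute_iptw(e0, T)))]
    best_asmd = path[0][1]

    model = GradientBoostingClassifier(
        n_estimators=0,
        learning_rate=params.learning_rate,
        max_depth=params.max_depth,
        subsample=params.subsample,
        random_state=params.seed,
        warm_start=True,
    )
    stale = 0
    n_trees = 0
    while n_trees < params.max_trees:
        n_trees = min(n_trees + params.eval_every, params.max_trees)
        model.set_params(n_estimators=n_trees)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X.to_numpy(float), T)
        e = np.clip(model.predict_proba(X.to_numpy(float))[:, 1], params.eps, 1 - params.eps)
        asmd = _mean_asmd(X, T, compute_iptw(e, T))
        path.append((n_trees, asmd))
        if asmd < best_asmd - 1e-9:
            best_asmd, best_e, best_iter = asmd, e, n_trees
            stale = 0
        else:
            stale += 1
            if stale >= params.patience:
                break
    if best_e.min() <= params.eps or best_e.max() >= 1 - params.eps:
        warnings.warn("propensities at the clipping bounds; extreme weights truncated")
    return np.clip(best_e, params.eps, 1 - params.eps), best_iter, path


def weight_cohort(
    patients: pd.DataFrame,
    profiles: pd.DataFrame,
    params: PropensityParams | None = None,
) -> WeightedCohort:
    """Full weighting stage: covariates -> propensity -> weights -> balance.

    Joins the overall adherence labels onto the patient table, drops
    excluded patients, fits the boosted propensity of being More Adherent,
    and returns the weighted cohort with unweighted and weighted balance
    tables.
    """
    merged = patients.merge(
        profiles[["patient_id", "overall_label"]], on="patient_id", validate="one_to_one"
    )
    analysis = merged[merged["overall_label"].isin(["MORE", "LESS"])].reset_index(drop=True)
    if analysis.empty:
        raise ValueError("no analyzable patients (all excluded)")
    T = (analysis["overall_label"] == "MORE").to_numpy(int)
    X = build_covariate_matrix(analysis)
    e, best_iter, path = fit_propensity(X, T, params)
    w = compute_iptw(e, T)
    table = pd.DataFrame(
        {
            "patient_id": analysis["patient_id"],
            "treatment": T,
            "propensity": e,
            "weight": w,
        }
    )
    return WeightedCohort(
        table=table,
        balance_unweighted=balance_table(X, T, None),
        balance_weighted=balance_table(X, T, w),
        best_iteration=best_iter,
        mean_asmd_path=path,
    )
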