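"""Configuration types for the synthetic claims-cohort generator.

The generator emulates an administrative-claims cohort of elderly stage
II/III colon cancer patients: categorical demographic and tumor covariates,
individual comorbid-condition flags, a latent surveillance-intensity class
whose probability depends on prognostic covariates (confounding by
indication), per-modality surveillance-claim streams, and two competing
cause-specific death processes (cancer vs. noncancer).

All dates are integer day offsets from a nominal diagnosis epoch; calendar
rendering is presentation-only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

import yaml

__all__ = ["HazardParams", "SynthConfig", "GroundTruth", "default_config"]

#: Event-type vocabulary for the claims table.
EVENT_TYPES = ("surgery", "chemo", "CEA", "CT", "PET", "colonoscopy")

#: Surveillance modalities after CT/PET pooling.
MODALITIES = ("cea", "ct", "scope")


@dataclass
class HazardParams:
    """One cause-specific hazard: baseline rate plus log-hazard coefficients.

    ``base_rate`` is in events per person-year. ``coefficients`` maps
    covariate indicators (``"column=value"`` for categoricals, a bare column
    name for 0/1 flags, or ``"comorbidity_count"``) to log-hazard
    contributions. ``dist`` selects exponential or Weibull event times;
    ``shape`` is the Weibull shape (ignored for exponential).
    """

    base_rate: float
    coefficients: dict[str, float] = field(default_factory=dict)
    dist: str = "exponential"
    shape: float = 1.0

    def validate(self) -> None:
        if self.base_rate <= 0:
            raise ValueError(f"base_rate must be strictly positive, got {self.base_rate}")
        if self.dist not in ("exponential", "weibull"):
            raise ValueError(f"dist must be 'exponential' or 'weibull', got {self.dist!r}")
        if self.shape <= 0:
            raise ValueError("Weibull shape must be strictly positive")


@dataclass
class SynthConfig:
    """Full parameterisation of one synthetic cohort draw.

    Parameters
    ----------
    n_patients, seed
        Cohort size and the seed for the single generator stream; identical
        ``(config, seed)`` pairs produce byte-identical output tables.
    covariate_margins
        Per categorical covariate, the category -> probability map
        (probabilities must sum to 1).
    comorbidity_prevalence
        Marginal prevalence of each individual comorbid-condition flag
        (conditions drawn independently; the count of flags is the
        comorbidity burden used by the noncancer hazard).
    chemo_coefficients
        Log-odds model for receipt of adjuvant chemotherapy (key
        ``"intercept"`` plus covariate indicators).
    propensity_coefficients
        Log-odds model for the latent high-surveillance-intensity class —
        this is where confounding by indication lives.
    test_rate_params
        ``modality -> class -> [year-1, year-2, year-3]`` Poisson means for
        surveillance-claim counts per post-treatment year, with classes
        ``"high"`` and ``"low"``.
    cancer_hazard, noncancer_hazard
        Competing cause-specific hazards; the observed cause is the argmin
        of the two latent event times.
    true_group_effect_cancer
        Log hazard ratio of the high-intensity class on cancer death
        (0 = surveillance intensity has no causal effect on cancer death).
    latent_risk_sd
        Standard deviation of an optional normal log-frailty added to the
        cancer log-hazard (0 disables it).
    admin_censor_years
        Administrative censoring horizon, in years after final treatment.
    ct_pet_fraction
        Fraction of imaging claims emitted with event type ``PET`` rather
        than ``CT`` (the two are pooled downstream).
    """

    n_patients: int = 2000
    seed: int = 0
    covariate_margins: dict[str, dict[str, float]] = field(default_factory=dict)
    comorbidity_prevalence: dict[str, float] = field(default_factory=dict)
    chemo_coefficients: dict[str, float] = field(default_factory=dict)
    propensity_coefficients: dict[str, float] = field(default_factory=dict)
    test_rate_params: dict[str, dict[str, list[float]]] = field(default_factory=dict)
    cancer_hazard: HazardParams = field(default_factory=lambda: HazardParams(0.025))
    noncancer_hazard: HazardParams = field(default_factory=lambda: HazardParams(0.015))
    true_group_effect_cancer: float = 0.0
    latent_risk_sd: float = 0.0
    admin_censor_years: float = 10.0
    ct_pet_fraction: float = 0.15

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be a positive integer")
        for cov, margins in self.covariate_margins.items():
            total = sum(margins.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"category probabilities for {cov!r} sum to {total}, not 1")
            if any(p < 0 for p in margins.values()):
                raise ValueError(f"negative category probability for {cov!r}")
        for cond, p in self.comorbidity_prevalence.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence for {cond!r} outside [0, 1]")
        for modality, classes in self.test_rate_params.items():
            for cls, rates in classes.items():
                if any(r <= 0 for r in rates):
                    raise ValueError(f"non-positive test rate for {modality}/{cls}")
        self.cancer_hazard.validate()
        self.noncancer_hazard.validate()
        if self.admin_censor_years <= 0:
            raise ValueError("admin_censor_years must be strictly positive")
        if not 0 <= self.ct_pet_fraction <= 1:
            raise ValueError("ct_pet_fraction outside [0, 1]")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SynthConfig":
        d = dict(d)
        for key in ("cancer_hazard", "noncancer_hazard"):
            if key in d and isinstance(d[key], Mapping):
                d[key] = HazardParams(**d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """Generator-side truth retained for recovery tests.

    ``per_patient`` records, per patient id, the latent intensity class and
    the true propensity of that class; the scalars echo the causal and
    hazard parameters the cohort was drawn under.
    """

    per_patient: "pandas.DataFrame"  # noqa: F821 - forward ref, avoids import cycle
    true_group_effect_cancer: float
    cancer_hazard: HazardParams
    noncancer_hazard: HazardParams

    def to_json(self, path) -> None:
        payload = {
            "true_group_effect_cancer": self.true_group_effect_cancer,
            "cancer_hazard": dataclasses.asdict(self.cancer_hazard),
            "noncancer_hazard": dataclasses.asdict(self.noncancer_hazard),
            "per_patient": self.per_patient.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        import pandas as pd

        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            per_patient=pd.DataFrame(payload["per_patient"]),
            true_group_effect_cancer=payload["true_group_effect_cancer"],
            cancer_hazard=HazardParams(**payload["cancer_hazard"]),
            noncancer_hazard=HazardParams(**payload["noncancer_hazard"]),
        )


def default_config(n_patients: int = 2000, seed: int = 0) -> SynthConfig:
    """Default study conditions: an elderly stage II/III colon cancer cohort.

    Covariate margins follow the overall distribution of a large US registry-
    claims population of this kind (the two surveillance groups' printed
    columns pooled); surveillance intensity is confounded with prognosis
    (stage, grade, chemotherapy receipt raise it; advanced age, Medicaid
    buy-in and comorbidity lower it); cancer mortality is driven by stage,
    grade and chemotherapy, noncancer mortality by age and comorbidity
    burden. The true causal effect of surveillance intensity on cancer death
    is zero by default.
    """
    margins = {
        "age_group": {"66-74": 0.444, "75-79": 0.291, "80-84": 0.265},
        "race": {
            "white": 0.846, "black": 0.084, "asian": 0.033,
            "other": 0.019, "hispanic": 0.014, "native_american": 0.003,
            "unknown": 0.001,
        },
        "sex": {"female": 0.559, "male": 0.441},
        "marital_status": {
            "married": 0.548, "separated_divorced": 0.067, "single": 0.078,
            "widowed": 0.275, "unknown": 0.032,
        },
        "dx_year_group": {"2002-2003": 0.293, "2004-2006": 0.378, "2007-2009": 0.329},
        "buyin": {"no": 0.777, "yes": 0.223},
        "poverty": {
            "low": 0.268, "lower_middle": 0.275, "upper_middle": 0.277,
            "high": 0.176, "unknown": 0.004,
        },
        "urban_rural": {"urban": 0.872, "less_urban": 0.104, "rural": 0.024},
        "region": {
            "west": 0.361, "south": 0.260, "northeast": 0.218,
            "midwest": 0.147, "pacific": 0.014,
        },
        "substage": {"II": 0.56, "III": 0.44},
        "grade": {"low": 0.763, "high": 0.218, "unknown": 0.019},
        "tumor_site": {"proximal": 0.648, "distal": 0.352},
    }
    comorbidity = {
        "chf": 0.12, "copd": 0.18, "diabetes": 0.22, "mi": 0.08,
        "pvd": 0.09, "cvd": 0.10, "renal": 0.06, "dementia": 0.05,
    }
    chemo = {
        "intercept": -1.4,
        "substage=III": 2.6,
        "age_group=75-79": -0.5,
        "age_group=80-84": -1.3,
        "comorbidity_count": -0.15,
    }
    propensity = {
        "intercept": 0.15,
        "substage=III": 1.1,
        "grade=high": 0.6,
        "chemo": 1.2,
        "age_group=80-84": -0.9,
        "buyin=yes": -0.5,
        "comorbidity_count": -0.25,
    }
    rates = {
        "cea": {"high": [2.8, 2.4, 2.1], "low": [0.35, 0.3, 0.28]},
        "ct": {"high": [1.6, 1.2, 1.0], "low": [0.22, 0.18, 0.16]},
        "scope": {"high": [1.2, 0.5, 0.45], "low": [0.25, 0.15, 0.12]},
    }
    cancer = HazardParams(
        base_rate=0.022,
        coefficients={"substage=III": 1.15, "grade=high": 0.65, "chemo": -0.25},
    )
    noncancer = HazardParams(
        base_rate=0.015,
        coefficients={
            "age_group=75-79": 0.45,
            "age_group=80-84": 0.95,
            "comorbidity_count": 0.35,
        },
    )
    return SynthConfig(
        n_patients=n_patients,
        seed=seed,
        covariate_margins=margins,
        comorbidity_prevalence=comorbidity,
        chemo_coefficients=chemo,
        propensity_coefficients=propensity,
        test_rate_params=rates,
        cancer_hazard=cancer,
        noncancer_hazard=noncancer,
    )
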