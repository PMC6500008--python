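"""Yearly and overall surveillance-adherence classification.

Guideline minima for stage II/III colon cancer surveillance: two CEA tests
per year, one CT per year, and a colonoscopy around one year post-resection
(a colonoscopy in the prior year carries over to satisfy years 2-3). Each
complete follow-up year is labelled:

* ``NONADHERENT`` — no surveillance tests at all that year (and no
  colonoscopy carry-over);
* ``MORE`` (More Adherent) — testing on at least two of the three
  modalities (full adherence, or one missing test compensated by activity
  elsewhere);
* ``LESS`` (Less Adherent) — testing on exactly one modality, i.e. at
  least one recommended test missed without additional testing.

Yearly labels over the complete years (up to three) combine into an overall
label; patients with no complete year, or no tests in any complete year,
are excluded from analysis.

The canonical ">= 2 active modalities" rule is a reconstruction of the
published per-year scheme; ``RuleTable`` accepts explicit tuple -> label
overrides so an exact enumerated scheme can be dropped in without code
change.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .claims_engine import N_ASSESS_YEARS

__all__ = ["AdherenceLabel", "RuleTable", "classify_year", "classify_overall", "build_profiles"]


class AdherenceLabel(str, enum.Enum):
    MORE = "MORE"
    LESS = "LESS"
    NONADHERENT = "NONADHERENT"
    #: Overall-classification outcome only, never a yearly label.
    EXCLUDED = "EXCLUDED"

    def __str__(self) -> str:  # cleaner table output
        return self.value


@dataclass
class RuleTable:
    """Per-year guideline minima plus optional explicit label overrides.

    ``year_overrides`` maps ``(year_index, cea_category, ct_category,
    scope_category, carry_over_active)`` to a label, where count categories
    are capped at the modality minimum (CEA in {0, 1, 2}, CT/colonoscopy in
    {0, 1}); an override supersedes the canonical rule tuple-by-tuple.
    ``overall_overrides`` maps a tuple of yearly label values to an overall
    label.
    """

    cea_min: int = 2
    ct_min: int = 1
    scope_min: int = 1
    scope_carry_over: bool = True
    year_overrides: dict[tuple, AdherenceLabel] = field(default_factory=dict)
    overall_overrides: dict[tuple, AdherenceLabel] = field(default_factory=dict)


DEFAULT_RULES = RuleTable()


def classify_year(
    year_index: int,
    cea_count: int,
    ct_count: int,
    scope_count: int,
    prior_year_scope_count: int = 0,
    rules: RuleTable = DEFAULT_RULES,
) -> AdherenceLabel:
    """Label one complete follow-up year.

    ``prior_year_scope_count`` is the (deduplicated) colonoscopy count of
    year ``year_index - 1``; it must be 0 for year 1. A prior-year
    colonoscopy makes the colonoscopy modality "active" in years >= 2, so a
    year with no claims of its own but a carry-over is Less Adherent, never
    Nonadherent.
    """
    counts = (cea_count, ct_count, scope_count, prior_year_scope_count)
    if any(c < 0 for c in counts):
        raise ValueError("test counts must be non-negative")
    if year_index < 1:
        raise ValueError("year_index is 1-based")
    if year_index == 1 and prior_year_scope_count != 0:
        raise ValueError("year 1 has no prior-year colonoscopy")

    carry = bool(
        rules.scope_carry_over and year_index >= 2 and prior_year_scope_count >= 1
    )
    key = (
        year_index,
        min(cea_count, rules.cea_min),
        min(ct_count, rules.ct_min),
        min(scope_count, rules.scope_min),
        carry,
    )
    if key in rules.year_overrides:
        return AdherenceLabel(rules.year_overrides[key])

    if cea_count == ct_count == scope_count == 0 and not carry:
        return AdherenceLabel.NONADHERENT
    active = (
        int(cea_count >= 1) + int(ct_count >= 1) + int(scope_count >= 1 or carry)
    )
    return AdherenceLabel.MORE if active >= 2 else AdherenceLabel.LESS


def classify_overall(
    yearly_labels: Sequence[AdherenceLabel],
    year_indices: Sequence[int] | None = None,
    rules: RuleTable = DEFAULT_RULES,
) -> AdherenceLabel:
    """Combine the yearly labels of all complete years into one label.

    No complete years, or Nonadherent in every complete year, excludes the
    patient. Otherwise a single year's label stands alone; with two or
    three years, Nonadherent years count as Less and the result is More iff
    strictly more More-years than Less-years (ties break to Less).
    """
    labels = [AdherenceLabel(l) for l in yearly_labels]
    if year_indices is not None:
        idx = list(year_indices)
        if idx != list(range(1, len(idx) + 1)):
            raise ValueError("yearly labels must cover consecutive years from 1")
    if len(labels) > N_ASSESS_YEARS:
        raise ValueError(f"at most {N_ASSESS_YEARS} assessment years")

    key = tuple(l.value for l in labels)
    if key in rules.overall_overrides:
        return AdherenceLabel(rules.overall_overrides[key])

    if not labels or all(l is AdherenceLabel.NONADHERENT for l in labels):
        return AdherenceLabel.EXCLUDED
    if len(labels) == 1:
        return labels[0]
    n_more = sum(l is AdherenceLabel.MORE for l in labels)
    n_less = len(labels) - n_more  # NONADHERENT years count as LESS
    return AdherenceLabel.MORE if n_more > n_less else AdherenceLabel.LESS


def build_profiles(counts: pd.DataFrame, rules: RuleTable = DEFAULT_RULES) -> pd.DataFrame:
    """Classify every patient from the per-year counts table.

    ``counts`` is the output of :func:`colonsurv.claims_engine.build_counts`
    (test counts ``{cea,ct,scope}_{1..3}`` plus ``n_complete_years``).
    Returns one row per patient with yearly labels (empty string for
    incomplete years), the overall label, and an ``exclusion_reason``
    (``""``, ``"no_complete_year"`` or ``"nonadherent_all_years"``).
    """
    needed = {"patient_id", "n_complete_years"} | {
        f"{m}_{k}" for m in ("cea", "ct", "scope") for k in range(1, N_ASSESS_YEARS + 1)
    }
    missing = needed - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")

    rows = []
    for rec in counts.to_dict(orient="records"):
        n_years = int(rec["n_complete_years"])
        yearly: list[AdherenceLabel] = []
        for k in range(1, n_years + 1):
            prior_scope = int(rec[f"scope_{k - 1}"]) if k >= 2 else 0
            yearly.append(
                classify_year(
                    k, int(rec[f"cea_{k}"]), int(rec[f"ct_{k}"]), int(rec[f"scope_{k}"]),
                    prior_year_scope_count=prior_scope, rules=rules,
                )
            )
        overall = classify_overall(yearly, rules=rules)
        if overall is AdherenceLabel.EXCLUDED:
            reason = "no_complete_year" if n_years == 0 else "nonadherent_all_years"
        else:
            reason = ""
        row = {"patient_id": rec["patient_id"], "n_complete_years": n_years}
        for k in range(1, N_ASSESS_YEARS + 1):
            row[f"year_{k}_label"] = yearly[k - 1].value if k <= n_years else ""
        row["overall_label"] = overall.value
        row["exclusion_reason"] = reason
        rows.append(row)
    return pd.DataFrame(rows)


def label_frequencies(profiles: pd.DataFrame) -> Mapping[str, int]:
    """Summary log of overall-label frequencies (including exclusions)."""
    return profiles["overall_label"].value_counts().to_dict()
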