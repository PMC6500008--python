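"""Claims processing: treatment anchor dates and deduplicated test counts.

Turns raw dated service events into, per patient:

* the final treatment date — the surgery date for surgery-only patients,
  or the end of the sequential chemotherapy course (claims <= 90 days apart
  count as sequential), capped at 6 months (183 days) after the first
  chemotherapy claim;
* per-modality surveillance-test counts for each of the first three
  post-treatment years, after >= 30-day deduplication of claims (CT and
  PET claims are pooled into a single imaging stream before deduplication);
* the number of complete follow-up years (0-3).

Years are fixed 365-day windows, half-open ``[start, start + 365)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TreatmentSummary",
    "final_treatment_date",
    "dedupe_tests",
    "count_by_year",
    "complete_years",
    "build_counts",
]

#: Gap (days) at or below which consecutive chemotherapy claims are one course.
SEQUENTIAL_CHEMO_GAP = 90
#: Cap: final treatment date is at most this many days after the first chemo claim.
CHEMO_CAP_DAYS = 183
#: Minimum separation (days) between claims counted as distinct tests.
DEDUP_MIN_GAP = 30
#: Length of a follow-up year in days.
YEAR_DAYS = 365
#: Number of post-treatment years assessed for surveillance.
N_ASSESS_YEARS = 3


@dataclass(frozen=True)
class TreatmentSummary:
    """Treatment anchor for one patient."""

    patient_id: object
    surgery_day: int
    final_treatment_day: int
    modality: str  # "surgery_only" | "surgery_plus_chemo"

    def __post_init__(self):
        if self.final_treatment_day < self.surgery_day:
            raise ValueError("final treatment cannot precede surgery")


def final_treatment_date(
    surgery_day: int, chemo_days: Sequence[int], patient_id: object = None
) -> TreatmentSummary:
    """Anchor follow-up at the end of primary treatment.

    With no chemotherapy the anchor is the surgery day. Otherwise the
    chemotherapy course is walked from the first claim, extending while
    consecutive gaps are <= 90 days; if the resulting course spans more
    than 183 days the anchor is capped at first claim + 183. Chemotherapy
    claims after a > 90-day break do not re-anchor.
    """
    chemo_days = list(chemo_days)
    if not chemo_days:
        return TreatmentSummary(patient_id, int(surgery_day), int(surgery_day), "surgery_only")
    if any(b < a for a, b in zip(chemo_days, chemo_days[1:])):
        raise ValueError("chemo_days must be sorted ascending")
    if chemo_days[0] < surgery_day:
        raise ValueError("chemotherapy cannot precede surgery")
    first = chemo_days[0]
    candidate = first
    for day in chemo_days[1:]:
        if day - candidate <= SEQUENTIAL_CHEMO_GAP:
            candidate = day
        else:
            break
    if candidate - first > CHEMO_CAP_DAYS:
        candidate = first + CHEMO_CAP_DAYS
    return TreatmentSummary(patient_id, int(surgery_day), int(candidate), "surgery_plus_chemo")


def dedupe_tests(days: Sequence[int], min_gap: int = DEDUP_MIN_GAP) -> list[int]:
    """Greedy left-to-right deduplication of one patient-modality stream.

    Keeps the first claim, then each subsequent claim iff it falls at least
    ``min_gap`` days after the last kept claim. Input must be sorted.
    """
    days = list(days)
    if any(b < a for a, b in zip(days, days[1:])):
        raise ValueError("event days must be sorted ascending")
    kept: list[int] = []
    for day in days:
        if not kept or day - kept[-1] >= min_gap:
            kept.append(int(day))
    return kept


def count_by_year(
    retained_days: Iterable[int], final_treatment_day: int, n_years: int = N_ASSESS_YEARS
) -> list[int]:
    """Count retained test days per post-treatment year.

    Year ``k`` (1-based) covers ``[final + 365*(k-1), final + 365*k)``;
    days before the final treatment date or beyond year ``n_years`` are
    ignored.
    """
    counts = [0] * n_years
    for day in retained_days:
        offset = day - final_treatment_day
        if offset < 0:
            continue
        year = offset // YEAR_DAYS
        if year < n_years:
            counts[year] += 1
    return counts


def complete_years(
    final_treatment_day: int, last_followup_day: int, n_years: int = N_ASSESS_YEARS
) -> int:
    """Number of fully observed post-treatment years, capped at ``n_years``.

    Year ``k`` is complete iff follow-up reaches ``final + 365*k``.
    """
    if last_followup_day < final_treatment_day:
        raise ValueError("follow-up ends before the final treatment date")
    return min(int((last_followup_day - final_treatment_day) // YEAR_DAYS), n_years)


def _per_patient_streams(claims: pd.DataFrame) -> dict:
    """Sorted event-day arrays per (patient, pooled modality)."""
    required = {"patient_id", "event_type", "service_day"}
    missing = required - set(claims.columns)
    if missing:
        raise ValueError(f"claims table missing columns: {sorted(missing)}")
    pooled = claims["event_type"].replace({"PET": "CT"})
    out: dict = {}
    order = claims.assign(_type=pooled).sort_values(["patient_id", "_type", "service_day"])
    for (pid, etype), grp in order.groupby(["patient_id", "_type"], sort=False):
        out[(pid, etype)] = grp["service_day"].to_numpy()
    return out


def build_counts(patients: pd.DataFrame, claims: pd.DataFrame) -> pd.DataFrame:
    """Per-patient treatment summary, yearly test counts and completeness.

    ``patients`` must carry ``patient_id``, ``death_day`` (nullable) and
    ``censor_day``; ``claims`` is the raw event table. Returns one row per
    patient: surgery/final treatment days, treatment modality, ``cea_k``,
    ``ct_k``, ``scope_k`` for k in 1..3, ``n_complete_years`` and
    ``last_followup_day``.
    """
    streams = _per_patient_streams(claims)
    modality_types = {"cea": "CEA", "ct": "CT", "scope": "colonoscopy"}
    rows = []
    for rec in patients.itertuples(index=False):
        pid = rec.patient_id
        surgery = streams.get((pid, "surgery"))
        if surgery is None or len(surgery) != 1:
            raise ValueError(f"patient {pid!r} must have exactly one surgery event")
        surgery_day = int(surgery[0])
        chemo = streams.get((pid, "chemo"), np.empty(0, dtype=int))
        summary = final_treatment_date(surgery_day, chemo.tolist(), patient_id=pid)
        death_day = getattr(rec, "death_day", None)
        censor_day = int(rec.censor_day)
        last_day = censor_day if pd.isna(death_day) else min(int(death_day), censor_day)
        row = {
            "patient_id": pid,
            "surgery_day": summary.surgery_day,
            "final_treatment_day": summary.final_treatment_day,
            "treatment_modality": summary.modality,
            "last_followup_day": last_day,
            "n_complete_years": complete_years(summary.final_treatment_day, last_day),
        }
        for name, etype in modality_types.items():
            days = streams.get((pid, etype), np.empty(0, dtype=int))
            kept = dedupe_tests(days.tolist())
            counts = count_by_year(kept, summary.final_treatment_day)
            for k, c in enumerate(counts, start=1):
                row[f"{name}_{k}"] = c
        rows.append(row)
    return pd.DataFrame(rows)
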