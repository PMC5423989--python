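"""Packaged 25-material case-study dataset with expected tier-wise outcomes.

The dataset encodes the published case-study materials (carbonaceous
materials, metal oxides and sulfates, amorphous silica variants, organic
pigments and crystalline quartz dust) at the level of information the
framework consumes: for criteria reported only qualitatively ("high
dissolution", "dispersible", "Range II") the stored numeric value is a
representative value on the stated side of the threshold, marked as such in
``source_note``.  Twenty-two of the 25 materials keep their non-animal
(Tier 1+2) group after Tier 3; for three -- SiO2.phosphate, Pigment blue
15:1 and graphite nanoplatelets -- the non-animal tiers overpredicted the
hazard and a Range IV short-term inhalation study NOAEC corrects them to
MG3 passive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .engine import EngineConfig, classify_batch
from .records import AssignmentStatus, MainGroup, MaterialRecord, NoaecRange

__all__ = ["CaseStudyEntry", "load_case_studies", "verify_case_studies", "VerificationResult"]

_DATA = "case_studies.json"


class CaseStudyEntry(BaseModel):
    model_config = ConfigDict(extra="forbid")

    record: MaterialRecord
    expected_nonanimal_group: MainGroup
    expected_final_group: MainGroup
    expected_status: AssignmentStatus
    expected_noaec_range: NoaecRange
    source_note: str = ""

    @model_validator(mode="after")
    def _consistent(self):
        if self.expected_status is AssignmentStatus.CORRECTED and (
            self.expected_nonanimal_group == self.expected_final_group
        ):
            raise ValueError("corrected entries must change group between tiers")
        return self


@lru_cache(maxsize=1)
def _load_raw() -> tuple[CaseStudyEntry, ...]:
    text = resources.files("nanogroup.data").joinpath(_DATA).read_text("utf-8")
    doc = json.loads(text)
    return tuple(CaseStudyEntry.model_validate(e) for e in doc["case_studies"])


def load_case_studies() -> list[CaseStudyEntry]:
    """Load the packaged case-study entries (pure; always identical)."""
    return [e.model_copy(deep=True) for e in _load_raw()]


@dataclass
class VerificationResult:
    table: pd.DataFrame
    n_total: int
    n_concordant: int  # non-animal group == final group
    n_corrected: int
    mismatches: list[str]

    @property
    def ok(self) -> bool:
        return not self.mismatches


def verify_case_studies(config: EngineConfig | None = None) -> VerificationResult:
    """Re-classify the packaged dataset and compare with the expected rows.

    Returns a table shaped like the published assignment overview (one row
    per material: non-animal group, Tier-3 final group, status, NOAEC
    range), plus the list of any expectation mismatches.
    """
    entries = load_case_studies()
    result = classify_batch([e.record for e in entries], config)
    rows = []
    mismatches: list[str] = []
    for entry, a in zip(entries, result.assignments):
        rows.append(
            {
                "material": entry.record.name or entry.record.material_id,
                "nonanimal_group": a.nonanimal_group.value,
                "expected_nonanimal": entry.expected_nonanimal_group.value,
                "final_group": a.main_group.value,
                "expected_final": entry.expected_final_group.value,
                "status": a.status.value,
                "expected_status": entry.expected_status.value,
                "noaec_range": a.noaec_range.value,
                "expected_range": entry.expected_noaec_range.value,
            }
        )
        for got, want, what in (
            (a.nonanimal_group, entry.expected_nonanimal_group, "non-animal group"),
            (a.main_group, entry.expected_final_group, "final group"),
            (a.status, entry.expected_status, "status"),
            (a.noaec_range, entry.expected_noaec_range, "NOAEC range"),
        ):
            if got != want:
                mismatches.append(
                    f"{entry.record.material_id}: {what} {got.value} != {want.value}"
                )
    for err in result.errors:
        mismatches.append(f"{err.material_id}: classification error: {err.error}")
    table = pd.DataFrame(rows)
    n_concordant = sum(
        1 for a in result.assignments if a.nonanimal_group == a.main_group
    )
    n_corrected = sum(
        1 for a in result.assignments if a.status is AssignmentStatus.CORRECTED
    )
    return VerificationResult(
        table=table,
        n_total=len(entries),
        n_concordant=n_concordant,
        n_corrected=n_corrected,
        mismatches=mismatches,
    )
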