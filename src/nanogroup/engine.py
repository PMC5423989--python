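"""Orchestration of the three grouping tiers.

``classify`` runs a validated :class:`~nanogroup.records.MaterialRecord`
through Tiers 1-3, applies the release qualifier (testing waiver), enforces
the precedence MG1 (terminal) > MG2 (biopersistent fiber) > MG4/MG3 and the
precautionary missing-data rules, and assembles a
:class:`~nanogroup.records.GroupAssignment` with a complete criterion trace.
Data collection stops at the earliest terminal tier.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .records import (
    AssignmentStatus,
    Comparison,
    CriterionEvaluation,
    CriterionId,
    DustLimitAnnotation,
    ExposureRoute,
    ExposureQualifiers,
    GroupAssignment,
    MainGroup,
    MaterialRecord,
    Outcome,
    ReleasePossible,
    ThresholdSet,
)
from . import tier1, tier2, tier3

__all__ = [
    "RangeIVariant",
    "EngineConfig",
    "check_waiver",
    "classify",
    "classify_batch",
    "BatchResult",
    "RecordError",
]


class RangeIVariant(str, enum.Enum):
    """Which published reading of the Range I NOAEC bound to apply."""

    TABLE1_0_5 = "table1_0_5"  # < 0.5 mg/m3 plus no regression of effects
    TABLE2_0_1 = "table2_0_1"  # < 0.1 mg/m3, plain banding


class EngineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    thresholds: ThresholdSet = Field(default_factory=ThresholdSet)
    range_i_variant: RangeIVariant = RangeIVariant.TABLE1_0_5
    report_format: str = "markdown"

    @property
    def strict_who_fiber(self) -> bool:
        return self.thresholds.who_fiber_rule_strict

    def effective_thresholds(self) -> ThresholdSet:
        """Thresholds with the Range I variant applied."""
        t = self.thresholds
        if self.range_i_variant is RangeIVariant.TABLE2_0_1:
            t = t.model_copy(
                update={
                    "noaec_range_i_mg_m3": 0.1,
                    "range_i_requires_persistent_effects": False,
                }
            )
        return t

    def echo(self) -> dict:
        """Effective configuration, for embedding into reports (audit)."""
        return {
            "range_i_variant": self.range_i_variant.value,
            "thresholds": self.effective_thresholds().model_dump(),
        }


def check_waiver(q: ExposureQualifiers) -> bool:
    """Testing may be waived only when release from the product matrix is
    positively excluded; an unknown release potential does not waive."""
    return q.release_possible is ReleasePossible.NO


def _waived_assignment(record: MaterialRecord) -> GroupAssignment:
    trace = [
        CriterionEvaluation(
            criterion_id=CriterionId.RELEASE_QUALIFIER,
            tier=1,
            input_value="missing",
            outcome=Outcome.NOT_APPLICABLE,
            note="release_possible = no: testing waived",
        )
    ]
    return GroupAssignment(
        material_id=record.material_id,
        main_group=None,
        nonanimal_group=None,
        status=AssignmentStatus.WAIVED,
        tier_reached=1,
        trace=trace,
    )


def _dust_annotation(group: Optional[MainGroup]) -> DustLimitAnnotation:
    if group is MainGroup.MG3:
        return DustLimitAnnotation.GENERAL_DUST_LIMIT_SUFFICIENT
    if group is MainGroup.MG4:
        return DustLimitAnnotation.SPECIFIC_OEL_NEEDED
    return DustLimitAnnotation.NOT_APPLICABLE


def _mg1_assignment(
    record: MaterialRecord,
    t: ThresholdSet,
    trace: list[CriterionEvaluation],
    tier_reached: int,
    warnings: list[str],
) -> GroupAssignment:
    """Terminal MG1 with optional biopersistence confirmation."""
    status = AssignmentStatus.ASSIGNED
    if record.invivo is not None and record.invivo.t50_days is not None:
        bio = tier3.eval_biopersistence(record.invivo, t)
        trace = trace + [bio]
        tier_reached = 3
        if bio.outcome is Outcome.TRIGGER:
            status = AssignmentStatus.CONFIRMED
        else:
            warnings = warnings + [
                "t50 at/above 40 days challenges the solubility-based MG1 assignment"
            ]
    return GroupAssignment(
        material_id=record.material_id,
        main_group=MainGroup.MG1,
        nonanimal_group=MainGroup.MG1,
        status=status,
        tier_reached=tier_reached,
        trace=trace,
        warnings=warnings,
    )


def classify(record: MaterialRecord, config: Optional[EngineConfig] = None) -> GroupAssignment:
    """Assign a material to one of the four main groups.

    The trace carries one :class:`CriterionEvaluation` per criterion actually
    consulted, in tier order; criteria beyond the earliest terminal tier are
    not evaluated (data economy).
    """
    if not isinstance(record, MaterialRecord):
        raise TypeError("classify expects a validated MaterialRecord")
    config = config or EngineConfig()
    t = config.effective_thresholds()

    if check_waiver(record.qualifiers):
        return _waived_assignment(record)

    t1 = tier1.tier1_summary(record.intrinsic, t)
    trace = list(t1.trace)
    warnings: list[str] = []

    if t1.mg1_terminal:
        if MainGroup.MG4 in t1.indications:
            warnings.append(
                "MG1 assignment with a simultaneous GHS-composition indication; "
                "read-across to dissolved species should cover the classified component"
            )
        return _mg1_assignment(record, t, trace, 1, warnings)

    t2 = tier2.tier2_summary(record, t1.indications, t)
    trace += t2.trace
    warnings += t2.warnings

    if t2.group is MainGroup.MG1:
        if MainGroup.MG4 in t1.indications:
            warnings.append(
                "MG1 (dissolution) with a Tier-1 GHS-composition indication; "
                "flagged, not resolved by the framework"
            )
        return _mg1_assignment(record, t, trace, 2, warnings)

    nonanimal = t2.group
    have_stis = record.invivo is not None and record.invivo.stis_noaec is not None

    if not have_stis:
        routes = record.qualifiers.exposure_routes
        if routes and ExposureRoute.INHALATION not in routes:
            warnings.append("route not covered by STIS; Tier 3 not demanded")
        if nonanimal is MainGroup.MG2:
            status = AssignmentStatus.ASSIGNED
        else:
            status = AssignmentStatus.INDICATED
            if _data_poor(trace):
                warnings.append(
                    "data-poor record: provisional MG4 rests on precautionary "
                    "missing-data rules only"
                )
        return GroupAssignment(
            material_id=record.material_id,
            main_group=nonanimal,
            nonanimal_group=nonanimal,
            status=status,
            tier_reached=2,
            dust_limit_annotation=_dust_annotation(nonanimal),
            trace=trace,
            warnings=warnings,
        )

    res = tier3.tier3_resolve(nonanimal, record.invivo, t)
    trace += res.trace
    warnings += res.warnings
    if res.corrected:
        status = AssignmentStatus.CORRECTED
    else:
        status = AssignmentStatus.CONFIRMED
    return GroupAssignment(
        material_id=record.material_id,
        main_group=res.final_group,
        nonanimal_group=nonanimal,
        status=status,
        tier_reached=3,
        noaec_range=res.noaec_range,
        reversibility_subgroup=res.reversibility,
        biodistribution_subgroup=res.biodistribution,
        dust_limit_annotation=_dust_annotation(res.final_group),
        trace=trace,
        warnings=warnings,
    )


def _data_poor(trace: Sequence[CriterionEvaluation]) -> bool:
    precautionary = [
        e for e in trace if e.outcome is Outcome.MISSING_PRECAUTIONARY
    ]
    measured_triggers = [
        e for e in trace if e.outcome is Outcome.TRIGGER
    ]
    return bool(precautionary) and not measured_triggers


@dataclass
class RecordError:
    material_id: str
    error: str


@dataclass
class BatchResult:
    assignments: list[GroupAssignment]
    errors: list[RecordError] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Counts per main group and status (non-waived records only add to
        the group columns; waived records are tallied separately)."""
        rows = []
        for a in self.assignments:
            rows.append(
                {
                    "main_group": a.main_group.value if a.main_group else "waived",
                    "status": a.status.value,
                }
            )
        if not rows:
            return pd.DataFrame(columns=["main_group", "status", "count"])
        df = pd.DataFrame(rows)
        out = (
            df.groupby(["main_group", "status"], sort=True)
            .size()
            .reset_index(name="count")
        )
        return out


def classify_batch(
    records: Iterable[MaterialRecord], config: Optional[EngineConfig] = None
) -> BatchResult:
    """Classify records in order; per-record failures are collected and the
    batch continues."""
    config = config or EngineConfig()
    assignments: list[GroupAssignment] = []
    errors: list[RecordError] = []
    for rec in records:
        try:
            assignments.append(classify(rec, config))
        except (ValidationError, ValueError, TypeError) as exc:
            mid = getattr(rec, "material_id", "<unknown>")
            errors.append(RecordError(material_id=str(mid), error=str(exc)))
    return BatchResult(assignments=assignments, errors=errors)
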