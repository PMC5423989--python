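"""Tier 3: in vivo screening (short-term inhalation study, STIS).

The STIS no-observed-adverse-effect concentration (NOAEC) is banded into
four ranges; Range IV (NOAEC >= 10 mg/m3) finalizes MG3 "passive" and
thereby corrects any Tier-2 overprediction, while Ranges I-III confirm an
active (MG4) or fiber (MG2) assignment and drive the MG4 subgrouping by
potency, reversibility of effects and pattern of biodistribution.  Small
biokinetics helpers (pulmonary half-life check, deposited lung fraction)
live here as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .records import (
    MISSING,
    BiodistributionProfile,
    BiodistributionSubgroup,
    Comparison,
    CriterionEvaluation,
    CriterionId,
    EffectsCourse,
    InVivoResults,
    MainGroup,
    NoaecCensoring,
    NoaecRange,
    Outcome,
    ReversibilitySubgroup,
    ThresholdSet,
)

__all__ = [
    "noaec_range",
    "eval_biopersistence",
    "biodistribution_subgroup",
    "tier3_resolve",
    "Tier3Resolution",
    "deposited_fraction",
]


def _band(n: float, effects: EffectsCourse, t: ThresholdSet) -> NoaecRange:
    if n >= t.noaec_range_iii_mg_m3:
        return NoaecRange.IV
    if n >= t.noaec_range_ii_mg_m3:
        return NoaecRange.III
    if n >= t.noaec_range_i_mg_m3:
        return NoaecRange.II
    # below the Range I bound
    if t.range_i_requires_persistent_effects and effects is EffectsCourse.REGRESSION:
        return NoaecRange.II
    return NoaecRange.I


def noaec_range(r: Optional[InVivoResults], t: ThresholdSet) -> NoaecRange:
    """Band a STIS NOAEC into Ranges I-IV.

    Ranges (defaults): I below 0.5 mg/m3 with effects showing no regression,
    II below 1, III below 10, IV at or above 10 mg/m3.  A censored
    ("at least n") NOAEC at or above 10 is a clean Range IV; below 10 it is
    banded at its lower bound.  Effects with unknown course below the Range I
    bound band conservatively as Range I.
    """
    if r is None or r.stis_noaec is None:
        return NoaecRange.UNKNOWN
    return _band(r.stis_noaec, r.effects_regression_or_progression, t)


def eval_biopersistence(
    r: Optional[InVivoResults], t: ThresholdSet
) -> CriterionEvaluation:
    """Pulmonary elimination half-life strictly < 40 days confirms low
    biopersistence (MG1 confirmation)."""
    t50 = None if r is None else r.t50_days
    if t50 is None:
        return CriterionEvaluation(
            criterion_id=CriterionId.BIOPERSISTENCE,
            tier=3,
            input_value=MISSING,
            threshold=t.t50_days,
            comparison=Comparison.LT,
            outcome=Outcome.NOT_APPLICABLE,
            note="no lung-burden kinetics available",
        )
    low = t50 < t.t50_days
    return CriterionEvaluation(
        criterion_id=CriterionId.BIOPERSISTENCE,
        tier=3,
        input_value=t50,
        threshold=t.t50_days,
        comparison=Comparison.LT,
        outcome=Outcome.TRIGGER if low else Outcome.NO_TRIGGER,
        note="low biopersistence" if low else "biopersistent",
    )


def biodistribution_subgroup(
    b: BiodistributionProfile, t: ThresholdSet
) -> BiodistributionSubgroup:
    """Subgroup by biodistribution pattern using the 1%-of-total-dose cut.

    Materials systemically available outside the mononuclear phagocyte
    system (MPS) above 1% of dose rank highest, then those found in the MPS
    above 1%, then those confined to the portal-of-entry organ.
    """
    if b.fraction_beyond_mps > t.biodistribution_fraction_pct:
        return BiodistributionSubgroup.BEYOND_MPS
    if b.fraction_mps > t.biodistribution_fraction_pct:
        return BiodistributionSubgroup.MPS
    return BiodistributionSubgroup.PRIMARY_ORGAN_ONLY


_REVERSIBILITY = {
    EffectsCourse.REGRESSION: ReversibilitySubgroup.REVERSIBLE,
    EffectsCourse.PROGRESSION: ReversibilitySubgroup.PROGRESSIVE,
    EffectsCourse.NONE: ReversibilitySubgroup.PROGRESSIVE,
    EffectsCourse.UNKNOWN: ReversibilitySubgroup.UNKNOWN,
}


@dataclass
class Tier3Resolution:
    """Result of confirming/correcting a provisional group against STIS data."""

    final_group: MainGroup
    corrected: bool
    noaec_range: NoaecRange
    reversibility: ReversibilitySubgroup
    biodistribution: BiodistributionSubgroup
    trace: list[CriterionEvaluation] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def tier3_resolve(
    provisional: MainGroup, r: InVivoResults, t: ThresholdSet
) -> Tier3Resolution:
    """Confirm or correct a provisional MG2/MG3/MG4 with STIS results.

    Range IV finalizes MG3 (confirmation of a provisional MG3, correction of
    a provisional MG4 overprediction).  Ranges I-III confirm MG4 -- or
    correct a provisional MG3 upward -- with the potency/reversibility/
    biodistribution subgroups populated.  A fiber (MG2) is never demoted by
    a high NOAEC: fiber hazard is not NOAEC-driven, so Range IV merely adds
    a warning.
    """
    if provisional not in (MainGroup.MG2, MainGroup.MG3, MainGroup.MG4):
        raise ValueError(f"tier3_resolve expects MG2/MG3/MG4, got {provisional}")
    if r.stis_noaec is None:
        raise ValueError("tier3_resolve requires a STIS NOAEC")

    rng = noaec_range(r, t)
    censored_note = ""
    if (
        r.noaec_censoring is NoaecCensoring.AT_LEAST
        and r.stis_noaec < t.noaec_range_iii_mg_m3
    ):
        censored_note = "censored NOAEC below 10 mg/m3; banded at its lower bound"

    stis_eval = CriterionEvaluation(
        criterion_id=CriterionId.STIS_NOAEC,
        tier=3,
        input_value=r.stis_noaec,
        threshold=t.noaec_range_iii_mg_m3,
        comparison=Comparison.GE,
        outcome=Outcome.TRIGGER if rng is NoaecRange.IV else Outcome.NO_TRIGGER,
        note=f"Range {rng.value}" + (f"; {censored_note}" if censored_note else ""),
    )
    trace = [stis_eval]
    warnings: list[str] = []

    bio = eval_biopersistence(r, t)
    if bio.outcome is not Outcome.NOT_APPLICABLE:
        trace.append(bio)

    reversibility = _REVERSIBILITY[r.effects_regression_or_progression]
    if r.biodistribution is not None:
        biodist = biodistribution_subgroup(r.biodistribution, t)
        trace.append(
            CriterionEvaluation(
                criterion_id=CriterionId.BIODISTRIBUTION,
                tier=3,
                input_value=r.biodistribution.fraction_beyond_mps,
                threshold=t.biodistribution_fraction_pct,
                comparison=Comparison.GT,
                outcome=Outcome.NO_TRIGGER
                if biodist is BiodistributionSubgroup.PRIMARY_ORGAN_ONLY
                else Outcome.TRIGGER,
                note=f"subgroup: {biodist.value}",
            )
        )
    else:
        biodist = BiodistributionSubgroup.UNKNOWN

    if provisional is MainGroup.MG2:
        if rng is NoaecRange.IV:
            warnings.append(
                "Range IV NOAEC for a biopersistent fiber: MG2 retained "
                "(fiber hazard is not NOAEC-driven)"
            )
        return Tier3Resolution(
            final_group=MainGroup.MG2,
            corrected=False,
            noaec_range=rng,
            reversibility=reversibility,
            biodistribution=biodist,
            trace=trace,
            warnings=warnings,
        )

    if rng is NoaecRange.IV:
        return Tier3Resolution(
            final_group=MainGroup.MG3,
            corrected=provisional is MainGroup.MG4,
            noaec_range=rng,
            reversibility=reversibility,
            biodistribution=biodist,
            trace=trace,
            warnings=warnings,
        )
    return Tier3Resolution(
        final_group=MainGroup.MG4,
        corrected=provisional is MainGroup.MG3,
        noaec_range=rng,
        reversibility=reversibility,
        biodistribution=biodist,
        trace=trace,
        warnings=warnings,
    )


def deposited_fraction(lung_burden: float, total_inhaled: float) -> float:
    """Percent of the total inhaled particle mass deposited in the lung.

    Reported at one decimal, e.g. a 0.17 mg lung burden out of 18 mg inhaled
    is 0.9%.
    """
    if total_inhaled <= 0:
        raise ValueError("total_inhaled must be > 0")
    if lung_burden < 0:
        raise ValueError("lung_burden must be >= 0")
    return round(100.0 * lung_burden / total_inhaled, 1)
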