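"""Tier 1: intrinsic material properties.

Three criteria are consulted: water solubility (terminal assignment to MG1,
the soluble group), particle size and shape (indication for MG2, biopersistent
high-aspect-ratio materials, pending the Tier-2 biopersistence check) and
chemical composition including impurities (indication for MG4, active
materials).

Missing-data semantics differ by concern direction: a missing water solubility
does NOT precautionarily force MG1, because MG1 is the low-particle-concern
branch (concern flows to the later tiers instead), whereas missing fiber
dimensions on an otherwise fiber-like particle ARE treated precautionarily.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import (
    MISSING,
    Comparison,
    CriterionEvaluation,
    CriterionId,
    IntrinsicProperties,
    MainGroup,
    Outcome,
    ShapeClass,
    ThresholdSet,
)

__all__ = [
    "eval_water_solubility",
    "eval_morphology",
    "eval_composition",
    "tier1_summary",
    "Tier1Summary",
]


def eval_water_solubility(
    p: IntrinsicProperties, t: ThresholdSet
) -> CriterionEvaluation:
    """Water solubility strictly > threshold (default 100 mg/L) assigns MG1."""
    ws = p.water_solubility
    if ws is None:
        return CriterionEvaluation(
            criterion_id=CriterionId.WATER_SOLUBILITY,
            tier=1,
            input_value=MISSING,
            threshold=t.water_solubility_mg_l,
            comparison=Comparison.GT,
            outcome=Outcome.NO_TRIGGER,
            note="not assessable; continue to Tier 2 dissolution",
        )
    return CriterionEvaluation(
        criterion_id=CriterionId.WATER_SOLUBILITY,
        tier=1,
        input_value=ws,
        threshold=t.water_solubility_mg_l,
        comparison=Comparison.GT,
        outcome=Outcome.TRIGGER if ws > t.water_solubility_mg_l else Outcome.NO_TRIGGER,
    )


def eval_morphology(p: IntrinsicProperties, t: ThresholdSet) -> CriterionEvaluation:
    """Fiber-shape criterion: aspect ratio > 3:1 and diameter < 3 um.

    The length criterion (> 5 um, the WHO fiber convention) is enforced only
    when ``t.who_fiber_rule_strict`` is set; by default materials may be
    flagged for MG2 even when their length falls short of it.

    Partial data are precautionary: if at least one sub-criterion is met and
    another cannot be evaluated, the outcome is ``missing_precautionary``. A
    declared fiber-like shape with no usable dimensions is likewise
    precautionary. If no sub-criterion is affirmatively met, the particle is
    not treated as a fiber.
    """
    checks: list[bool | None] = []

    def cmp(value, op):
        return None if value is None else op(value)

    checks.append(cmp(p.aspect_ratio, lambda v: v > t.aspect_ratio_min))
    if t.who_fiber_rule_strict:
        checks.append(cmp(p.length, lambda v: v > t.fiber_length_um))
    checks.append(cmp(p.diameter, lambda v: v < t.fiber_diameter_max_um))

    note = ""
    if any(c is False for c in checks):
        outcome = Outcome.NO_TRIGGER
    elif all(c is True for c in checks):
        outcome = Outcome.TRIGGER
    elif any(c is True for c in checks):
        outcome = Outcome.MISSING_PRECAUTIONARY
        note = "partial fiber evidence with missing dimensions; treated as fiber-like"
    elif p.shape_class is ShapeClass.FIBER_LIKE:
        outcome = Outcome.MISSING_PRECAUTIONARY
        note = "fiber-like shape declared without dimensions; treated as fiber-like"
    else:
        outcome = Outcome.NO_TRIGGER
        note = "no fiber evidence"

    # a partially missing compound input is traced as missing
    value = None if outcome is Outcome.MISSING_PRECAUTIONARY else p.aspect_ratio
    return CriterionEvaluation(
        criterion_id=CriterionId.MORPHOLOGY,
        tier=1,
        input_value=MISSING if value is None else value,
        threshold=t.aspect_ratio_min,
        comparison=Comparison.GT,
        outcome=outcome,
        note=note,
    )


def eval_composition(p: IntrinsicProperties, t: ThresholdSet) -> CriterionEvaluation:
    """>= 0.1% of a component with a GHS classification for systemic effects."""
    classified = [c for c in p.composition if c.ghs_systemic]
    if not p.composition:
        return CriterionEvaluation(
            criterion_id=CriterionId.COMPOSITION,
            tier=1,
            input_value=MISSING,
            threshold=t.ghs_component_pct,
            comparison=Comparison.GE,
            outcome=Outcome.NO_TRIGGER,
            note="no composition data",
        )
    top = max((c.mass_fraction for c in classified), default=0.0)
    hit = top >= t.ghs_component_pct
    names = ", ".join(c.name for c in classified if c.mass_fraction >= t.ghs_component_pct)
    return CriterionEvaluation(
        criterion_id=CriterionId.COMPOSITION,
        tier=1,
        input_value=top,
        threshold=t.ghs_component_pct,
        comparison=Comparison.GE,
        outcome=Outcome.TRIGGER if hit else Outcome.NO_TRIGGER,
        note=f"GHS-classified component(s): {names}" if hit else "",
    )


@dataclass
class Tier1Summary:
    """Outcome of Tier 1: either a terminal MG1 or a set of indications."""

    mg1_terminal: bool
    indications: set[MainGroup] = field(default_factory=set)
    trace: list[CriterionEvaluation] = field(default_factory=list)

    @property
    def fiber_indicated(self) -> bool:
        return MainGroup.MG2 in self.indications


def tier1_summary(p: IntrinsicProperties, t: ThresholdSet) -> Tier1Summary:
    """Evaluate all Tier-1 criteria and summarize.

    A water-solubility trigger is terminal (MG1); morphology and composition
    triggers are indications carried into Tier 2.  All three evaluations are
    recorded in the trace even when MG1 terminates the tier, so that e.g. a
    simultaneous composition indication remains auditable.
    """
    sol = eval_water_solubility(p, t)
    morph = eval_morphology(p, t)
    comp = eval_composition(p, t)
    trace = [sol, morph, comp]

    indications: set[MainGroup] = set()
    if morph.outcome in (Outcome.TRIGGER, Outcome.MISSING_PRECAUTIONARY):
        indications.add(MainGroup.MG2)
    if comp.outcome is Outcome.TRIGGER:
        indications.add(MainGroup.MG4)

    return Tier1Summary(
        mg1_terminal=sol.outcome is Outcome.TRIGGER,
        indications=indications,
        trace=trace,
    )
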