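"""Tier 2: system-dependent properties and in vitro effects.

Criteria: dissolution in biological fluids (MG1 indication for globular
materials, MG2 for fiber-indicated ones), surface reactivity (MG4),
dispersibility (MG4 for non-fibers), cellular effects in lung epithelial
cells and the alveolar-macrophage assay (MG4), plus the supplementary
surface-charge indication which never assigns a group on its own.

Precautionary defaults follow the framework's case-study precedents: a
surface reactivity that cannot be determined counts as an MG4 concern,
missing dissolution on a fiber-indicated material leaves the fiber assumed
biopersistent, while absent dispersibility data default to "agglomeration
assumed" (no trigger).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .records import (
    MISSING,
    Comparison,
    CriterionEvaluation,
    CriterionId,
    InVitroResults,
    MacrophageParam,
    MainGroup,
    MaterialRecord,
    Outcome,
    SystemDependentProperties,
    ThresholdSet,
)

__all__ = [
    "MacrophageCallResult",
    "MacrophageCall",
    "eval_dissolution",
    "eval_surface_reactivity",
    "eval_dispersibility",
    "eval_epithelial",
    "macrophage_call",
    "eval_surface_charge",
    "tier2_summary",
    "Tier2Summary",
]

import enum


class MacrophageCallResult(str, enum.Enum):
    ACTIVE = "active"
    PASSIVE = "passive"
    NOT_ASSESSABLE = "not_assessable"


@dataclass
class MacrophageCall:
    """Joint activity call over the four macrophage assay parameters."""

    positive_params: int
    call: MacrophageCallResult
    per_param: dict[MacrophageParam, bool] = field(default_factory=dict)
    note: str = ""


def eval_dissolution(
    s: SystemDependentProperties, fiber_indicated: bool, t: ThresholdSet
) -> CriterionEvaluation:
    """Dissolution in biological fluids against the 100 mg/L cut-off.

    Globular materials: dissolution strictly above the threshold indicates
    MG1 (the particle dissolves before exerting particle effects).  Fibers:
    dissolution strictly below the threshold flags the fiber as biopersistent
    (MG2); a fiber with unknown dissolution is assumed biopersistent.
    """
    d = s.dissolution_biological
    if fiber_indicated:
        if d is None:
            return CriterionEvaluation(
                criterion_id=CriterionId.DISSOLUTION,
                tier=2,
                input_value=MISSING,
                threshold=t.dissolution_mg_l,
                comparison=Comparison.LT,
                outcome=Outcome.MISSING_PRECAUTIONARY,
                note="fiber-indicated; biopersistence assumed",
            )
        return CriterionEvaluation(
            criterion_id=CriterionId.DISSOLUTION,
            tier=2,
            input_value=d,
            threshold=t.dissolution_mg_l,
            comparison=Comparison.LT,
            outcome=Outcome.TRIGGER if d < t.dissolution_mg_l else Outcome.NO_TRIGGER,
            note="fiber rule: low dissolution confirms biopersistent fiber"
            if d < t.dissolution_mg_l
            else "fiber dissolves; fiber concern not biopersistent",
        )
    if d is None:
        return CriterionEvaluation(
            criterion_id=CriterionId.DISSOLUTION,
            tier=2,
            input_value=MISSING,
            threshold=t.dissolution_mg_l,
            comparison=Comparison.GT,
            outcome=Outcome.NO_TRIGGER,
            note="not assessable; no dissolution-based MG1 indication",
        )
    return CriterionEvaluation(
        criterion_id=CriterionId.DISSOLUTION,
        tier=2,
        input_value=d,
        threshold=t.dissolution_mg_l,
        comparison=Comparison.GT,
        outcome=Outcome.TRIGGER if d > t.dissolution_mg_l else Outcome.NO_TRIGGER,
    )


def eval_surface_reactivity(
    s: SystemDependentProperties, t: ThresholdSet
) -> CriterionEvaluation:
    """Surface reactivity >= 10% of Mn2O3, equivalently >= 0.19 uU FRAS/m2*h.

    Either measurement suffices (inclusive comparisons).  If both are absent
    the outcome is precautionary: reactivity cannot be excluded.  Discordant
    duplicate measurements resolve conservatively to a trigger.
    """
    rel, fras = s.surface_reactivity_relative, s.surface_reactivity_fras
    if rel is None and fras is None:
        return CriterionEvaluation(
            criterion_id=CriterionId.SURFACE_REACTIVITY,
            tier=2,
            input_value=MISSING,
            threshold=t.reactivity_relative_min,
            comparison=Comparison.GE,
            outcome=Outcome.MISSING_PRECAUTIONARY,
            note="surface reactivity could not be determined; concern assumed",
        )
    votes = []
    if rel is not None:
        votes.append(rel >= t.reactivity_relative_min)
    if fras is not None:
        votes.append(fras >= t.reactivity_fras_min)
    trigger = any(votes)
    note = ""
    if len(votes) == 2 and votes[0] != votes[1]:
        note = "discordant measurements; conservative trigger"
    value = rel if rel is not None else fras
    threshold = t.reactivity_relative_min if rel is not None else t.reactivity_fras_min
    return CriterionEvaluation(
        criterion_id=CriterionId.SURFACE_REACTIVITY,
        tier=2,
        input_value=value,
        threshold=threshold,
        comparison=Comparison.GE,
        outcome=Outcome.TRIGGER if trigger else Outcome.NO_TRIGGER,
        note=note,
    )


def eval_dispersibility(
    s: SystemDependentProperties, t: ThresholdSet
) -> CriterionEvaluation:
    """Dispersibility: AAN strictly < 3 OR agglomerate diameter strictly < 100 nm.

    Missing both measurements defaults to "agglomeration assumed" (no
    trigger) -- the benchmark behaviour of unfunctionalized suspended silica.
    """
    aan, diam = s.aan, s.agglomerate_diameter
    if aan is None and diam is None:
        return CriterionEvaluation(
            criterion_id=CriterionId.DISPERSIBILITY,
            tier=2,
            input_value=MISSING,
            threshold=t.aan_max,
            comparison=Comparison.LT,
            outcome=Outcome.NO_TRIGGER,
            note="no dispersibility data; agglomeration assumed",
        )
    trigger = (aan is not None and aan < t.aan_max) or (
        diam is not None and diam < t.dispersible_diameter_nm
    )
    value = aan if aan is not None else diam
    threshold = t.aan_max if aan is not None else t.dispersible_diameter_nm
    return CriterionEvaluation(
        criterion_id=CriterionId.DISPERSIBILITY,
        tier=2,
        input_value=value,
        threshold=threshold,
        comparison=Comparison.LT,
        outcome=Outcome.TRIGGER if trigger else Outcome.NO_TRIGGER,
    )


def macrophage_call(iv: InVitroResults, t: ThresholdSet) -> MacrophageCall:
    """Joint activity call of the NR8383 alveolar-macrophage assay.

    A parameter is positive when its LOEC lies strictly below the
    non-overload surface-area bound (default 6000 mm2/mL).  The material is
    active when at least two of the four parameters are positive, passive
    when none or one is.  Fewer than four reported parameters make the assay
    not assessable.
    """
    params = iv.macrophage_params
    if params is None or set(params) != set(MacrophageParam):
        have = set(params or {})
        missing = sorted(p.value for p in MacrophageParam if p not in have)
        return MacrophageCall(
            positive_params=0,
            call=MacrophageCallResult.NOT_ASSESSABLE,
            note="missing parameters: " + ", ".join(missing) if missing else "",
        )
    per_param = {
        p: (r.loec_surface_area is not None and r.loec_surface_area < t.macrophage_overload_mm2_ml)
        for p, r in params.items()
    }
    n_pos = sum(per_param.values())
    call = (
        MacrophageCallResult.ACTIVE
        if n_pos >= t.macrophage_min_positive_params
        else MacrophageCallResult.PASSIVE
    )
    return MacrophageCall(positive_params=n_pos, call=call, per_param=per_param)


def eval_epithelial(iv: InVitroResults, t: ThresholdSet) -> CriterionEvaluation:
    """Cytotoxicity in lung epithelial cells: effect at <= 10 ug/cm2 -> MG4.

    A "no effect up to X" record with X at or above the threshold is a clean
    negative; a bound below the threshold is uninformative and treated like a
    missing result.  When the epithelial assay is absent the outcome depends
    on whether a macrophage call is available: ``not_applicable`` if it is,
    ``missing_precautionary`` when neither cellular assay exists.
    """
    thr = t.epithelial_loec_ug_cm2
    if iv.epithelial_loec is not None:
        loec = iv.epithelial_loec
        return CriterionEvaluation(
            criterion_id=CriterionId.EPITHELIAL_CYTOTOXICITY,
            tier=2,
            input_value=loec,
            threshold=thr,
            comparison=Comparison.LE,
            outcome=Outcome.TRIGGER if loec <= thr else Outcome.NO_TRIGGER,
        )
    bound = iv.epithelial_no_effect_up_to
    if bound is not None and bound >= thr:
        return CriterionEvaluation(
            criterion_id=CriterionId.EPITHELIAL_CYTOTOXICITY,
            tier=2,
            input_value=bound,
            threshold=thr,
            comparison=Comparison.LE,
            outcome=Outcome.NO_TRIGGER,
            note=f"no effect up to {bound:g} ug/cm2",
        )
    mac_assessable = macrophage_call(iv, t).call is not MacrophageCallResult.NOT_ASSESSABLE
    if mac_assessable:
        return CriterionEvaluation(
            criterion_id=CriterionId.EPITHELIAL_CYTOTOXICITY,
            tier=2,
            input_value=MISSING,
            threshold=thr,
            comparison=Comparison.LE,
            outcome=Outcome.NOT_APPLICABLE,
            note="no epithelial assay; macrophage call available",
        )
    return CriterionEvaluation(
        criterion_id=CriterionId.EPITHELIAL_CYTOTOXICITY,
        tier=2,
        input_value=MISSING,
        threshold=thr,
        comparison=Comparison.LE,
        outcome=Outcome.MISSING_PRECAUTIONARY,
        note="no cellular assay at all; concern assumed",
    )


def eval_surface_charge(
    s: SystemDependentProperties, t: ThresholdSet
) -> CriterionEvaluation:
    """Supplementary criterion: positive zeta potential (> +10 mV).

    Only ever an annotation supporting MG4 -- never a sole basis for
    assignment.  A missing zeta potential is ``not_applicable`` because
    surface charge is evaluated jointly with dispersibility and need not be
    assessed separately.
    """
    z = s.zeta_potential
    if z is None:
        return CriterionEvaluation(
            criterion_id=CriterionId.SURFACE_CHARGE,
            tier=2,
            input_value=MISSING,
            threshold=t.zeta_positive_mv,
            comparison=Comparison.GT,
            outcome=Outcome.NOT_APPLICABLE,
            note="jointly evaluated with dispersibility",
        )
    return CriterionEvaluation(
        criterion_id=CriterionId.SURFACE_CHARGE,
        tier=2,
        input_value=z,
        threshold=t.zeta_positive_mv,
        comparison=Comparison.GT,
        outcome=Outcome.TRIGGER if z > t.zeta_positive_mv else Outcome.NO_TRIGGER,
        note="supplementary MG4 indication" if z > t.zeta_positive_mv else "",
    )


@dataclass
class Tier2Summary:
    """Provisional group after the non-animal tiers, with trace fragment."""

    group: MainGroup
    terminal: bool  # MG1 (dissolution) and MG2 terminate data collection
    trace: list[CriterionEvaluation] = field(default_factory=list)
    macrophage: Optional[MacrophageCall] = None
    warnings: list[str] = field(default_factory=list)


def tier2_summary(
    record: MaterialRecord,
    tier1_indications: set[MainGroup],
    t: ThresholdSet,
) -> Tier2Summary:
    """Combine the Tier-2 criteria into a provisional group.

    Precedence: biopersistent fiber -> MG2; globular high dissolution -> MG1
    (terminal); any active/precautionary trigger (reactivity, cellular,
    dispersibility on non-fibers, or a carried-over composition indication)
    -> provisional MG4; otherwise provisional MG3.  Provisional MG3/MG4 are
    only indications until Tier 3 confirms or corrects them.
    """
    s, iv = record.system, record.invitro
    fiber = MainGroup.MG2 in tier1_indications
    warnings: list[str] = []

    diss = eval_dissolution(s, fiber, t)
    if fiber:
        if diss.outcome in (Outcome.TRIGGER, Outcome.MISSING_PRECAUTIONARY):
            return Tier2Summary(group=MainGroup.MG2, terminal=True, trace=[diss])
        # fiber-shaped but dissolving: fall back to the globular track
        warnings.append(
            "fiber indication dropped: dissolution at/above threshold"
        )
        diss_globular = eval_dissolution(s, False, t)
        if diss_globular.outcome is Outcome.TRIGGER:
            return Tier2Summary(
                group=MainGroup.MG1,
                terminal=True,
                trace=[diss, diss_globular],
                warnings=warnings,
            )
        trace = [diss, diss_globular]
    else:
        if diss.outcome is Outcome.TRIGGER:
            return Tier2Summary(group=MainGroup.MG1, terminal=True, trace=[diss])
        trace = [diss]

    react = eval_surface_reactivity(s, t)
    disp = eval_dispersibility(s, t)
    epi = eval_epithelial(iv, t)
    mac = macrophage_call(iv, t)
    mac_eval = _macrophage_evaluation(mac, epi, t)
    charge = eval_surface_charge(s, t)
    trace += [react, disp, epi, mac_eval, charge]

    mg4 = (
        react.outcome in (Outcome.TRIGGER, Outcome.MISSING_PRECAUTIONARY)
        or epi.outcome in (Outcome.TRIGGER, Outcome.MISSING_PRECAUTIONARY)
        or mac_eval.outcome in (Outcome.TRIGGER, Outcome.MISSING_PRECAUTIONARY)
        or disp.outcome is Outcome.TRIGGER  # non-fiber track by construction
        or MainGroup.MG4 in tier1_indications
    )
    group = MainGroup.MG4 if mg4 else MainGroup.MG3
    return Tier2Summary(
        group=group, terminal=False, trace=trace, macrophage=mac, warnings=warnings
    )


def _macrophage_evaluation(
    mac: MacrophageCall, epithelial: CriterionEvaluation, t: ThresholdSet
) -> CriterionEvaluation:
    """Wrap the macrophage call as a trace entry.

    A not-assessable assay is ``not_applicable`` when the epithelial assay
    covers the cellular-effects criterion, and precautionary when it does not
    (no cellular information at all).
    """
    if mac.call is MacrophageCallResult.NOT_ASSESSABLE:
        epithelial_covers = epithelial.outcome in (
            Outcome.TRIGGER,
            Outcome.NO_TRIGGER,
        )
        return CriterionEvaluation(
            criterion_id=CriterionId.MACROPHAGE_ASSAY,
            tier=2,
            input_value=MISSING,
            threshold=float(t.macrophage_min_positive_params),
            comparison=Comparison.GE,
            outcome=Outcome.NOT_APPLICABLE
            if epithelial_covers
            else Outcome.MISSING_PRECAUTIONARY,
            note=mac.note or "macrophage assay not assessable",
        )
    return CriterionEvaluation(
        criterion_id=CriterionId.MACROPHAGE_ASSAY,
        tier=2,
        input_value=float(mac.positive_params),
        threshold=float(t.macrophage_min_positive_params),
        comparison=Comparison.GE,
        outcome=Outcome.TRIGGER
        if mac.call is MacrophageCallResult.ACTIVE
        else Outcome.NO_TRIGGER,
        note=f"{mac.positive_params} of 4 parameters positive",
    )
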