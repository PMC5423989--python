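"""Domain types for nanomaterial characterization records and group assignments.

All quantities are stored in the units of the framework's criteria table and
never converted:

=============================  =============
water solubility, dissolution  mg/L
primary particle size          nm
fiber length / diameter        um
surface area                   m2/g
FRAS surface reactivity        uU per m2*h
agglomerate diameter           nm
zeta potential                 mV
epithelial LOEC                ug/cm2
macrophage LOEC                mm2/mL (surface-area dose)
STIS NOAEC                     mg/m3
pulmonary half-life t50        days
biodistribution fractions      percent of total dose
=============================  =============

A value that was not measured is ``None`` ("missing") and is never silently
replaced by a numeric default; how missingness propagates into the grouping
decision is the business of the tier evaluators, not of the record types.
"""

from __future__ import annotations

import enum
import math
from typing import Literal, Optional

from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    field_validator,
    model_validator,
)

__all__ = [
    "ShapeClass",
    "MainGroup",
    "AssignmentStatus",
    "NoaecRange",
    "ReversibilitySubgroup",
    "BiodistributionSubgroup",
    "DustLimitAnnotation",
    "NoaecCensoring",
    "EffectsCourse",
    "ReleasePossible",
    "ExposureRoute",
    "MacrophageParam",
    "Comparison",
    "CriterionId",
    "Outcome",
    "ComponentEntry",
    "IntrinsicProperties",
    "SystemDependentProperties",
    "MacrophageParamResult",
    "InVitroResults",
    "BiodistributionProfile",
    "InVivoResults",
    "ExposureQualifiers",
    "MaterialRecord",
    "ThresholdSet",
    "CriterionEvaluation",
    "GroupAssignment",
    "MISSING",
]

#: sentinel used in serialized criterion traces for absent inputs
MISSING: Literal["missing"] = "missing"


class _StrEnum(str, enum.Enum):
    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ShapeClass(_StrEnum):
    GLOBULAR = "globular"
    PLATELET = "platelet"
    FIBER_LIKE = "fiber_like"
    OTHER = "other"


class MainGroup(_StrEnum):
    MG1 = "MG1"  # soluble
    MG2 = "MG2"  # biopersistent high aspect ratio
    MG3 = "MG3"  # passive
    MG4 = "MG4"  # active


class AssignmentStatus(_StrEnum):
    INDICATED = "indicated"
    ASSIGNED = "assigned"
    CONFIRMED = "confirmed"
    CORRECTED = "corrected"
    WAIVED = "waived"


class NoaecRange(_StrEnum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    UNKNOWN = "unknown"


class ReversibilitySubgroup(_StrEnum):
    REVERSIBLE = "reversible"
    PROGRESSIVE = "progressive"
    UNKNOWN = "unknown"


class BiodistributionSubgroup(_StrEnum):
    PRIMARY_ORGAN_ONLY = "primary_organ_only"
    MPS = "mps"
    BEYOND_MPS = "beyond_mps"
    UNKNOWN = "unknown"


class DustLimitAnnotation(_StrEnum):
    GENERAL_DUST_LIMIT_SUFFICIENT = "general_dust_limit_sufficient"
    SPECIFIC_OEL_NEEDED = "specific_oel_needed"
    NOT_APPLICABLE = "not_applicable"


class NoaecCensoring(_StrEnum):
    EXACT = "exact"
    AT_LEAST = "at_least"  # ">=X" / ">X": no adverse effect up to highest tested


class EffectsCourse(_StrEnum):
    """Post-exposure course of effects observed in the short-term inhalation study."""

    REGRESSION = "regression"
    PROGRESSION = "progression"
    NONE = "none"
    UNKNOWN = "unknown"


class ReleasePossible(_StrEnum):
    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


class ExposureRoute(_StrEnum):
    INHALATION = "inhalation"
    ORAL = "oral"
    DERMAL = "dermal"
    OCULAR = "ocular"


class MacrophageParam(_StrEnum):
    LDH = "ldh"
    GLUCURONIDASE = "glucuronidase"
    TNF_ALPHA = "tnf_alpha"
    ROS = "ros"


class Comparison(_StrEnum):
    GT = "gt"
    GE = "ge"
    LT = "lt"
    LE = "le"


class CriterionId(_StrEnum):
    WATER_SOLUBILITY = "water_solubility"
    MORPHOLOGY = "morphology"
    COMPOSITION = "composition"
    DISSOLUTION = "dissolution"
    SURFACE_REACTIVITY = "surface_reactivity"
    DISPERSIBILITY = "dispersibility"
    EPITHELIAL_CYTOTOXICITY = "epithelial_cytotoxicity"
    MACROPHAGE_ASSAY = "macrophage_assay"
    SURFACE_CHARGE = "surface_charge"
    STIS_NOAEC = "stis_noaec"
    BIOPERSISTENCE = "biopersistence"
    BIODISTRIBUTION = "biodistribution"
    RELEASE_QUALIFIER = "release_qualifier"


class Outcome(_StrEnum):
    TRIGGER = "trigger"
    NO_TRIGGER = "no_trigger"
    MISSING_PRECAUTIONARY = "missing_precautionary"
    NOT_APPLICABLE = "not_applicable"


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    @field_validator("*", mode="before")
    @classmethod
    def _reject_non_finite(cls, v):
        if isinstance(v, float) and not math.isfinite(v):
            raise ValueError("numeric fields must be finite")
        return v


class ComponentEntry(_Base):
    """One constituent (including impurities) of the material."""

    name: str
    mass_fraction: float = Field(ge=0, le=100, description="percent of total mass")
    #: component carries a GHS classification for systemic effects
    ghs_systemic: bool = False


class IntrinsicProperties(_Base):
    water_solubility: Optional[float] = Field(default=None, ge=0, description="mg/L")
    primary_particle_size: Optional[float] = Field(default=None, ge=0, description="nm")
    aspect_ratio: Optional[float] = Field(default=None, ge=1)
    length: Optional[float] = Field(default=None, ge=0, description="um")
    diameter: Optional[float] = Field(default=None, ge=0, description="um")
    shape_class: Optional[ShapeClass] = None
    composition: list[ComponentEntry] = Field(default_factory=list)
    # supplementary criteria -- never a sole basis for assignment
    surface_area: Optional[float] = Field(default=None, ge=0, description="m2/g")
    surface_chemistry: Optional[str] = None

    @model_validator(mode="after")
    def _composition_mass_balance(self):
        total = sum(c.mass_fraction for c in self.composition)
        if total > 100 + 1e-9:
            raise ValueError(
                f"composition mass fractions sum to {total:g} > 100%"
            )
        return self


class SystemDependentProperties(_Base):
    dissolution_biological: Optional[float] = Field(
        default=None, ge=0, description="mg/L, dissolution in biological fluids"
    )
    medium_label: Optional[str] = None
    surface_reactivity_relative: Optional[float] = Field(
        default=None, ge=0, description="fraction of Mn2O3 reactivity (1.0 = equal)"
    )
    surface_reactivity_fras: Optional[float] = Field(
        default=None, ge=0, description="uU FRAS per m2*h"
    )
    aan: Optional[float] = Field(
        default=None, ge=1, description="average agglomeration number (aan >= 1)"
    )
    agglomerate_diameter: Optional[float] = Field(default=None, ge=0, description="nm")
    zeta_potential: Optional[float] = Field(default=None, description="mV, signed")
    hydrophobicity_class: Optional[str] = None


class MacrophageParamResult(_Base):
    """Outcome for one of the four alveolar-macrophage assay parameters.

    Exactly one of ``loec_surface_area`` (lowest surface-area dose, mm2/mL,
    with a significant alteration) or ``no_effect`` holds.
    """

    loec_surface_area: Optional[float] = Field(default=None, gt=0)
    no_effect: bool = False

    @model_validator(mode="after")
    def _exactly_one(self):
        if (self.loec_surface_area is None) == (not self.no_effect):
            raise ValueError(
                "exactly one of loec_surface_area / no_effect=true must be given"
            )
        return self


class InVitroResults(_Base):
    epithelial_loec: Optional[float] = Field(
        default=None, gt=0, description="ug/cm2, lowest effective concentration"
    )
    epithelial_no_effect_up_to: Optional[float] = Field(
        default=None, gt=0, description='ug/cm2, "no effect up to X"'
    )
    macrophage_params: Optional[dict[MacrophageParam, MacrophageParamResult]] = None

    @model_validator(mode="after")
    def _loec_xor_bound(self):
        if self.epithelial_loec is not None and self.epithelial_no_effect_up_to is not None:
            raise ValueError(
                "epithelial result is either a LOEC or a no-effect bound, not both"
            )
        return self


class BiodistributionProfile(_Base):
    fraction_primary_organ: float = Field(ge=0, le=100, description="% of total dose")
    fraction_mps: float = Field(ge=0, le=100, description="% of total dose in MPS organs")
    fraction_beyond_mps: float = Field(ge=0, le=100, description="% systemic outside MPS")


class InVivoResults(_Base):
    stis_noaec: Optional[float] = Field(default=None, gt=0, description="mg/m3")
    noaec_censoring: NoaecCensoring = NoaecCensoring.EXACT
    effects_regression_or_progression: EffectsCourse = EffectsCourse.UNKNOWN
    t50_days: Optional[float] = Field(default=None, gt=0)
    biodistribution: Optional[BiodistributionProfile] = None


class ExposureQualifiers(_Base):
    release_possible: ReleasePossible = ReleasePossible.UNKNOWN
    exposure_routes: set[ExposureRoute] = Field(default_factory=set)
    use_stage_notes: Optional[str] = None
    dustiness_class: Optional[str] = None


class MaterialRecord(_Base):
    material_id: str = Field(min_length=1)
    name: str = ""
    intrinsic: IntrinsicProperties = Field(default_factory=IntrinsicProperties)
    system: SystemDependentProperties = Field(default_factory=SystemDependentProperties)
    invitro: InVitroResults = Field(default_factory=InVitroResults)
    invivo: Optional[InVivoResults] = None
    qualifiers: ExposureQualifiers = Field(default_factory=ExposureQualifiers)
    notes: str = ""


class ThresholdSet(_Base):
    """Every numeric cut-off of the grouping-criteria table, configurable.

    Defaults are the published framework values; comparison directions are
    fixed in the tier evaluators (printed operators, e.g. solubility strictly
    ``>``, GHS component ``>=``).
    """

    water_solubility_mg_l: float = Field(default=100.0, gt=0)
    dissolution_mg_l: float = Field(default=100.0, gt=0)
    aspect_ratio_min: float = Field(default=3.0, gt=0)
    fiber_length_um: float = Field(default=5.0, gt=0)
    fiber_diameter_max_um: float = Field(default=3.0, gt=0)
    ghs_component_pct: float = Field(default=0.1, gt=0)
    reactivity_relative_min: float = Field(default=0.10, gt=0)
    reactivity_fras_min: float = Field(default=0.19, gt=0)
    aan_max: float = Field(default=3.0, gt=0)
    dispersible_diameter_nm: float = Field(default=100.0, gt=0)
    epithelial_loec_ug_cm2: float = Field(default=10.0, gt=0)
    macrophage_overload_mm2_ml: float = Field(default=6000.0, gt=0)
    macrophage_min_positive_params: int = Field(default=2, gt=0)
    #: Range I upper bound; 0.5 by default, 0.1 under the alternate reading
    noaec_range_i_mg_m3: float = Field(default=0.5, gt=0)
    noaec_range_ii_mg_m3: float = Field(default=1.0, gt=0)
    noaec_range_iii_mg_m3: float = Field(default=10.0, gt=0)
    t50_days: float = Field(default=40.0, gt=0)
    zeta_positive_mv: float = Field(default=10.0, gt=0)
    biodistribution_fraction_pct: float = Field(default=1.0, gt=0)
    #: enforce the WHO fiber length criterion (> 5 um) in addition to AR/diameter
    who_fiber_rule_strict: bool = False
    #: Range I additionally requires effects without regression (default reading)
    range_i_requires_persistent_effects: bool = True

    @model_validator(mode="after")
    def _ordered_ranges(self):
        if not (
            self.noaec_range_i_mg_m3
            < self.noaec_range_ii_mg_m3
            < self.noaec_range_iii_mg_m3
        ):
            raise ValueError("NOAEC range bounds must satisfy I < II < III")
        return self


class CriterionEvaluation(_Base):
    """Audit-trace unit: one criterion's input, threshold, and outcome."""

    criterion_id: CriterionId
    tier: int = Field(ge=1, le=3)
    input_value: float | Literal["missing"]
    threshold: Optional[float] = None
    comparison: Optional[Comparison] = None
    outcome: Outcome
    note: str = ""

    @model_validator(mode="after")
    def _missing_consistency(self):
        if self.outcome is Outcome.MISSING_PRECAUTIONARY and self.input_value != MISSING:
            raise ValueError("missing_precautionary requires input_value == 'missing'")
        return self


class GroupAssignment(_Base):
    """Final outcome of the tiered classification for one material."""

    material_id: str
    main_group: Optional[MainGroup] = None
    #: group from the non-animal tiers 1+2 alone (before any tier-3 resolution)
    nonanimal_group: Optional[MainGroup] = None
    status: AssignmentStatus
    tier_reached: int = Field(ge=1, le=3)
    noaec_range: NoaecRange = NoaecRange.UNKNOWN
    reversibility_subgroup: ReversibilitySubgroup = ReversibilitySubgroup.UNKNOWN
    biodistribution_subgroup: BiodistributionSubgroup = BiodistributionSubgroup.UNKNOWN
    dust_limit_annotation: DustLimitAnnotation = DustLimitAnnotation.NOT_APPLICABLE
    trace: list[CriterionEvaluation] = Field(default_factory=list)
    warnings: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _subgroup_scope(self):
        if self.status is AssignmentStatus.WAIVED:
            if not any(
                e.criterion_id is CriterionId.RELEASE_QUALIFIER for e in self.trace
            ):
                raise ValueError("waived assignment must trace the release qualifier")
            return self
        scoped = self.main_group in (MainGroup.MG2, MainGroup.MG4) or self.tier_reached == 3
        if not scoped:
            for fld in ("noaec_range", "reversibility_subgroup", "biodistribution_subgroup"):
                if getattr(self, fld) != "unknown":
                    raise ValueError(
                        f"{fld} may only be set for MG2/MG4 or tier-3 assignments"
                    )
        return self
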