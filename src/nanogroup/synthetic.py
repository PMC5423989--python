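"""Seeded synthetic-material generator for recovery and property testing.

Records are generated per intended main group with every criterion value
drawn uniformly from a range lying strictly on the group-consistent side of
its threshold, so that at zero missingness the classifier recovers the
intended group for every record by construction.  Optional missingness
removes only fields whose absence cannot change the assigned group
(precaution-neutral for the intended group), keeping the ground truth
well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .engine import EngineConfig, classify_batch
from .records import (
    GroupAssignment,
    MainGroup,
    MaterialRecord,
    Outcome,
)

__all__ = [
    "SyntheticSpec",
    "SyntheticCohort",
    "generate_cohort",
    "recovery_report",
    "RecoveryReport",
    "MG4_CHANNELS",
]

#: tier-2 activity channels a synthetic MG4 record can be triggered through
MG4_CHANNELS = ("reactivity", "macrophage", "epithelial", "dispersibility", "composition")


class SyntheticSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_per_group: dict[MainGroup, int] = Field(
        default_factory=lambda: {g: 10 for g in MainGroup}
    )
    seed: int = 0
    missingness_rate: float = Field(default=0.0, ge=0.0, lt=1.0)
    mg4_channels: tuple[str, ...] = MG4_CHANNELS
    #: fraction of MG3/MG4 records carrying a short-term inhalation study
    stis_fraction: float = Field(default=1.0, ge=0.0, le=1.0)

    @field_validator("n_per_group")
    @classmethod
    def _nonneg(cls, v):
        if any(n < 0 for n in v.values()):
            raise ValueError("group counts must be >= 0")
        return v

    @field_validator("mg4_channels")
    @classmethod
    def _known_channels(cls, v):
        unknown = set(v) - set(MG4_CHANNELS)
        if unknown or not v:
            raise ValueError(f"unknown or empty MG4 channels: {sorted(unknown)}")
        return v


@dataclass
class SyntheticCohort:
    records: list[MaterialRecord]
    intended: list[MainGroup]
    channels: list[Optional[str]] = dc_field(default_factory=list)


def _passive_macrophage() -> dict:
    return {k: {"no_effect": True} for k in ("ldh", "glucuronidase", "tnf_alpha", "ros")}


def _base(rng: np.random.Generator) -> dict:
    """Fields common to every synthetic record, all on the passive side."""
    return {
        "intrinsic": {
            "water_solubility": float(rng.uniform(0.01, 50)),
            "primary_particle_size": float(rng.uniform(5, 95)),
            "aspect_ratio": float(rng.uniform(1.0, 2.5)),
            "shape_class": "globular",
            "surface_area": float(rng.uniform(5, 300)),
            "composition": [{"name": "core", "mass_fraction": 99.0}],
        },
        "system": {
            "dissolution_biological": float(rng.uniform(0.01, 50)),
            "surface_reactivity_relative": float(rng.uniform(0.0, 0.08)),
            "aan": float(rng.uniform(3.5, 15)),
            "agglomerate_diameter": float(rng.uniform(150, 800)),
            "zeta_potential": float(rng.uniform(-50, 5)),
        },
        "invitro": {
            "epithelial_no_effect_up_to": float(rng.uniform(15, 100)),
            "macrophage_params": _passive_macrophage(),
        },
        "qualifiers": {"release_possible": "yes", "exposure_routes": ["inhalation"]},
    }


def _make_mg1(rng: np.random.Generator, d: dict) -> None:
    d["intrinsic"]["water_solubility"] = float(10 ** rng.uniform(np.log10(150), np.log10(5000)))
    d["invivo"] = {"t50_days": float(rng.uniform(1, 35))}


def _make_mg2(rng: np.random.Generator, d: dict) -> None:
    d["intrinsic"].update(
        {
            "aspect_ratio": float(rng.uniform(5, 200)),
            "length": float(rng.uniform(6, 20)),
            "diameter": float(rng.uniform(0.01, 0.5)),
            "shape_class": "fiber_like",
        }
    )
    d["system"]["dissolution_biological"] = float(rng.uniform(0.01, 50))
    d["invivo"] = {
        "stis_noaec": float(rng.uniform(0.05, 0.45)),
        "noaec_censoring": "exact",
        "effects_regression_or_progression": "progression",
    }


def _make_mg3(rng: np.random.Generator, d: dict, with_stis: bool) -> None:
    if with_stis:
        d["invivo"] = {
            "stis_noaec": float(rng.uniform(15, 80)),
            "noaec_censoring": "at_least" if rng.random() < 0.5 else "exact",
            "t50_days": float(rng.uniform(5, 35)),
        }


def _make_mg4(rng: np.random.Generator, d: dict, channel: str, with_stis: bool) -> None:
    if channel == "reactivity":
        d["system"]["surface_reactivity_relative"] = float(rng.uniform(0.12, 1.0))
    elif channel == "macrophage":
        params = _passive_macrophage()
        n_pos = int(rng.integers(2, 5))
        keys = list(params)
        for k in rng.choice(keys, size=n_pos, replace=False):
            params[k] = {"loec_surface_area": float(rng.uniform(500, 5500))}
        d["invitro"]["macrophage_params"] = params
    elif channel == "epithelial":
        d["invitro"].pop("epithelial_no_effect_up_to", None)
        d["invitro"]["epithelial_loec"] = float(rng.uniform(0.5, 9.5))
    elif channel == "dispersibility":
        d["system"]["aan"] = float(rng.uniform(1.0, 2.8))
        d["system"]["agglomerate_diameter"] = float(rng.uniform(120, 600))
    elif channel == "composition":
        d["intrinsic"]["composition"] = [
            {"name": "core", "mass_fraction": 90.0},
            {"name": "Ni impurity", "mass_fraction": float(rng.uniform(0.15, 5)),
             "ghs_systemic": True},
        ]
    else:  # pragma: no cover
        raise ValueError(channel)
    if with_stis:
        d["invivo"] = {
            "stis_noaec": float(10 ** rng.uniform(np.log10(0.15), np.log10(9))),
            "noaec_censoring": "exact",
            "effects_regression_or_progression": "progression",
            "t50_days": float(rng.uniform(45, 300)),
        }


# fields whose deletion cannot change the assigned group for the intended one
_DELETABLE_COMMON = (
    ("intrinsic", "primary_particle_size"),
    ("intrinsic", "surface_area"),
    ("system", "zeta_potential"),
    ("system", "agglomerate_diameter"),
    ("invivo", "t50_days"),
)
_DELETABLE = {
    MainGroup.MG1: _DELETABLE_COMMON,
    MainGroup.MG2: _DELETABLE_COMMON + (("intrinsic", "length"),),
    MainGroup.MG3: _DELETABLE_COMMON,
    MainGroup.MG4: _DELETABLE_COMMON,
}


def _apply_missingness(rng, d: dict, group: MainGroup, rate: float, channel) -> None:
    for section, key in _DELETABLE[group]:
        if group is MainGroup.MG4 and channel == "dispersibility" and key == "agglomerate_diameter":
            continue  # keep the channel's paired measurement intact
        if section in d and key in d[section] and rng.random() < rate:
            del d[section][key]


def generate_cohort(spec: SyntheticSpec) -> SyntheticCohort:
    """Generate a cohort of structurally valid records with known groups.

    Deterministic under a fixed seed; records are emitted in MG1..MG4 order
    with ids ``SYN-<group>-<index>``.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[MaterialRecord] = []
    intended: list[MainGroup] = []
    channels: list[Optional[str]] = []
    for group in MainGroup:
        n = spec.n_per_group.get(group, 0)
        for i in range(n):
            d = _base(rng)
            channel: Optional[str] = None
            if group is MainGroup.MG1:
                _make_mg1(rng, d)
            elif group is MainGroup.MG2:
                _make_mg2(rng, d)
            elif group is MainGroup.MG3:
                _make_mg3(rng, d, rng.random() < spec.stis_fraction)
            else:
                channel = spec.mg4_channels[i % len(spec.mg4_channels)]
                _make_mg4(rng, d, channel, rng.random() < spec.stis_fraction)
            if spec.missingness_rate > 0:
                _apply_missingness(rng, d, group, spec.missingness_rate, channel)
            d["material_id"] = f"SYN-{group.value}-{i:04d}"
            d["name"] = f"synthetic {group.value} material #{i}"
            records.append(MaterialRecord.model_validate(d))
            intended.append(group)
            channels.append(channel)
    return SyntheticCohort(records=records, intended=intended, channels=channels)


@dataclass
class RecoveryReport:
    matrix: pd.DataFrame  # rows intended, columns assigned
    mismatches: list[dict]

    @property
    def accuracy(self) -> float:
        total = int(self.matrix.to_numpy().sum())
        if total == 0:
            return float("nan")
        return float(np.trace(self.matrix.to_numpy()) / total)


def recovery_report(
    cohort: SyntheticCohort,
    assignments: Optional[list[GroupAssignment]] = None,
    config: Optional[EngineConfig] = None,
) -> RecoveryReport:
    """Intended-vs-assigned confusion matrix over a synthetic cohort.

    Off-diagonal records are listed with the trace criteria responsible for
    the assigned group (triggers and precautionary missing-data outcomes).
    """
    if assignments is None:
        assignments = classify_batch(cohort.records, config).assignments
    if len(assignments) != len(cohort.records):
        raise ValueError("cohort and assignments differ in length")
    groups = [g.value for g in MainGroup]
    mat = pd.DataFrame(0, index=groups, columns=groups, dtype=int)
    mismatches: list[dict] = []
    for rec, want, a in zip(cohort.records, cohort.intended, assignments):
        got = a.main_group
        if got is None:
            continue  # waived records do not enter the matrix
        mat.loc[want.value, got.value] += 1
        if got != want:
            responsible = [
                e.criterion_id.value
                for e in a.trace
                if e.outcome in (Outcome.TRIGGER, Outcome.MISSING_PRECAUTIONARY)
            ]
            mismatches.append(
                {
                    "material_id": rec.material_id,
                    "intended": want.value,
                    "assigned": got.value,
                    "responsible_criteria": responsible,
                }
            )
    return RecoveryReport(matrix=mat, mismatches=mismatches)
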