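"""Shared fixtures: record builders used across the suite."""

from __future__ import annotations

import copy

import pytest

from nanogroup.records import MaterialRecord, ThresholdSet

PASSIVE_MACROPHAGE = {
    "ldh": {"no_effect": True},
    "glucuronidase": {"no_effect": True},
    "tnf_alpha": {"no_effect": True},
    "ros": {"no_effect": True},
}


def active_macrophage(**loecs) -> dict:
    d = copy.deepcopy(PASSIVE_MACROPHAGE)
    for k, v in loecs.items():
        d[k] = {"loec_surface_area": v}
    return d


#: fully measured, everywhere-passive record -> provisional MG3
PASSIVE_RECORD = {
    "material_id": "TEST-PASSIVE",
    "name": "fully passive test material",
    "intrinsic": {
        "water_solubility": 1.0,
        "primary_particle_size": 40,
        "aspect_ratio": 1.2,
        "shape_class": "globular",
        "composition": [{"name": "core", "mass_fraction": 99.0}],
    },
    "system": {
        "dissolution_biological": 5.0,
        "surface_reactivity_relative": 0.02,
        "aan": 8.0,
        "agglomerate_diameter": 400.0,
        "zeta_potential": -20.0,
    },
    "invitro": {
        "epithelial_no_effect_up_to": 50.0,
        "macrophage_params": PASSIVE_MACROPHAGE,
    },
    "qualifiers": {"release_possible": "yes", "exposure_routes": ["inhalation"]},
}


def make_record(**overrides) -> MaterialRecord:
    """Passive baseline record with nested overrides merged in.

    ``make_record(system={"aan": 1.5})`` changes only ``system.aan``; a value
    of ``None`` for a key removes it (missing).
    """
    d = copy.deepcopy(PASSIVE_RECORD)
    for section, patch in overrides.items():
        if not isinstance(patch, dict) or section not in d or not isinstance(d.get(section), dict):
            d[section] = patch
            continue
        for k, v in patch.items():
            if v is None:
                d[section].pop(k, None)
            else:
                d[section][k] = v
    return MaterialRecord.model_validate(d)


@pytest.fixture
def thresholds() -> ThresholdSet:
    return ThresholdSet()


@pytest.fixture
def passive_record() -> MaterialRecord:
    return make_record()
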