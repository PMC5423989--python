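"""End-to-end engine behaviour: precedence, waiver, traces, batching."""

import pytest

from nanogroup import (
    EngineConfig,
    MainGroup,
    classify,
    classify_batch,
    write_assignment,
)
from nanogroup.records import (
    AssignmentStatus,
    CriterionId,
    DustLimitAnnotation,
    ExposureQualifiers,
    MaterialRecord,
    NoaecRange,
    Outcome,
)
from nanogroup.engine import check_waiver

from conftest import active_macrophage, make_record


@pytest.mark.parametrize(
    "release, waived", [("no", True), ("yes", False), ("unknown", False)]
)
def test_waiver_only_on_positive_exclusion(release, waived):
    q = ExposureQualifiers(release_possible=release)
    assert check_waiver(q) is waived


def test_waived_assignment_has_no_group_and_traces_qualifier():
    rec = make_record(qualifiers={"release_possible": "no"})
    a = classify(rec)
    assert a.status is AssignmentStatus.WAIVED
    assert a.main_group is None
    assert any(e.criterion_id is CriterionId.RELEASE_QUALIFIER for e in a.trace)


class TestPrecedence:
    def test_soluble_reactive_record_is_mg1_at_tier1(self):
        rec = make_record(
            intrinsic={"water_solubility": 500},
            system={"surface_reactivity_relative": 0.8},
        )
        a = classify(rec)
        assert a.main_group is MainGroup.MG1
        assert a.tier_reached == 1
        # tier-2 criteria were never consulted (data economy)
        assert all(e.tier == 1 for e in a.trace)

    def test_biopersistent_fiber_beats_mg4_triggers(self):
        rec = make_record(
            intrinsic={"aspect_ratio": 100, "length": 10, "diameter": 0.02,
                       "shape_class": "fiber_like"},
            system={"dissolution_biological": 0.5, "surface_reactivity_relative": 0.9},
        )
        a = classify(rec)
        assert a.main_group is MainGroup.MG2

    def test_mg1_via_tier2_dissolution_terminal(self):
        rec = make_record(system={"dissolution_biological": 800})
        a = classify(rec)
        assert a.main_group is MainGroup.MG1
        assert a.tier_reached == 2
        assert a.status is AssignmentStatus.ASSIGNED

    def test_mg1_confirmed_by_short_half_life(self):
        rec = make_record(
            intrinsic={"water_solubility": 500}, invivo={"t50_days": 5}
        )
        a = classify(rec)
        assert a.main_group is MainGroup.MG1
        assert a.status is AssignmentStatus.CONFIRMED
        assert a.tier_reached == 3

    def test_mg1_with_long_half_life_warns(self):
        rec = make_record(
            intrinsic={"water_solubility": 500}, invivo={"t50_days": 200}
        )
        a = classify(rec)
        assert a.main_group is MainGroup.MG1
        assert a.status is AssignmentStatus.ASSIGNED
        assert any("t50" in w for w in a.warnings)


def test_no_data_record_is_precautionary_mg4_with_warning():
    rec = MaterialRecord(material_id="EMPTY")
    a = classify(rec)
    assert a.main_group is MainGroup.MG4
    assert a.status is AssignmentStatus.INDICATED
    precautionary = [e for e in a.trace if e.outcome is Outcome.MISSING_PRECAUTIONARY]
    assert {e.criterion_id for e in precautionary} >= {
        CriterionId.SURFACE_REACTIVITY,
        CriterionId.EPITHELIAL_CYTOTOXICITY,
    }
    assert any("data-poor" in w for w in a.warnings)


def test_graphite_nanoplatelets_pattern_missing_reactivity_corrected():
    rec = make_record(
        system={"surface_reactivity_relative": None},
        invivo={"stis_noaec": 10, "noaec_censoring": "at_least"},
    )
    a = classify(rec)
    assert a.nonanimal_group is MainGroup.MG4
    assert a.main_group is MainGroup.MG3
    assert a.status is AssignmentStatus.CORRECTED
    assert a.noaec_range is NoaecRange.IV


def test_dust_limit_annotation_follows_final_group():
    mg3 = classify(make_record(invivo={"stis_noaec": 50}))
    assert mg3.dust_limit_annotation is DustLimitAnnotation.GENERAL_DUST_LIMIT_SUFFICIENT
    mg4 = classify(
        make_record(
            invitro={"macrophage_params": active_macrophage(ldh=2000, ros=2500)},
            invivo={"stis_noaec": 2, "effects_regression_or_progression": "progression"},
        )
    )
    assert mg4.dust_limit_annotation is DustLimitAnnotation.SPECIFIC_OEL_NEEDED
    mg1 = classify(make_record(intrinsic={"water_solubility": 500}))
    assert mg1.dust_limit_annotation is DustLimitAnnotation.NOT_APPLICABLE


def test_non_inhalation_route_keeps_tier2_with_note():
    rec = make_record(qualifiers={"exposure_routes": ["oral"]})
    a = classify(rec)
    assert a.tier_reached == 2
    assert any("route not covered" in w for w in a.warnings)


def test_trace_is_ordered_by_tier():
    rec = make_record(invivo={"stis_noaec": 50, "t50_days": 20})
    a = classify(rec)
    tiers = [e.tier for e in a.trace]
    assert tiers == sorted(tiers)


def test_classify_deterministic_and_serialization_stable():
    rec = make_record(invivo={"stis_noaec": 0.4,
                              "effects_regression_or_progression": "progression"})
    a1, a2 = classify(rec), classify(rec)
    assert a1 == a2
    assert write_assignment(a1, "json") == write_assignment(a2, "json")


def test_strict_who_variant_changes_short_fiber_outcome():
    from nanogroup.records import ThresholdSet

    rec = make_record(
        intrinsic={"aspect_ratio": 50, "length": 2, "diameter": 0.05,
                   "shape_class": "fiber_like"},
        system={"dissolution_biological": 0.5},
    )
    default = classify(rec)
    strict = classify(
        rec, EngineConfig(thresholds=ThresholdSet(who_fiber_rule_strict=True))
    )
    assert default.main_group is MainGroup.MG2
    assert strict.main_group is not MainGroup.MG2


def test_range_i_variant_rebands_but_keeps_group():
    from nanogroup.engine import RangeIVariant

    rec = make_record(
        invitro={"macrophage_params": active_macrophage(ldh=2000, ros=2500)},
        invivo={"stis_noaec": 0.3, "effects_regression_or_progression": "progression"},
    )
    table1 = classify(rec)
    table2 = classify(rec, EngineConfig(range_i_variant=RangeIVariant.TABLE2_0_1))
    assert table1.main_group is table2.main_group is MainGroup.MG4
    assert table1.noaec_range is NoaecRange.I
    assert table2.noaec_range is NoaecRange.II


class TestBatch:
    def test_empty_batch(self):
        res = classify_batch([])
        assert res.assignments == [] and res.errors == []
        assert len(res.summary()) == 0

    def test_error_isolation(self):
        good = [make_record(material_id=f"G{i}") for i in range(3)]
        res = classify_batch(good[:1] + ["not a record"] + good[1:])
        assert len(res.assignments) == 3
        assert len(res.errors) == 1

    def test_summary_counts_sum_to_non_waived(self):
        recs = [make_record(material_id=f"M{i}") for i in range(4)] + [
            make_record(material_id="W", qualifiers={"release_possible": "no"})
        ]
        res = classify_batch(recs)
        s = res.summary()
        non_waived = s[s.main_group != "waived"]["count"].sum()
        assert non_waived == 4
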