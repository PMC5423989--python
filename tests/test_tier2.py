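"""Tier-2 criteria: dissolution, reactivity, dispersibility, cellular effects."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from nanogroup.records import (
    InVitroResults,
    MacrophageParam,
    MacrophageParamResult,
    MainGroup,
    Outcome,
    SystemDependentProperties,
    ThresholdSet,
)
from nanogroup.tier2 import (
    MacrophageCallResult,
    eval_dispersibility,
    eval_dissolution,
    eval_epithelial,
    eval_surface_charge,
    eval_surface_reactivity,
    macrophage_call,
    tier2_summary,
)

from conftest import PASSIVE_MACROPHAGE, active_macrophage, make_record

T = ThresholdSet()


def _sys(**kw):
    return SystemDependentProperties(**kw)


@pytest.mark.parametrize(
    "fiber, dissolution, outcome",
    [
        (False, 500, Outcome.TRIGGER),      # globular, dissolves -> MG1 indication
        (False, 100, Outcome.NO_TRIGGER),   # strict ">"
        (False, None, Outcome.NO_TRIGGER),
        (True, 1, Outcome.TRIGGER),         # biopersistent fiber -> MG2
        (True, 100, Outcome.NO_TRIGGER),    # strict "<"
        (True, None, Outcome.MISSING_PRECAUTIONARY),
    ],
)
def test_dissolution_two_tracks(fiber, dissolution, outcome):
    ev = eval_dissolution(_sys(dissolution_biological=dissolution), fiber, T)
    assert ev.outcome is outcome


@pytest.mark.parametrize(
    "rel, fras, outcome",
    [
        (0.10, None, Outcome.TRIGGER),   # boundary inclusive
        (0.09, None, Outcome.NO_TRIGGER),
        (None, 0.19, Outcome.TRIGGER),   # FRAS boundary inclusive
        (None, 0.01, Outcome.NO_TRIGGER),
        (None, None, Outcome.MISSING_PRECAUTIONARY),
        (0.5, 0.01, Outcome.TRIGGER),    # discordant -> conservative
        (0.01, 5.0, Outcome.TRIGGER),
    ],
)
def test_surface_reactivity_either_assay_inclusive(rel, fras, outcome):
    ev = eval_surface_reactivity(
        _sys(surface_reactivity_relative=rel, surface_reactivity_fras=fras), T
    )
    assert ev.outcome is outcome
    if rel is not None and fras is not None and (rel >= 0.10) != (fras >= 0.19):
        assert "discordant" in ev.note


@pytest.mark.parametrize(
    "aan, diam, outcome",
    [
        (1.5, None, Outcome.TRIGGER),
        (3.0, None, Outcome.NO_TRIGGER),    # strict "<"
        (None, 50, Outcome.TRIGGER),
        (None, 100, Outcome.NO_TRIGGER),    # strict "<"
        (8, 50, Outcome.TRIGGER),           # OR-semantics
        (8, 500, Outcome.NO_TRIGGER),
        (None, None, Outcome.NO_TRIGGER),   # agglomeration assumed
    ],
)
def test_dispersibility_or_semantics_and_default(aan, diam, outcome):
    ev = eval_dispersibility(_sys(aan=aan, agglomerate_diameter=diam), T)
    assert ev.outcome is outcome


@pytest.mark.parametrize(
    "loec, bound, has_mac, outcome",
    [
        (5, None, False, Outcome.TRIGGER),
        (10, None, False, Outcome.TRIGGER),      # boundary inclusive
        (11, None, False, Outcome.NO_TRIGGER),
        (None, 50, False, Outcome.NO_TRIGGER),   # no effect up to 50
        (None, None, True, Outcome.NOT_APPLICABLE),
        (None, None, False, Outcome.MISSING_PRECAUTIONARY),
        (None, 5, False, Outcome.MISSING_PRECAUTIONARY),  # bound below threshold
    ],
)
def test_epithelial_loec_and_missing_semantics(loec, bound, has_mac, outcome):
    iv = InVitroResults(
        epithelial_loec=loec,
        epithelial_no_effect_up_to=bound,
        macrophage_params=PASSIVE_MACROPHAGE if has_mac else None,
    )
    assert eval_epithelial(iv, T).outcome is outcome


class TestMacrophageCall:
    def test_two_of_four_active(self):
        iv = InVitroResults(macrophage_params=active_macrophage(ldh=2000, tnf_alpha=4000))
        call = macrophage_call(iv, T)
        assert call.positive_params == 2
        assert call.call is MacrophageCallResult.ACTIVE

    @pytest.mark.parametrize("n_pos, expected", [(0, "passive"), (1, "passive"),
                                                 (2, "active"), (4, "active")])
    def test_activity_threshold(self, n_pos, expected):
        params = list(MacrophageParam)[:n_pos]
        iv = InVitroResults(
            macrophage_params=active_macrophage(**{p.value: 1000 for p in params})
        )
        assert macrophage_call(iv, T).call.value == expected

    def test_boundary_loec_at_6000_not_positive(self):
        iv = InVitroResults(macrophage_params=active_macrophage(ros=6000))
        call = macrophage_call(iv, T)
        assert call.positive_params == 0
        assert call.call is MacrophageCallResult.PASSIVE

    def test_fewer_than_four_params_not_assessable(self):
        params = {
            MacrophageParam.LDH: MacrophageParamResult(loec_surface_area=100),
        }
        call = macrophage_call(InVitroResults(macrophage_params=params), T)
        assert call.call is MacrophageCallResult.NOT_ASSESSABLE
        assert "glucuronidase" in call.note and "ros" in call.note

    @settings(max_examples=30, derandomize=True)
    @given(perm=st.permutations(list(MacrophageParam)),
           loecs=st.lists(st.floats(100, 12000), min_size=4, max_size=4))
    def test_invariant_under_parameter_permutation(self, perm, loecs):
        base = {p.value: loecs[i] for i, p in enumerate(MacrophageParam)}
        permuted = {p.value: base[q.value] for p, q in zip(MacrophageParam, perm)}
        a = macrophage_call(InVitroResults(macrophage_params=active_macrophage(**base)), T)
        b = macrophage_call(InVitroResults(macrophage_params=active_macrophage(**permuted)), T)
        assert a.call == b.call and a.positive_params == b.positive_params


@pytest.mark.parametrize(
    "zeta, outcome",
    [(25, Outcome.TRIGGER), (10, Outcome.NO_TRIGGER), (-40, Outcome.NO_TRIGGER),
     (None, Outcome.NOT_APPLICABLE)],
)
def test_surface_charge_supplementary(zeta, outcome):
    assert eval_surface_charge(_sys(zeta_potential=zeta), T).outcome is outcome


class TestTier2Summary:
    def test_dispersible_passive_record_is_provisional_mg4(self):
        rec = make_record(system={"aan": 1.5})
        s = tier2_summary(rec, set(), T)
        assert s.group is MainGroup.MG4 and not s.terminal

    def test_macrophage_active_record_is_provisional_mg4(self):
        rec = make_record(invitro={"macrophage_params": active_macrophage(ldh=3000, ros=4000)})
        assert tier2_summary(rec, set(), T).group is MainGroup.MG4

    def test_all_passive_record_is_provisional_mg3(self, passive_record):
        s = tier2_summary(passive_record, set(), T)
        assert s.group is MainGroup.MG3 and not s.terminal

    def test_fiber_with_low_dissolution_terminal_mg2(self):
        rec = make_record(system={"dissolution_biological": 1})
        s = tier2_summary(rec, {MainGroup.MG2}, T)
        assert s.group is MainGroup.MG2 and s.terminal

    def test_dissolving_fiber_drops_fiber_indication(self):
        rec = make_record(system={"dissolution_biological": 500})
        s = tier2_summary(rec, {MainGroup.MG2}, T)
        assert s.group is MainGroup.MG1 and s.terminal
        assert any("fiber indication dropped" in w for w in s.warnings)

    def test_surface_charge_alone_never_assigns_mg4(self):
        rec = make_record(system={"zeta_potential": 40})
        assert tier2_summary(rec, set(), T).group is MainGroup.MG3

    def test_composition_indication_carried_to_mg4(self, passive_record):
        assert tier2_summary(passive_record, {MainGroup.MG4}, T).group is MainGroup.MG4


# precaution dominance: blanking any single present, non-triggering tier-2
# input never yields a less conservative provisional group
_FIELD_BLANKS = [
    ("system", "dissolution_biological"),
    ("system", "surface_reactivity_relative"),
    ("system", "aan"),
    ("system", "agglomerate_diameter"),
    ("system", "zeta_potential"),
    ("invitro", "epithelial_no_effect_up_to"),
]


@pytest.mark.parametrize("section,field", _FIELD_BLANKS)
def test_precaution_dominance_single_blank(section, field, passive_record):
    rank = {MainGroup.MG3: 0, MainGroup.MG4: 1}
    base = tier2_summary(passive_record, set(), T).group
    blanked = make_record(**{section: {field: None}})
    after = tier2_summary(blanked, set(), T).group
    assert rank[after] >= rank[base]
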