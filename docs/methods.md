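# Methods

## Scope and model

`nanogroup` implements the DF4nanoGrouping tiered decision framework as a
deterministic rule engine. There is no fitted statistical model: the
scientific content is (a) the criteria, thresholds and comparison directions
of the published grouping table, (b) the precedence and stop rules between
tiers, and (c) the precautionary semantics of missing data. The engine's
output is a `GroupAssignment` whose `trace` records one evaluation per
criterion actually consulted, in tier order — classification stops at the
earliest terminal tier, mirroring the framework's data-economy principle.

Out of scope (by design): genotoxicity criteria (the framework defines no
thresholds or benchmarks for them), chronic/long-term study evaluation,
route-specific rules beyond carrying the route qualifier, unit conversion,
macrophage volumetric-overload modelling, and DNEL/OEL derivation. The
occupational-limit output is an annotation only: final MG3 → the general
dust limit suffices; final MG4 → a specific OEL may be required.

## Thresholds and comparison directions

All cut-offs live in `ThresholdSet` and are overridable; defaults are the
published values. Comparison directions follow the printed operators and are
pinned by dedicated boundary tests:

| criterion | default threshold | direction |
|---|---|---|
| water solubility | 100 mg/L | strictly > |
| fiber shape | AR 3:1, length 5 µm, diameter 3 µm | AR >, length >, diameter < |
| GHS component | 0.1 % | ≥ |
| dissolution (biol. fluids) | 100 mg/L | globular strictly >, fiber strictly < |
| surface reactivity | 10 % of Mn₂O₃ ≡ 0.19 µU FRAS/m²·h | ≥ (either assay) |
| dispersibility | AAN 3 / 100 nm | strictly < (OR) |
| epithelial LOEC | 10 µg/cm² | ≤ |
| macrophage parameter LOEC | 6000 mm²/mL | strictly < ; active at ≥ 2 of 4 |
| STIS NOAEC ranges | 0.5 / 1 / 10 mg/m³ | IV at ≥ 10 |
| biopersistence t50 | 40 days | strictly < |
| positive surface charge | +10 mV | strictly > (supplementary only) |
| biodistribution fractions | 1 % of dose | strictly > |

Two published readings of the Range I bound exist (< 0.5 mg/m³ with a
"no regression or progression of effects" condition, vs < 0.1 mg/m³ as plain
banding). Both ship; `EngineConfig.range_i_variant` selects one, with the
0.5 mg/m³ + effects-condition reading as default. The choice never affects
the MG3/MG4 decision, which is governed solely by the 10 mg/m³ bound. Below
the Range I bound, an *unknown* course of effects bands conservatively as
Range I; regressing effects band as Range II. The WHO fiber length
criterion (> 5 µm) is relaxed by default (`who_fiber_rule_strict = False`):
biopersistent thin high-aspect-ratio materials are flagged for MG2 even when
shorter.

## Missing-data semantics

Missingness is directional, following the concern structure of the
framework rather than a uniform rule:

* **Non-precautionary:** missing water solubility or dissolution (MG1 is the
  *low*-particle-concern branch; concern flows onward), and missing
  dispersibility data ("agglomeration assumed", the benchmark behaviour of
  unfunctionalized suspended silica). Missing zeta potential is
  not applicable — surface charge is jointly evaluated with dispersibility
  and never assigns a group alone.
* **Precautionary:** surface reactivity that cannot be determined (MG4
  assumed — the graphite-nanoplatelets precedent); missing dissolution on a
  fiber-indicated material (biopersistence assumed); partial fiber evidence
  with missing dimensions; absence of *any* cellular assay. A record with no
  data at all is therefore provisional MG4 with a "data-poor" warning, never
  silently MG3.

A consequence worth stating plainly: deleting a present value can only move
the outcome in the conservative direction **unless the deleted value was
itself the sole trigger** of a non-precautionary criterion (e.g. the AAN of
a dispersibility-triggered record) — then its trigger disappears, because
absent dispersibility data legitimately default to "agglomeration assumed".
The engine-wide monotonicity property is accordingly stated, and tested,
over deletions of non-triggering inputs.

## Engine precedence and status vocabulary

MG1 at Tier 1 is terminal (`assigned`; upgraded to `confirmed` when
t50 < 40 d exists, with a warning instead when t50 contradicts it). A
biopersistent fiber is MG2 at Tier 2 (`assigned`, `confirmed` by any STIS;
a Range IV NOAEC does not demote a fiber — fiber hazard is not NOAEC-driven
— it only adds a warning). Provisional MG3/MG4 are `indicated` until Tier 3
`confirmed`/`corrected` them; Range IV corrects MG4 → MG3 (the only
correction observed in the case studies) and Ranges I–III would correct an
underpredicted MG3 → MG4. A fiber whose dissolution reaches the threshold
drops the fiber indication (with a warning) and continues on the globular
track. Conflicts the framework leaves open — e.g. MG1 via dissolution
combined with a Tier-1 composition indication — are resolved as MG1 plus an
explicit warning, never silently. Records whose release qualifier is
positively "no" are `waived` with no main group.

## Case-study dataset

The packaged dataset (`data/case_studies.json`, same schema as user input)
encodes the 25 published case-study materials at the information level the
engine consumes. Where the published overview gives only qualitative entries
("high dissolution", "dispersible", "Range II"), the stored number is a
representative value on the stated side of the threshold, flagged as such in
`source_note` — the framework compares against thresholds, so any compliant
value reproduces the assignment. Carbonaceous materials, whose lung burden
could not be determined for technical reasons, carry a missing t50.
Acceptance-critical facts are encoded exactly: 25 entries; 22 keep their
non-animal group after Tier 3; exactly three (SiO₂.phosphate via
dispersibility, Pigment blue 15:1 via macrophage activity, graphite
nanoplatelets via undeterminable reactivity) are corrected MG4 → MG3 by
Range IV NOAECs; benchmark rows (MWCNT Range I, CeO₂ Range II, TiO₂ and
unfunctionalized silica Range III, BaSO₄ Range IV with accelerated
clearance, ZnO/CuO soluble) band as published.

## Synthetic cohorts

`generate_cohort` draws every criterion value uniformly from a range lying
strictly on the intended group's side of its threshold (e.g. MG3 reactivity
from [0, 0.08] vs the 0.10 cut-off; MG4-via-dispersibility AAN from
[1.0, 2.8] vs 3). This satisfies — trivially, with 100 % rather than the
required ≥ 95 % of mass — the requirement that distributions sit on the
group-consistent side, and makes intended-group recovery at zero missingness
exact by construction. MG4 records are triggered through a chosen channel
(reactivity, macrophage, epithelial, dispersibility or composition) with all
other channels held passive, enabling channel-isolation tests. Optional
missingness deletes only fields whose absence cannot change the assigned
group for the intended one (particle size, surface area, zeta potential,
agglomerate diameter where AAN is present, t50), so ground truth stays
well-defined; conservative misclassification is exercised separately by
forced deletions in the tests. The generator emulates threshold geometry
and missingness patterns only — not correlations between real measurements,
assay noise, or borderline values — so passing recovery tests demonstrates
engine correctness, not field performance on ambiguous materials.

Default problem sizes used in the test suite — a ~1.6·10⁴-combination
discretized truth-table grid checked against an independently hand-coded
flat oracle, 1000 records for deletion-monotonicity, and a 400-record
recovery cohort — keep the whole suite in the low seconds while exhausting
the discrete rule space.

## Numerical choices and degenerate inputs

Quantities are stored in the published units and never converted. Boundary
ties are fixed by the printed operators; nothing is broken randomly.
Discordant duplicate reactivity measurements (relative vs FRAS) resolve
conservatively to a trigger with a note. The deposited lung fraction is
reported at one decimal; a zero inhaled mass is rejected. Composition mass
fractions must sum to ≤ 100 % (remainder = unspecified matrix); an
epithelial result is either a LOEC or a "no effect up to X" bound, never
both, and a bound below the 10 µg/cm² threshold is treated as uninformative
(missing). Validation rejects unknown enum values instead of coercing them,
and empty CSV cells parse to missing — never zero.

## Known limitations

* The AAN is consumed as a measured input; how it is derived from raw size
  distributions is outside the engine.
* GHS classification of components is an input flag; there is no lookup by
  chemical identity.
* Qualitative case-study entries are representative encodings (see above);
  the dataset is not a source of raw measurement values.
* Tier 3 covers the inhalation route only; for other routes the engine
  still groups on Tiers 1–2 and marks Tier 3 as not covered.
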