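# nanogroup

A rule engine for the **DF4nanoGrouping** scheme — the ECETOC three-tier
decision-making framework that sorts nanomaterials into four hazard-relevant
main groups:

* **MG1** soluble nanomaterials (hazard dominated by released ions),
* **MG2** biopersistent high-aspect-ratio (fiber-like) nanomaterials,
* **MG3** passive nanomaterials (no material-specific effects),
* **MG4** active nanomaterials (merit in-depth investigation).

It is written for regulatory and industrial toxicologists who need grouping
decisions that are *auditable*: every classification carries a criterion-level
trace (input, threshold, printed comparison direction, outcome, note), all
cut-offs are configurable, and missing data propagate by explicit
precautionary rules rather than silent defaults.

## The framework in brief

Tier 1 consults intrinsic properties: water solubility (> 100 mg/L assigns
MG1 terminally), particle size and shape (aspect ratio > 3:1, diameter
< 3 µm — indication for MG2), and composition (≥ 0.1 % of a component with a
GHS classification for systemic effects — indication for MG4).

Tier 2 consults system-dependent properties and in vitro effects:
dissolution in biological fluids (> 100 mg/L → MG1 for globular materials;
< 100 mg/L confirms a biopersistent fiber → MG2), surface reactivity
(≥ 10 % of Mn₂O₃, i.e. ≥ 0.19 µU FRAS/m²·h → MG4; not determinable → MG4
precautionarily), dispersibility (AAN < 3 or agglomerate diameter < 100 nm
→ MG4 for non-fibers), and cellular effects — lung-epithelial cytotoxicity at
≤ 10 µg/cm² or activity in the NR8383 alveolar-macrophage assay (≥ 2 of the 4
parameters LDH, glucuronidase, TNF-α, ROS altered below the 6000 mm²/mL
non-overload surface-area dose) → MG4. Anything that triggers nothing is
provisionally MG3.

Tier 3 confirms or corrects the non-animal assignment with a rat short-term
inhalation study (STIS): NOAEC ≥ 10 mg/m³ (Range IV) finalizes MG3 whatever
Tier 2 indicated; Ranges I–III confirm MG4 with subgrouping by potency range,
reversibility of effects, and biodistribution pattern (beyond-MPS / MPS /
primary organ only, at the 1 %-of-dose cut). A pulmonary elimination
half-life t50 < 40 days confirms MG1. Use/release/route information acts as a
qualifier and can waive testing entirely.

## Worked example

```python
from nanogroup import classify, read_records, write_assignment

(record,) = read_records("my_material.json")   # or .csv
assignment = classify(record)
print(write_assignment(assignment, "md"))
```

For a dispersible (AAN 1.5), otherwise passive silica-like material with a
censored STIS NOAEC of ≥ 50 mg/m³ this prints:

```
# Grouping report: EX-1

* main group: **MG3**
* non-animal (Tier 1+2) group: MG4
* status: corrected
* tier reached: 3
* NOAEC range: IV
...
| 6 | 2 | dispersibility | 1.5 | 3 | lt | trigger |  |
...
| 10 | 3 | stis_noaec | 50 | 10 | ge | trigger | Range IV |
| 11 | 3 | biopersistence | 20 | 40 | lt | trigger | low biopersistence |
```

Read: the non-animal tiers flagged the material as MG4 "active" solely on its
high dispersibility; the in vivo screen found no adverse effects up to
50 mg/m³ (Range IV), so the overprediction is *corrected* to MG3 "passive",
for which the general occupational dust limit suffices.

The same engine is exposed on the command line:

```sh
nanogroup classify my_material.json --report md
nanogroup batch cohort.csv --report csv
nanogroup casestudies --verify     # packaged 25-material regression
nanogroup simulate --n 40 --seed 1 # synthetic cohort with known groups
```

`nanogroup casestudies --verify` re-classifies the packaged 25 case-study
materials and exits non-zero on any deviation from the expected tier-wise
outcomes (22 materials keep their non-animal group after Tier 3; exactly
three — SiO₂.phosphate, Pigment blue 15:1, graphite nanoplatelets — are
corrected from MG4 to MG3).

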