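"""Readers and writers for material records and group assignments.

Two input dialects are supported:

* JSON: ``{"records": [...]}`` or a bare list, each element matching the
  :class:`~nanogroup.records.MaterialRecord` schema
  (see :func:`material_record_schema`).
* flat CSV: UTF-8, comma separator, "." decimal, one row per material, with
  dotted column names mirroring the type tree (``system.aan``,
  ``invitro.macrophage.ldh``, ...).  Units are fixed by the schema; a header
  comment documents them.  An empty cell is a missing value -- never zero.

Assignments are written as JSON (round-trippable), CSV (batch summary rows)
or a markdown audit report listing every criterion evaluation in tier order.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
from pydantic import ValidationError

from .records import (
    GroupAssignment,
    MacrophageParam,
    MacrophageParamResult,
    MaterialRecord,
)

__all__ = [
    "RecordValidationError",
    "read_records",
    "records_to_json",
    "records_to_csv",
    "write_assignment",
    "write_assignments_csv",
    "read_assignment",
    "material_record_schema",
    "CSV_COLUMNS",
]

Source = Union[str, Path, _io.IOBase]


class RecordValidationError(ValueError):
    """A record failed schema validation; names the record, field and rule."""

    def __init__(self, material_id: str, detail: str):
        self.material_id = material_id
        super().__init__(f"record '{material_id}': {detail}")


_NO_EFFECT = "no_effect"

#: flat CSV column order (dotted names mirroring the record type tree)
CSV_COLUMNS = [
    "material_id",
    "name",
    "intrinsic.water_solubility",
    "intrinsic.primary_particle_size",
    "intrinsic.aspect_ratio",
    "intrinsic.length",
    "intrinsic.diameter",
    "intrinsic.shape_class",
    "intrinsic.composition",
    "intrinsic.surface_area",
    "intrinsic.surface_chemistry",
    "system.dissolution_biological",
    "system.medium_label",
    "system.surface_reactivity_relative",
    "system.surface_reactivity_fras",
    "system.aan",
    "system.agglomerate_diameter",
    "system.zeta_potential",
    "system.hydrophobicity_class",
    "invitro.epithelial_loec",
    "invitro.epithelial_no_effect_up_to",
    "invitro.macrophage.ldh",
    "invitro.macrophage.glucuronidase",
    "invitro.macrophage.tnf_alpha",
    "invitro.macrophage.ros",
    "invivo.stis_noaec",
    "invivo.noaec_censoring",
    "invivo.effects_regression_or_progression",
    "invivo.t50_days",
    "invivo.biodistribution.fraction_primary_organ",
    "invivo.biodistribution.fraction_mps",
    "invivo.biodistribution.fraction_beyond_mps",
    "qualifiers.release_possible",
    "qualifiers.exposure_routes",
    "qualifiers.use_stage_notes",
    "qualifiers.dustiness_class",
    "notes",
]

_UNITS_COMMENT = (
    "# units: solubility/dissolution mg/L; particle size and agglomerate "
    "diameter nm; fiber length/diameter um; surface area m2/g; FRAS uU/m2*h; "
    "zeta mV; epithelial LOEC ug/cm2; macrophage LOEC mm2/mL; NOAEC mg/m3; "
    "t50 days; biodistribution % of dose"
)

_NUMERIC_LEAVES = {
    "intrinsic.water_solubility",
    "intrinsic.primary_particle_size",
    "intrinsic.aspect_ratio",
    "intrinsic.length",
    "intrinsic.diameter",
    "intrinsic.surface_area",
    "system.dissolution_biological",
    "system.surface_reactivity_relative",
    "system.surface_reactivity_fras",
    "system.aan",
    "system.agglomerate_diameter",
    "system.zeta_potential",
    "invitro.epithelial_loec",
    "invitro.epithelial_no_effect_up_to",
    "invivo.stis_noaec",
    "invivo.t50_days",
    "invivo.biodistribution.fraction_primary_organ",
    "invivo.biodistribution.fraction_mps",
    "invivo.biodistribution.fraction_beyond_mps",
}


def material_record_schema() -> dict:
    """JSON schema for a single material record (2020-12 dialect, draft-07
    compatible structure)."""
    return MaterialRecord.model_json_schema()


# ---------------------------------------------------------------------------
# reading


def _read_text(source: Source) -> str:
    if isinstance(source, Path):
        return source.read_text(encoding="utf-8")
    if isinstance(source, str):
        p = Path(source)
        # treat short extension-bearing strings as paths, anything else as content
        if "\n" not in source and p.suffix.lower() in {".json", ".csv"}:
            return p.read_text(encoding="utf-8")
        return source
    return source.read()


def read_records(source: Source) -> list[MaterialRecord]:
    """Read and validate material records from a JSON or CSV document.

    ``source`` may be a path, raw document text, or an open file.  Every
    record is validated against the full type invariants; a violation raises
    :class:`RecordValidationError` naming the record, field and rule.
    Duplicate material ids are rejected.  Unknown CSV columns are preserved
    in the record's ``notes``.
    """
    text = _read_text(source).lstrip("﻿")
    stripped = text.lstrip()
    if stripped.startswith("{") or stripped.startswith("["):
        records = _records_from_json(text)
    else:
        records = _records_from_csv(text)
    seen: set[str] = set()
    for r in records:
        if r.material_id in seen:
            raise RecordValidationError(r.material_id, "duplicate material_id")
        seen.add(r.material_id)
    return records


def _validate(payload: dict) -> MaterialRecord:
    mid = str(payload.get("material_id", "<missing id>"))
    try:
        return MaterialRecord.model_validate(payload)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(x) for x in first["loc"])
        raise RecordValidationError(mid, f"field '{loc}': {first['msg']}") from exc


def _records_from_json(text: str) -> list[MaterialRecord]:
    doc = json.loads(text)
    if isinstance(doc, dict):
        doc = doc.get("records", doc)
    if isinstance(doc, dict):
        doc = [doc]
    return [_validate(item) for item in doc]


def _set_path(tree: dict, dotted: str, value) -> None:
    parts = dotted.split(".")
    node = tree
    for p in parts[:-1]:
        node = node.setdefault(p, {})
    node[parts[-1]] = value


def _records_from_csv(text: str) -> list[MaterialRecord]:
    df = pd.read_csv(
        _io.StringIO(text),
        comment="#",
        dtype=str,
        keep_default_na=False,
    )
    known = set(CSV_COLUMNS)
    unknown = [c for c in df.columns if c not in known]
    records = []
    for _, row in df.iterrows():
        tree: dict = {}
        macrophage: dict = {}
        for col in df.columns:
            raw = row[col].strip() if isinstance(row[col], str) else row[col]
            if col in unknown:
                continue
            if raw == "":
                continue  # missing, never 0
            if col.startswith("invitro.macrophage."):
                param = col.rsplit(".", 1)[1]
                if raw == _NO_EFFECT:
                    macrophage[param] = {"no_effect": True}
                else:
                    macrophage[param] = {"loec_surface_area": _num(col, raw)}
                continue
            if col == "intrinsic.composition":
                _set_path(tree, col, json.loads(raw))
                continue
            if col == "qualifiers.exposure_routes":
                routes = [r for r in raw.split(";") if r]
                _set_path(tree, col, routes)
                continue
            if col in _NUMERIC_LEAVES:
                _set_path(tree, col, _num(col, raw))
            else:
                _set_path(tree, col, raw)
        if macrophage:
            tree.setdefault("invitro", {})["macrophage_params"] = macrophage
        if unknown:
            extras = "; ".join(
                f"{c}={row[c]}" for c in unknown if str(row[c]).strip() != ""
            )
            if extras:
                prior = tree.get("notes", "")
                tree["notes"] = (prior + " | " if prior else "") + f"unparsed: {extras}"
        records.append(_validate(tree))
    return records


def _num(col: str, raw: str) -> float:
    try:
        return float(raw)
    except ValueError as exc:
        raise RecordValidationError(
            "<csv>", f"field '{col}': not a number: {raw!r}"
        ) from exc


# ---------------------------------------------------------------------------
# writing records


def records_to_json(records: Iterable[MaterialRecord]) -> str:
    payload = {"records": [_record_dump(r) for r in records]}
    return json.dumps(payload, indent=2, sort_keys=False)


def _record_dump(r: MaterialRecord) -> dict:
    d = r.model_dump(mode="json", exclude_none=True)
    q = d.get("qualifiers", {})
    if "exposure_routes" in q:
        q["exposure_routes"] = sorted(q["exposure_routes"])
    return d


def records_to_csv(records: Iterable[MaterialRecord]) -> str:
    rows = []
    for r in records:
        d = r.model_dump(mode="json", exclude_none=True)
        row: dict[str, str] = {}
        for col in CSV_COLUMNS:
            if col.startswith("invitro.macrophage."):
                param = col.rsplit(".", 1)[1]
                params = d.get("invitro", {}).get("macrophage_params") or {}
                res = params.get(param)
                if res is None:
                    row[col] = ""
                elif res.get("no_effect"):
                    row[col] = _NO_EFFECT
                else:
                    row[col] = _fmt(res["loec_surface_area"])
                continue
            node = d
            ok = True
            for part in col.split("."):
                if isinstance(node, dict) and part in node:
                    node = node[part]
                else:
                    ok = False
                    break
            if not ok or node is None:
                row[col] = ""
            elif col == "intrinsic.composition":
                row[col] = json.dumps(node) if node else ""
            elif col == "qualifiers.exposure_routes":
                row[col] = ";".join(sorted(node))
            else:
                row[col] = _fmt(node)
        rows.append(row)
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    return _UNITS_COMMENT + "\n" + df.to_csv(index=False)


def _fmt(v) -> str:
    if isinstance(v, bool):
        return str(v).lower()
    if isinstance(v, float) and v == int(v):
        return str(int(v))
    return str(v)


# ---------------------------------------------------------------------------
# assignments


def write_assignment(
    assignment: GroupAssignment,
    format: str = "json",
    config_echo: Optional[dict] = None,
) -> str:
    """Serialize one assignment; JSON round-trips via :func:`read_assignment`."""
    if format == "json":
        doc = {"assignment": assignment.model_dump(mode="json")}
        if config_echo is not None:
            doc["config"] = config_echo
        return json.dumps(doc, indent=2)
    if format == "csv":
        return write_assignments_csv([assignment])
    if format in ("md", "markdown"):
        return _markdown_report(assignment, config_echo)
    raise ValueError(f"unknown report format: {format!r}")


def read_assignment(text: str) -> GroupAssignment:
    doc = json.loads(text)
    payload = doc.get("assignment", doc) if isinstance(doc, dict) else doc
    return GroupAssignment.model_validate(payload)


_ASSIGNMENT_CSV_FIELDS = [
    "material_id",
    "main_group",
    "nonanimal_group",
    "status",
    "tier_reached",
    "noaec_range",
    "reversibility_subgroup",
    "biodistribution_subgroup",
    "dust_limit_annotation",
]


def write_assignments_csv(assignments: Iterable[GroupAssignment]) -> str:
    rows = []
    for a in assignments:
        d = a.model_dump(mode="json")
        rows.append({k: ("" if d[k] is None else d[k]) for k in _ASSIGNMENT_CSV_FIELDS})
    df = pd.DataFrame(rows, columns=_ASSIGNMENT_CSV_FIELDS)
    return df.to_csv(index=False)


def _markdown_report(a: GroupAssignment, config_echo: Optional[dict]) -> str:
    lines = [
        f"# Grouping report: {a.material_id}",
        "",
        f"* main group: **{a.main_group.value if a.main_group else 'none (waived)'}**",
        f"* non-animal (Tier 1+2) group: {a.nonanimal_group.value if a.nonanimal_group else '-'}",
        f"* status: {a.status.value}",
        f"* tier reached: {a.tier_reached}",
        f"* NOAEC range: {a.noaec_range.value}",
        f"* reversibility subgroup: {a.reversibility_subgroup.value}",
        f"* biodistribution subgroup: {a.biodistribution_subgroup.value}",
        f"* occupational dust limit: {a.dust_limit_annotation.value}",
        "",
        "## Criterion trace",
        "",
        "| # | tier | criterion | input | threshold | cmp | outcome | note |",
        "|---|------|-----------|-------|-----------|-----|---------|------|",
    ]
    for i, e in enumerate(a.trace, 1):
        thr = "" if e.threshold is None else f"{e.threshold:g}"
        cmp_ = e.comparison.value if e.comparison else ""
        val = e.input_value if e.input_value == "missing" else f"{e.input_value:g}"
        lines.append(
            f"| {i} | {e.tier} | {e.criterion_id.value} | {val} | {thr} "
            f"| {cmp_} | {e.outcome.value} | {e.note} |"
        )
    if a.warnings:
        lines += ["", "## Warnings", ""] + [f"* {w}" for w in a.warnings]
    if config_echo is not None:
        lines += [
            "",
            "## Effective configuration",
            "",
            "```json",
            json.dumps(config_echo, indent=2),
            "```",
        ]
    return "\n".join(lines) + "\n"
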