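"""Normalized reporting ontology: sections → subsections → fields.

The ontology is the 3-level hierarchy distilled from the CAP breast cancer
reporting protocols: 8 fixed sections, their subsections (one per checklist
heading), and discrete fields. Each field declares how its value behaves:

* ``categorical`` — the value must be one of ≥2 enumerated canonical options;
* ``numeric_template`` — the value is a display template with a single
  placeholder dash (e.g. ``"Exact distance: — mm"``) whose number travels in
  a separate integer "extra" channel;
* ``free_text`` — unconstrained narrative, no options.

The bundled default schema (:func:`default_schema_paths`) carries 8 sections,
86 subsections and 229 fields with representative CAP-breast field names.
"""
from __future__ import annotations

import hashlib
import json
import re
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path
from typing import Literal

import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from ._text import normalize

__all__ = [
    "SECTION_NAMES",
    "SCHEMA_COLUMNS",
    "FieldSpec",
    "OntologySchema",
    "SchemaError",
    "load_schema",
    "write_schema",
    "default_schema_paths",
    "get_options",
    "schema_counts",
]

#: The eight fixed top-level section names.
SECTION_NAMES: tuple[str, ...] = (
    "specimen",
    "tumor",
    "margins",
    "regional lymph nodes",
    "distant metastasis",
    "pTNM classification",
    "additional findings",
    "comments",
)

SCHEMA_COLUMNS: tuple[str, ...] = (
    "section", "subsection", "field_id", "label", "value_kind",
    "options", "numeric_template", "synonyms",
)

#: Placeholder used in numeric display templates (ASCII "-" accepted on read).
PLACEHOLDER = "—"


class SchemaError(ValueError):
    """Raised when schema files violate the ontology invariants."""


class FieldSpec(BaseModel):
    """One discrete reporting field of the ontology."""

    model_config = ConfigDict(frozen=True)

    field_id: str
    label: str
    section: str
    subsection: str
    value_kind: Literal["categorical", "numeric_template", "free_text"]
    allowed_options: tuple[str, ...] = ()
    numeric_template: str | None = None
    #: canonical option -> alternative surface forms
    synonyms: Mapping[str, tuple[str, ...]] = {}

    @model_validator(mode="after")
    def _check_invariants(self) -> "FieldSpec":
        if self.section not in SECTION_NAMES:
            raise SchemaError(
                f"field {self.field_id!r}: unknown section {self.section!r}; "
                f"expected one of {SECTION_NAMES}"
            )
        if self.value_kind == "categorical":
            if len(self.allowed_options) < 2:
                raise SchemaError(
                    f"categorical field {self.field_id!r} needs >=2 options"
                )
        elif self.value_kind == "numeric_template":
            if not self.numeric_template:
                raise SchemaError(
                    f"numeric_template field {self.field_id!r} lacks a template"
                )
            if self.numeric_template.count(PLACEHOLDER) != 1:
                raise SchemaError(
                    f"field {self.field_id!r}: template must contain exactly one "
                    f"placeholder {PLACEHOLDER!r}: {self.numeric_template!r}"
                )
            if not self.allowed_options:
                raise SchemaError(
                    f"numeric_template field {self.field_id!r} needs its template "
                    "among allowed_options"
                )
        else:  # free_text
            if self.allowed_options:
                raise SchemaError(
                    f"free_text field {self.field_id!r} must have no options"
                )
        if len(set(self.allowed_options)) != len(self.allowed_options):
            raise SchemaError(f"field {self.field_id!r}: duplicate options")
        for canon in self.synonyms:
            if canon not in self.allowed_options:
                raise SchemaError(
                    f"field {self.field_id!r}: synonym target {canon!r} is not "
                    "an allowed option"
                )
        return self


class OntologySchema(BaseModel):
    """Validated 3-level ontology with order-stable lookups."""

    model_config = ConfigDict(frozen=True)

    sections: tuple[str, ...]
    subsections: Mapping[str, tuple[str, ...]]
    fields: Mapping[str, FieldSpec]
    version: str = ""

    @model_validator(mode="after")
    def _check_hierarchy(self) -> "OntologySchema":
        for sec in self.sections:
            if sec not in SECTION_NAMES:
                raise SchemaError(f"unknown section name {sec!r}")
        known = {
            (sec, sub) for sec, subs in self.subsections.items() for sub in subs
        }
        used = set()
        for spec in self.fields.values():
            pair = (spec.section, spec.subsection)
            if pair not in known:
                raise SchemaError(
                    f"field {spec.field_id!r} references unknown subsection "
                    f"{pair!r}"
                )
            used.add(pair)
        orphans = known - used
        if orphans:
            raise SchemaError(f"orphan subsections with no fields: {sorted(orphans)}")
        return self

    # -- queries ------------------------------------------------------------

    def field(self, field_id: str) -> FieldSpec:
        try:
            return self.fields[field_id]
        except KeyError:
            raise KeyError(f"unknown field_id {field_id!r}") from None

    def get_options(self, field_id: str) -> list[str]:
        """Canonical allowed options, verbatim and order-stable."""
        return list(self.field(field_id).allowed_options)

    def counts(self) -> tuple[int, int, int]:
        """(n_sections, n_subsections, n_fields)."""
        n_subs = sum(len(subs) for subs in self.subsections.values())
        return (len(self.sections), n_subs, len(self.fields))

    def fields_of_subsection(self, section: str, subsection: str) -> list[FieldSpec]:
        return [
            s for s in self.fields.values()
            if s.section == section and s.subsection == subsection
        ]

    def iter_subsections(self) -> Iterable[tuple[str, str]]:
        for sec in self.sections:
            for sub in self.subsections.get(sec, ()):
                yield sec, sub

    def to_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), ensure_ascii=False, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "OntologySchema":
        return cls.model_validate(json.loads(text))


# -- CSV I/O ----------------------------------------------------------------


def _parse_synonyms(cell: str) -> dict[str, tuple[str, ...]]:
    out: dict[str, tuple[str, ...]] = {}
    for entry in filter(None, (cell or "").split("|")):
        if "=>" not in entry:
            raise SchemaError(f"malformed synonyms cell entry {entry!r}")
        canon, alts = entry.split("=>", 1)
        out[canon] = tuple(a for a in alts.split(";") if a)
    return out


def _format_synonyms(syn: Mapping[str, Sequence[str]]) -> str:
    return "|".join(f"{c}=>{';'.join(a)}" for c, a in syn.items())


def load_schema(schema_paths: Sequence[str | Path]) -> OntologySchema:
    """Load and validate an ontology from one or more CSV files.

    Files are read in the order given; rows keep file order, so loading is
    order-stable. Raises :class:`FileNotFoundError` for a missing path and
    :class:`SchemaError` for any invariant violation (duplicate ids, unknown
    sections, malformed rows, empty schema).
    """
    frames = []
    for p in schema_paths:
        path = Path(p)
        if not path.exists():
            raise FileNotFoundError(f"schema file not found: {path}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
        missing = set(SCHEMA_COLUMNS) - set(df.columns)
        if missing:
            raise SchemaError(f"{path}: missing columns {sorted(missing)}")
        df["__source"] = str(path)
        frames.append(df)
    if not frames:
        raise SchemaError("no schema files given")
    table = pd.concat(frames, ignore_index=True)
    if table.empty:
        raise SchemaError("schema contains no fields")

    dupes = table["field_id"][table["field_id"].duplicated()].unique().tolist()
    if dupes:
        raise SchemaError(f"duplicate field_id values: {dupes}")

    sections: list[str] = []
    subsections: dict[str, list[str]] = {}
    fields: dict[str, FieldSpec] = {}
    for idx, row in table.iterrows():
        try:
            template = row["numeric_template"] or None
            if (template and row["value_kind"] == "numeric_template"
                    and PLACEHOLDER not in template):
                # ASCII "-" accepted on read as the placeholder (standalone token)
                template = re.sub(r"(?<!\w)-(?!\w)", PLACEHOLDER, template, count=1)
            options = tuple(o for o in row["options"].split("|") if o)
            if row["value_kind"] == "numeric_template" and template:
                options = tuple(
                    template if normalize(o) == normalize(template) else o
                    for o in options
                ) or (template,)
            spec = FieldSpec(
                field_id=row["field_id"],
                label=row["label"],
                section=row["section"],
                subsection=row["subsection"],
                value_kind=row["value_kind"],
                allowed_options=options,
                numeric_template=template,
                synonyms=_parse_synonyms(row["synonyms"]),
            )
        except (SchemaError, ValueError) as exc:
            raise SchemaError(
                f"{row['__source']} row {int(idx) + 2}: {exc}"
            ) from None
        if spec.section not in sections:
            sections.append(spec.section)
        subs = subsections.setdefault(spec.section, [])
        if spec.subsection not in subs:
            subs.append(spec.subsection)
        fields[spec.field_id] = spec

    version = _content_hash(fields)
    return OntologySchema(
        sections=tuple(sections),
        subsections={k: tuple(v) for k, v in subsections.items()},
        fields=fields,
        version=version,
    )


def _content_hash(fields: Mapping[str, FieldSpec]) -> str:
    payload = json.dumps(
        [f.model_dump(mode="json") for f in fields.values()],
        ensure_ascii=False, sort_keys=True,
    )
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:12]


def write_schema(schema: OntologySchema, path: str | Path) -> Path:
    """Write the schema back to a single CSV (round-trips with load_schema)."""
    rows = []
    for spec in schema.fields.values():
        rows.append({
            "section": spec.section,
            "subsection": spec.subsection,
            "field_id": spec.field_id,
            "label": spec.label,
            "value_kind": spec.value_kind,
            "options": "|".join(spec.allowed_options),
            "numeric_template": spec.numeric_template or "",
            "synonyms": _format_synonyms(spec.synonyms),
        })
    path = Path(path)
    pd.DataFrame(rows, columns=list(SCHEMA_COLUMNS)).to_csv(
        path, index=False, encoding="utf-8"
    )
    return path


def default_schema_paths() -> list[Path]:
    """Paths of the bundled default schema CSVs (one file per section)."""
    from importlib.resources import files

    root = Path(str(files("synoptex") / "data" / "schema"))
    return sorted(root.glob("*.csv"))


def load_default_schema() -> OntologySchema:
    return load_schema(default_schema_paths())


# module-level conveniences mirroring the operation names


def get_options(schema: OntologySchema, field_id: str) -> list[str]:
    return schema.get_options(field_id)


def schema_counts(schema: OntologySchema) -> tuple[int, int, int]:
    return schema.counts()
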