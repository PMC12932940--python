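"""End-to-end workflow: segment, prompt, complete, parse — per report and field.

The run proceeds from two independent initialization products (the loaded
ontology and the report's segments) through sequential per-field stages:
prompt construction, backend completion, and response parsing. Every
attempted field yields exactly one :class:`ExtractionRecord`; fields whose
subsection heading never matched produce an abstaining record flagged
``no_segment``. A backend or parsing failure on one field is encoded in
that record's status and never interrupts the rest of the run, and output
order is deterministic (report order, then schema field order), so a full
seeded run is byte-reproducible at the JSONL level.

Each stage is also callable in isolation through :func:`call_agent`, which
gives stage-level testing the same semantics as the full run.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

from ._text import ABSTAIN
from .backends import Backend, ExtractionRecord, parse_response
from .prompts import build_prompt
from .schema import OntologySchema
from .segmentation import Segment, SectionPattern, segment_report

__all__ = ["RunManifest", "run_report", "run_corpus", "call_agent",
           "write_records_jsonl", "read_records_jsonl", "OrchestratorError"]


class OrchestratorError(RuntimeError):
    pass


@dataclass(frozen=True)
class RunManifest:
    """Re-runnable configuration and record tally of one extraction run."""

    run_id: str
    schema_version: str
    backend_id: str
    template_id: str
    seed: int
    n_reports: int
    n_records: int
    per_report_counts: Mapping[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), ensure_ascii=False,
                          sort_keys=True, indent=1)


def _record_for_field(
    report_id: str,
    field_id: str,
    schema: OntologySchema,
    segments: Sequence[Segment],
    backend: Backend,
) -> ExtractionRecord:
    spec = schema.field(field_id)
    mine = [s for s in segments if field_id in s.field_ids]
    if not mine:
        return ExtractionRecord(
            report_id=report_id, field_id=field_id, value=ABSTAIN,
            backend_id=getattr(backend, "backend_id", ""), status="ok",
            no_segment=True, note="no segment matched",
        )
    last: ExtractionRecord | None = None
    for seg in mine:  # document order; first non-abstaining result wins
        try:
            bundle = build_prompt(seg, spec)
            raw = backend.complete(bundle, seg.text)
            rec = parse_response(
                raw, spec, report_id=report_id,
                backend_id=getattr(backend, "backend_id", ""),
            )
        except Exception as exc:  # per-field isolation
            rec = ExtractionRecord(
                report_id=report_id, field_id=field_id, value=ABSTAIN,
                backend_id=getattr(backend, "backend_id", ""),
                status="invalid", note=f"stage failure: {exc}",
            )
        last = rec
        if rec.value != ABSTAIN:
            return rec
    assert last is not None
    return last


def run_report(
    report: Mapping[str, str],
    schema: OntologySchema,
    backend: Backend,
    *,
    field_ids: Sequence[str] | None = None,
    patterns: Sequence[SectionPattern] | None = None,
) -> list[ExtractionRecord]:
    """Extract every requested field from one report document.

    ``report`` is a mapping with ``report_id`` and ``text``. ``field_ids``
    defaults to every field in schema order. Returns one record per field.
    """
    report_id = report.get("report_id", "")
    text = report.get("text", "")
    segments = segment_report(text, schema, patterns)
    wanted = list(field_ids) if field_ids is not None else list(schema.fields)
    unknown = [f for f in wanted if f not in schema.fields]
    if unknown:
        raise OrchestratorError(f"unknown field_ids requested: {unknown}")
    return [
        _record_for_field(report_id, fid, schema, segments, backend)
        for fid in wanted
    ]


def run_corpus(
    reports: Iterable[Mapping[str, str]],
    schema: OntologySchema,
    backend: Backend,
    *,
    fields_map: Mapping[str, Sequence[str]] | None = None,
    seed: int = 0,
    run_id: str = "run",
    template_id: str = "default-v1",
) -> tuple[list[ExtractionRecord], RunManifest]:
    """Run extraction over many reports; returns (records, manifest).

    ``fields_map`` optionally restricts the attempted fields per report_id
    (used for field-targeted synthetic cases); otherwise every schema field
    is attempted for every report.
    """
    records: list[ExtractionRecord] = []
    counts: dict[str, int] = {}
    n_reports = 0
    for report in reports:
        n_reports += 1
        rid = report.get("report_id", "")
        wanted = fields_map.get(rid) if fields_map else None
        recs = run_report(report, schema, backend, field_ids=wanted)
        counts[rid] = len(recs)
        records.extend(recs)
    manifest = RunManifest(
        run_id=run_id,
        schema_version=schema.version,
        backend_id=getattr(backend, "backend_id", ""),
        template_id=template_id,
        seed=seed,
        n_reports=n_reports,
        n_records=len(records),
        per_report_counts=counts,
    )
    return records, manifest


# -- stage-level agent calls -------------------------------------------------


def _task_segment(payload: Mapping[str, Any]) -> list[Segment]:
    return segment_report(payload["text"], payload["schema"],
                          payload.get("patterns"))


def _task_build_prompt(payload: Mapping[str, Any]):
    return build_prompt(payload["segment"], payload["spec"],
                        payload.get("template_id"))


def _task_complete(payload: Mapping[str, Any]) -> str:
    backend: Backend = payload["backend"]
    return backend.complete(payload["bundle"], payload.get("segment_text"))


def _task_parse(payload: Mapping[str, Any]) -> ExtractionRecord:
    return parse_response(
        payload["raw"], payload["spec"],
        report_id=payload.get("report_id", ""),
        backend_id=payload.get("backend_id", ""),
    )


_TASKS = {
    "segment": _task_segment,
    "build_prompt": _task_build_prompt,
    "complete": _task_complete,
    "parse": _task_parse,
}


def call_agent(task_name: str, payload: Mapping[str, Any]) -> Any:
    """Run exactly one pipeline stage in isolation (same semantics as the run)."""
    try:
        task = _TASKS[task_name]
    except KeyError:
        raise OrchestratorError(
            f"unknown task {task_name!r}; available: {sorted(_TASKS)}"
        ) from None
    return task(payload)


# -- JSONL I/O ---------------------------------------------------------------


def write_records_jsonl(records: Iterable[ExtractionRecord],
                        path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_dict(), ensure_ascii=False,
                                sort_keys=True) + "\n")
    return path


def read_records_jsonl(path: str | Path) -> list[ExtractionRecord]:
    out = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(ExtractionRecord.from_dict(json.loads(line)))
    return out
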