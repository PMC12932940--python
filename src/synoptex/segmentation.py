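"""Locate the free-text block behind each schema heading.

Synoptic reports are label-prefixed checklists ("Tumor Site: ...",
"Additional Findings: ..."). Segmentation finds every heading occurrence by
regular expression and cuts the report at heading boundaries: each segment
runs from its own match to the start of the next matched heading (any
pattern) or end of text, so segments never overlap and jointly tile the
labeled region. Spans are 0-based half-open offsets into the source report;
the stored snippet is the span substring with surrounding whitespace
trimmed. Noise tokens such as "nan" are deliberately retained — filtering
is the extractor's concern.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .schema import OntologySchema

__all__ = ["Segment", "SectionPattern", "build_patterns", "segment_report",
           "SegmentationError"]


class SegmentationError(ValueError):
    """Configuration or input errors during segmentation."""


@dataclass(frozen=True)
class SectionPattern:
    """One heading pattern and the schema fields answered under it."""

    pattern_id: str
    regex: re.Pattern
    field_ids: tuple[str, ...]


@dataclass(frozen=True)
class Segment:
    """A located free-text block tied to schema fields.

    ``span`` is half-open into the source report; ``text`` equals the span
    substring after trimming leading/trailing whitespace.
    """

    pattern_id: str
    field_ids: tuple[str, ...]
    text: str
    span: tuple[int, int]

    @property
    def field_id(self) -> str:
        """Primary (first) field answered in this segment."""
        return self.field_ids[0]

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]


def _slug(label: str) -> str:
    return re.sub(r"\W+", "_", label.lower()).strip("_")


def _label_regex(label: str) -> re.Pattern:
    # heading anchored at line start, case-insensitive, colon-terminated
    return re.compile(
        rf"^[ \t]*{re.escape(label)}[ \t]*:",
        re.IGNORECASE | re.MULTILINE,
    )


def build_patterns(
    schema: OntologySchema,
    granularity: str = "subsection",
    overrides: Mapping[str, str] | None = None,
) -> list[SectionPattern]:
    """Derive the heading-pattern table from the schema.

    One pattern per subsection label (default) or per section name;
    ``overrides`` maps a pattern_id to a replacement regex source for
    irregular headings. Every pattern's fields must exist in the schema.
    """
    overrides = dict(overrides or {})
    patterns: list[SectionPattern] = []
    if granularity == "subsection":
        for sec, sub in schema.iter_subsections():
            fids = tuple(s.field_id for s in schema.fields_of_subsection(sec, sub))
            pid = _slug(sub)
            source = overrides.pop(pid, None)
            regex = re.compile(source, re.IGNORECASE | re.MULTILINE) \
                if source else _label_regex(sub)
            patterns.append(SectionPattern(pid, regex, fids))
    elif granularity == "section":
        for sec in schema.sections:
            fids = tuple(
                s.field_id for s in schema.fields.values() if s.section == sec
            )
            pid = _slug(sec)
            source = overrides.pop(pid, None)
            regex = re.compile(source, re.IGNORECASE | re.MULTILINE) \
                if source else _label_regex(sec)
            patterns.append(SectionPattern(pid, regex, fids))
    else:
        raise SegmentationError(f"unknown granularity {granularity!r}")
    if overrides:
        raise SegmentationError(
            f"override(s) reference unknown pattern ids: {sorted(overrides)}"
        )
    return patterns


def _check_patterns(patterns: Iterable[SectionPattern], schema: OntologySchema) -> None:
    for pat in patterns:
        unknown = [f for f in pat.field_ids if f not in schema.fields]
        if unknown:
            raise SegmentationError(
                f"pattern {pat.pattern_id!r} references unknown fields {unknown}"
            )


def segment_report(
    report_text: str,
    schema: OntologySchema,
    patterns: Sequence[SectionPattern] | None = None,
) -> list[Segment]:
    """Cut a report into heading-anchored segments, ordered by offset.

    Returns an empty list when no heading matches. Raises
    :class:`SegmentationError` on an empty document or a pattern that
    references a field absent from the schema.
    """
    if not report_text or not report_text.strip():
        raise SegmentationError("empty document")
    if patterns is None:
        patterns = build_patterns(schema)
    _check_patterns(patterns, schema)

    # all matches of all patterns; first pattern in table order wins a tie
    hits: dict[int, SectionPattern] = {}
    for pat in patterns:
        for m in pat.regex.finditer(report_text):
            hits.setdefault(m.start(), pat)

    starts = sorted(hits)
    segments: list[Segment] = []
    for i, start in enumerate(starts):
        end = starts[i + 1] if i + 1 < len(starts) else len(report_text)
        raw = report_text[start:end]
        segments.append(Segment(
            pattern_id=hits[start].pattern_id,
            field_ids=hits[start].field_ids,
            text=raw.strip(),
            span=(start, end),
        ))
    return segments
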