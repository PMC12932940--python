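"""Deterministic prompt rendering for one (segment, field) pair.

Templates are versioned text assets shipped with the package (not code) and
addressed by ``template_id``; rendering is a pure function of the segment,
the field spec and the template, with no timestamps or randomness, so two
identical calls produce byte-identical instruction text. The rendered prompt
embeds the snippet verbatim exactly once and every allowed option exactly
once, and states the machine-readable output contract: a single JSON object
with keys ``field``, ``value`` and (optionally) integer ``extra``.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from string import Template
from typing import Any, Mapping

from .schema import FieldSpec
from .segmentation import Segment

__all__ = ["PromptBundle", "build_prompt", "PromptError", "DEFAULT_TEMPLATE",
           "FREETEXT_TEMPLATE", "MAX_PROMPT_CHARS"]

DEFAULT_TEMPLATE = "default-v1"
FREETEXT_TEMPLATE = "freetext-v1"

#: Hard ceiling on rendered prompt length; exceeding it is an error, never a
#: silent truncation.
MAX_PROMPT_CHARS = 20_000


class PromptError(ValueError):
    """Contract violations while building a prompt."""


@dataclass(frozen=True)
class PromptBundle:
    """A rendered instruction plus its expected response contract."""

    field_id: str
    rendered_text: str
    options_offered: tuple[str, ...]
    output_contract: Mapping[str, Any]
    template_id: str
    #: snippet carried alongside for offline backends
    segment_text: str = ""


@lru_cache(maxsize=None)
def _load_template(template_id: str) -> Template:
    from importlib.resources import files

    path = Path(str(files("synoptex") / "data" / "templates" / f"{template_id}.txt"))
    if not path.exists():
        raise PromptError(f"unknown template {template_id!r}")
    return Template(path.read_text(encoding="utf-8"))


def _contract(spec: FieldSpec) -> dict[str, Any]:
    value_schema: dict[str, Any] = {"type": ["string", "null"]}
    if spec.allowed_options:
        value_schema = {"enum": list(spec.allowed_options) + [None]}
    contract: dict[str, Any] = {
        "type": "object",
        "required": ["field", "value"],
        "properties": {
            "field": {"const": spec.field_id},
            "value": value_schema,
        },
        "additionalProperties": False,
    }
    if spec.value_kind == "numeric_template":
        contract["properties"]["extra"] = {"type": "integer"}
        contract["additionalProperties"] = True
    return contract


def build_prompt(
    segment: Segment,
    spec: FieldSpec,
    template_id: str | None = None,
    max_chars: int = MAX_PROMPT_CHARS,
) -> PromptBundle:
    """Render the instruction text for one field over one segment.

    Raises :class:`PromptError` when the segment is not mapped to the field,
    when a free-text field meets an option-requiring template, or when the
    rendered prompt would exceed ``max_chars``.
    """
    if spec.field_id not in segment.field_ids:
        raise PromptError(
            f"segment (pattern {segment.pattern_id!r}) is not mapped to field "
            f"{spec.field_id!r}"
        )
    if template_id is None:
        template_id = (
            FREETEXT_TEMPLATE if spec.value_kind == "free_text" else DEFAULT_TEMPLATE
        )
    template = _load_template(template_id)
    needs_options = "${options_block}" in template.template \
        or "$options_block" in template.template
    if spec.value_kind == "free_text" and needs_options:
        raise PromptError(
            f"template {template_id!r} enumerates options but field "
            f"{spec.field_id!r} is free_text"
        )

    options = tuple(spec.allowed_options)
    options_block = "\n".join(
        f"  {i}. {opt}" for i, opt in enumerate(options, 1)
    ) or "  (none)"
    rendered = template.substitute(
        field_id=spec.field_id,
        field_label=spec.label,
        snippet=segment.text,
        options_block=options_block,
    )
    if len(rendered) > max_chars:
        raise PromptError(
            f"rendered prompt for {spec.field_id!r} is {len(rendered)} chars "
            f"(ceiling {max_chars})"
        )
    return PromptBundle(
        field_id=spec.field_id,
        rendered_text=rendered,
        options_offered=options,
        output_contract=_contract(spec),
        template_id=template_id,
        segment_text=segment.text,
    )
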