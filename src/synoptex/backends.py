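"""Pluggable extraction backends and response parsing.

A backend maps a rendered prompt to a raw string; :func:`parse_response`
turns any raw string into a schema-validated :class:`ExtractionRecord`.
The reference backend is a deterministic rule-based matcher ("oracle") that
selects the longest allowed option (or synonym) whose normalized form occurs
in the segment text, captures "Found number N" tails into the integer extra
channel, and abstains otherwise. "oracle-noisy" adds seeded error injection
(swap / drop / spurious) so an imperfect model with known expected
sensitivity and specificity can be emulated offline. Live LLM providers are
optional adapters behind the same contract and are never needed for
installation or testing.
"""
from __future__ import annotations

import dataclasses
import json
import random
import re
from dataclasses import dataclass
from typing import Any, Callable, Mapping, Protocol

from ._text import ABSTAIN, normalize, template_match_form
from .prompts import PromptBundle
from .schema import FieldSpec

__all__ = [
    "ABSTAIN",
    "ExtractionRecord",
    "Backend",
    "BackendError",
    "OracleBackend",
    "NoisyOracleBackend",
    "register_backend",
    "select_backend",
    "available_backends",
    "oracle_match",
    "oracle_complete",
    "parse_response",
    "serialize_record",
    "inject_errors",
]

_FOUND_NUMBER = re.compile(r"found number\s+(-?\d+)")


class BackendError(RuntimeError):
    """Backend registry and adapter errors."""


@dataclass(frozen=True)
class ExtractionRecord:
    """One backend prediction for one field of one report."""

    report_id: str
    field_id: str
    value: str  # canonical option, free text, or ABSTAIN
    extra: int | None = None
    raw_response: str = ""
    backend_id: str = ""
    status: str = "ok"  # ok | repaired | invalid
    no_segment: bool = False
    note: str = ""

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ExtractionRecord":
        return cls(**d)


class Backend(Protocol):
    backend_id: str

    def complete(self, bundle: PromptBundle, segment_text: str | None = None) -> str:
        """Return a raw response string for the prompt (total, never raises)."""
        ...


# -- deterministic matcher ---------------------------------------------------


def _match_forms(spec: FieldSpec) -> list[tuple[str, str]]:
    """(matchable form, canonical option) pairs, schema order, options first."""
    forms: list[tuple[str, str]] = []
    for opt in spec.allowed_options:
        form = template_match_form(opt) if spec.value_kind == "numeric_template" \
            else normalize(opt)
        forms.append((form, opt))
    for canon, alts in spec.synonyms.items():
        forms.extend((normalize(a), canon) for a in alts)
    return forms


def oracle_match(spec: FieldSpec, segment_text: str) -> tuple[str | None, int | None]:
    """Longest-normalized-substring match of the field's options in the text.

    Ties on length break toward schema order. Returns (canonical value or
    None, extra or None); the extra channel is only populated for
    numeric-template fields.
    """
    hay = normalize(segment_text)
    best: tuple[str, str] | None = None
    for form, canon in _match_forms(spec):
        if form and form in hay and (best is None or len(form) > len(best[0])):
            best = (form, canon)
    extra = None
    if spec.value_kind == "numeric_template":
        m = _FOUND_NUMBER.search(hay)
        if m:
            extra = int(m.group(1))
    return (best[1] if best else None, extra)


def oracle_complete(bundle: PromptBundle, segment_text: str,
                    spec: FieldSpec) -> str:
    """Raw JSON response of the deterministic matcher (abstention = null)."""
    value, extra = oracle_match(spec, segment_text)
    payload: dict[str, Any] = {"field": bundle.field_id, "value": value}
    if extra is not None:
        payload["extra"] = extra
    return json.dumps(payload, ensure_ascii=False)


class OracleBackend:
    """Deterministic rule-based stand-in for an LLM provider."""

    backend_id = "oracle"

    def __init__(self, schema=None, **_config: Any) -> None:
        self._schema = schema

    def _spec_for(self, bundle: PromptBundle) -> FieldSpec:
        if self._schema is not None:
            return self._schema.field(bundle.field_id)
        # reconstruct a minimal spec from the bundle's offered options
        kind = "categorical" if len(bundle.options_offered) >= 2 else "free_text"
        template = None
        if len(bundle.options_offered) == 1:
            kind, template = "numeric_template", bundle.options_offered[0]
        return FieldSpec(
            field_id=bundle.field_id, label=bundle.field_id,
            section="specimen", subsection="_", value_kind=kind,
            allowed_options=bundle.options_offered, numeric_template=template,
        )

    def complete(self, bundle: PromptBundle, segment_text: str | None = None) -> str:
        text = bundle.segment_text if segment_text is None else segment_text
        return oracle_complete(bundle, text, self._spec_for(bundle))


# -- error injection ---------------------------------------------------------


def _validate_rates(rates: tuple[float, float, float]) -> tuple[float, float, float]:
    eps_swap, eps_drop, eps_spurious = (float(r) for r in rates)
    for r in (eps_swap, eps_drop, eps_spurious):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"error rates must lie in [0, 1], got {rates}")
    if eps_swap + eps_drop > 1.0:
        raise ValueError(f"eps_swap + eps_drop must be <= 1, got {rates}")
    return eps_swap, eps_drop, eps_spurious


def _corrupt_value(value: str, options: tuple[str, ...],
                   rates: tuple[float, float, float],
                   rng: random.Random) -> tuple[str, str]:
    """Apply swap/drop/spurious to one value; returns (new value, note)."""
    eps_swap, eps_drop, eps_spurious = rates
    if value != ABSTAIN:
        u = rng.random()
        if u < eps_swap:
            wrong = [o for o in options if o != value]
            if wrong:
                return rng.choice(wrong), "injected:swap"
        elif u < eps_swap + eps_drop:
            return ABSTAIN, "injected:drop"
    else:
        if rng.random() < eps_spurious and options:
            return rng.choice(list(options)), "injected:spurious"
    return value, ""


def inject_errors(
    record: ExtractionRecord,
    spec: FieldSpec,
    rates: tuple[float, float, float],
    rng_seed: int,
) -> ExtractionRecord:
    """Seeded corruption of one record: swap / drop / spurious.

    With probability ``eps_swap`` a non-abstaining value is replaced by a
    uniformly chosen different option; with ``eps_drop`` it is forced to
    abstain; an abstention becomes a uniformly chosen option with probability
    ``eps_spurious``. Rates (0, 0, 0) return the record unchanged.
    """
    rates = _validate_rates(rates)
    rng = random.Random(rng_seed)
    value, note = _corrupt_value(record.value, tuple(spec.allowed_options),
                                 rates, rng)
    if value == record.value:
        return record
    extra = record.extra if value != ABSTAIN else None
    return dataclasses.replace(record, value=value, extra=extra, note=note)


class NoisyOracleBackend(OracleBackend):
    """Oracle matcher with seeded error injection at configured rates."""

    backend_id = "oracle-noisy"

    def __init__(self, schema=None, seed: int = 0,
                 rates: tuple[float, float, float] = (0.0, 0.0, 0.0),
                 **config: Any) -> None:
        super().__init__(schema=schema, **config)
        self._rates = _validate_rates(rates)
        self._seed = int(seed)
        self._calls = 0

    def complete(self, bundle: PromptBundle, segment_text: str | None = None) -> str:
        raw = super().complete(bundle, segment_text)
        payload = json.loads(raw)
        value = payload.get("value")
        self._calls += 1
        call_seed = (self._seed * 1_000_003 + self._calls) % (2 ** 31)
        rng = random.Random(call_seed)
        new_value, _ = _corrupt_value(
            ABSTAIN if value is None else value,
            bundle.options_offered, self._rates, rng,
        )
        payload["value"] = None if new_value == ABSTAIN else new_value
        if payload["value"] is None:
            payload.pop("extra", None)
        return json.dumps(payload, ensure_ascii=False)


class OllamaBackend:
    """Adapter stub for a local Ollama server (optional; requires network).

    Kept out of the test matrix: construction succeeds so the registry can
    list it, but completion requires a reachable server.
    """

    backend_id = "ollama"

    def __init__(self, model: str = "", host: str = "http://localhost:11434",
                 **_config: Any) -> None:
        self._model = model
        self._host = host.rstrip("/")

    def complete(self, bundle: PromptBundle, segment_text: str | None = None) -> str:
        import urllib.request

        body = json.dumps({
            "model": self._model, "prompt": bundle.rendered_text, "stream": False,
        }).encode("utf-8")
        req = urllib.request.Request(
            f"{self._host}/api/generate", data=body,
            headers={"Content-Type": "application/json"},
        )
        try:
            with urllib.request.urlopen(req, timeout=120) as resp:
                return json.loads(resp.read())["response"]
        except Exception as exc:  # total: failures become a parseable non-answer
            return f'backend-error: {exc}'


_REGISTRY: dict[str, Callable[..., Backend]] = {}


def register_backend(name: str, factory: Callable[..., Backend]) -> None:
    _REGISTRY[name] = factory


register_backend("oracle", OracleBackend)
register_backend("oracle-noisy", NoisyOracleBackend)
register_backend("ollama", OllamaBackend)


def available_backends() -> list[str]:
    return sorted(_REGISTRY)


def select_backend(name: str, config: Mapping[str, Any] | None = None) -> Backend:
    """Instantiate a registered backend by name with keyword configuration."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise BackendError(
            f"unknown backend {name!r}; available: {available_backends()}"
        ) from None
    return factory(**dict(config or {}))


# -- response parsing --------------------------------------------------------

_FENCE = re.compile(r"```(?:json)?|```", re.IGNORECASE)


def _repair_json(raw: str) -> dict[str, Any] | None:
    """One bounded repair pass: strip fences/prose, take first JSON object."""
    cleaned = _FENCE.sub("", raw)
    decoder = json.JSONDecoder()
    for pos in (m.start() for m in re.finditer(r"\{", cleaned)):
        try:
            obj, _ = decoder.raw_decode(cleaned, pos)
        except json.JSONDecodeError:
            continue
        if isinstance(obj, dict):
            return obj
    return None


def _canonical_value(value: Any, spec: FieldSpec) -> str | None:
    """Map a raw value onto the schema; None means unvalidatable."""
    if value is None:
        return ABSTAIN
    text = str(value)
    if normalize(text) in ("", normalize(ABSTAIN), "none", "null"):
        return ABSTAIN
    if spec.value_kind == "free_text":
        return text
    wanted = normalize(text) if spec.value_kind == "categorical" \
        else template_match_form(text)
    for form, canon in _match_forms(spec):
        if wanted == form:
            return canon
    return None


def parse_response(
    raw: str,
    spec: FieldSpec,
    *,
    report_id: str = "",
    backend_id: str = "",
) -> ExtractionRecord:
    """Parse any raw backend string into a validated record (never raises).

    Strict JSON first; on failure one repair pass (status ``repaired``);
    values that cannot be normalized onto the field's options yield status
    ``invalid`` with the raw response retained. Evaluation treats invalid
    records as non-extractions.
    """
    status = "ok"
    try:
        payload = json.loads(raw)
        if not isinstance(payload, dict):
            raise json.JSONDecodeError("not an object", raw, 0)
    except (json.JSONDecodeError, TypeError):
        payload = _repair_json(raw if isinstance(raw, str) else "")
        status = "repaired" if payload is not None else "invalid"

    if payload is None:
        return ExtractionRecord(
            report_id=report_id, field_id=spec.field_id, value=ABSTAIN,
            raw_response=raw, backend_id=backend_id, status="invalid",
            note="unparseable response",
        )

    value = _canonical_value(payload.get("value"), spec)
    note = ""
    if value is None:
        status, value = "invalid", ABSTAIN
        note = "value not in allowed options"

    extra: int | None = None
    if spec.value_kind == "numeric_template" and value != ABSTAIN:
        raw_extra = payload.get("extra")
        try:
            extra = int(raw_extra) if raw_extra is not None else None
        except (TypeError, ValueError):
            extra = None

    return ExtractionRecord(
        report_id=report_id, field_id=spec.field_id, value=value, extra=extra,
        raw_response=raw, backend_id=backend_id, status=status, note=note,
    )


def serialize_record(record: ExtractionRecord) -> str:
    """Canonical raw JSON for a record (inverse of :func:`parse_response`)."""
    payload: dict[str, Any] = {
        "field": record.field_id,
        "value": None if record.value == ABSTAIN else record.value,
    }
    if record.extra is not None:
        payload["extra"] = record.extra
    return json.dumps(payload, ensure_ascii=False)
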