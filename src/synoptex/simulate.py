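"""Synthetic validation corpus with known ground truth.

Real synoptic reports are PHI-restricted, so validation runs on a controlled
corpus that emulates their surface styles: positive cases embed one correct
ontology value under its checklist heading ("Label: value", numeric-template
tails like "Found number 4", interleaved "nan" noise tokens), negative cases
carry a heading with no valid value (noise and distractor free text such as
"Some other free text."). A configurable fraction of cases is adversarial —
ambiguous wording that defeats literal matching (vague "Tumor is malignant"
phrasing, numeric tails under a mislabeled heading) — and is flagged so that
exact-match identity checks can exclude it.

The default composition is 864 cases: 445 positive and 419 negative. Ground
truth is written to a manifest separate from the input texts so an
extraction run cannot leak labels. Generation is fully reproducible: the
same (schema, config, seed) yields a byte-identical corpus.
"""
from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from ._text import normalize, template_match_form
from .backends import oracle_match
from .schema import FieldSpec, OntologySchema

__all__ = ["SyntheticCase", "CorpusConfig", "generate_suite", "render_case",
           "write_corpus", "read_corpus", "GeneratorError", "STYLES"]

#: Default composition of the validation suite.
DEFAULT_POSITIVES = 445
DEFAULT_NEGATIVES = 419


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticCase:
    """One field-targeted test case with known polarity."""

    case_id: str
    field_id: str
    input_text: str
    polarity: str  # positive | negative
    truth_value: str | None
    truth_extra: int | None
    style_id: str
    adversarial: bool
    seed: int


@dataclass(frozen=True)
class CorpusConfig:
    """Composition of the generated suite (defaults are the study conditions)."""

    positives: int = DEFAULT_POSITIVES
    negatives: int = DEFAULT_NEGATIVES
    adversarial_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.positives < 0 or self.negatives < 0:
            raise GeneratorError("composition counts must be >= 0")
        if not 0.0 <= self.adversarial_fraction <= 1.0:
            raise GeneratorError("adversarial_fraction must lie in [0, 1]")


def _stripped_template(template: str) -> str:
    """Display form of a template with the placeholder removed.

    "Exact distance: — mm" -> "Exact distance: mm"
    """
    return re.sub(r"\s*—\s*", " ", template).strip()


# -- style renderers ---------------------------------------------------------
# Each renderer: (spec, rng) -> (text, truth_value, truth_extra)


def _style_plain(spec: FieldSpec, rng: random.Random):
    value = rng.choice(list(spec.allowed_options))
    return f"{spec.subsection}: {value}", value, None


def _style_noise(spec: FieldSpec, rng: random.Random):
    value = rng.choice(list(spec.allowed_options))
    return f"{spec.subsection}: {value}. nan", value, None


def _style_numeric(spec: FieldSpec, rng: random.Random):
    n = rng.randint(1, 20)
    template = spec.numeric_template or spec.allowed_options[0]
    text = f"{spec.subsection}: {_stripped_template(template)}. Found number {n}"
    return text, template, n


def _style_distractor(spec: FieldSpec, rng: random.Random):
    return f"{spec.subsection}: Comment(s):. nan. Some other free text.", None, None


def _style_nan_only(spec: FieldSpec, rng: random.Random):
    return f"{spec.subsection}: nan.", None, None


def _style_adv_numeric(spec: FieldSpec, rng: random.Random):
    # numeric tail under a mislabeled vague heading; truth not recoverable
    n = rng.randint(1, 20)
    template = spec.numeric_template or spec.allowed_options[0]
    text = f"{spec.subsection} (Note B): At least:. nan. Found number {n}"
    return text, template, n


def _style_adv_vague(spec: FieldSpec, rng: random.Random):
    # vague phrasing that names no canonical option; truth not recoverable
    value = rng.choice(list(spec.allowed_options))
    return f"{spec.subsection}: Tumor is malignant. nan", value, None


def _style_adv_vague_negative(spec: FieldSpec, rng: random.Random):
    return f"{spec.subsection}: Tumor is malignant. nan", None, None


#: style_id -> (renderer, polarity, adversarial flag)
STYLES: dict[str, tuple[Callable, str, bool]] = {
    "plain": (_style_plain, "positive", False),
    "noise": (_style_noise, "positive", False),
    "numeric": (_style_numeric, "positive", False),
    "distractor": (_style_distractor, "negative", False),
    "nan-only": (_style_nan_only, "negative", False),
    "adv-numeric": (_style_adv_numeric, "positive", True),
    "adv-vague": (_style_adv_vague, "positive", True),
    "adv-vague-negative": (_style_adv_vague_negative, "negative", True),
}


def render_case(
    spec: FieldSpec,
    polarity: str,
    style_id: str,
    rng: random.Random,
) -> SyntheticCase:
    """Render one case in the given style (case_id left for the suite)."""
    try:
        renderer, style_polarity, adversarial = STYLES[style_id]
    except KeyError:
        raise GeneratorError(
            f"unknown style {style_id!r}; available: {sorted(STYLES)}"
        ) from None
    if polarity != style_polarity:
        raise GeneratorError(
            f"style {style_id!r} renders {style_polarity} cases, not {polarity}"
        )
    text, truth_value, truth_extra = renderer(spec, rng)
    return SyntheticCase(
        case_id="", field_id=spec.field_id, input_text=text, polarity=polarity,
        truth_value=truth_value, truth_extra=truth_extra, style_id=style_id,
        adversarial=adversarial, seed=0,
    )


# -- polarity soundness ------------------------------------------------------


def _option_forms(spec: FieldSpec) -> list[str]:
    forms = [
        template_match_form(o) if spec.value_kind == "numeric_template"
        else normalize(o)
        for o in spec.allowed_options
    ]
    for alts in spec.synonyms.values():
        forms.extend(normalize(a) for a in alts)
    return forms


def _negative_sound(spec: FieldSpec, text: str) -> bool:
    hay = normalize(text)
    return not any(f and f in hay for f in _option_forms(spec))


def _positive_sound(spec: FieldSpec, case: SyntheticCase) -> bool:
    value, extra = oracle_match(spec, case.input_text)
    return value == case.truth_value and extra == case.truth_extra


# -- suite generation --------------------------------------------------------


def _eligible_fields(schema: OntologySchema) -> list[FieldSpec]:
    return [
        s for s in schema.fields.values()
        if s.value_kind in ("categorical", "numeric_template")
    ]


def _pick_style(spec: FieldSpec, polarity: str, adversarial: bool,
                rng: random.Random) -> str:
    if polarity == "negative":
        if adversarial:
            return "adv-vague-negative"
        return rng.choice(["distractor", "nan-only"])
    if adversarial:
        return "adv-numeric" if spec.value_kind == "numeric_template" \
            else "adv-vague"
    if spec.value_kind == "numeric_template":
        return "numeric"
    return rng.choice(["plain", "noise"])


def _render_sound(spec: FieldSpec, polarity: str, adversarial: bool,
                  rng: random.Random) -> SyntheticCase:
    for _ in range(20):
        style = _pick_style(spec, polarity, adversarial, rng)
        case = render_case(spec, polarity, style, rng)
        if adversarial:
            if _negative_sound(spec, case.input_text):  # no literal option leaked
                return case
        elif polarity == "positive":
            if _positive_sound(spec, case):
                return case
        else:
            if _negative_sound(spec, case.input_text):
                return case
    raise GeneratorError(
        f"could not render a sound {polarity} case for field {spec.field_id!r}"
    )


def generate_suite(
    schema: OntologySchema,
    config: CorpusConfig | None = None,
    seed: int = 0,
) -> list[SyntheticCase]:
    """Generate the full validation suite for the given composition.

    Cases are spread round-robin over a seeded shuffle of all categorical and
    numeric-template fields; the adversarial fraction is assigned to seeded
    case indices within each polarity. Reproducible from ``seed``.
    """
    config = config or CorpusConfig()
    rng = random.Random(seed)
    eligible = _eligible_fields(schema)
    if (config.positives or config.negatives) and not eligible:
        raise GeneratorError(
            "schema has no categorical or numeric_template fields to simulate"
        )
    pos_fields = list(eligible)
    rng.shuffle(pos_fields)
    neg_fields = list(eligible)
    rng.shuffle(neg_fields)

    n_adv_pos = round(config.positives * config.adversarial_fraction)
    n_adv_neg = round(config.negatives * config.adversarial_fraction)
    adv_pos = set(rng.sample(range(config.positives), n_adv_pos)) \
        if config.positives else set()
    adv_neg = set(rng.sample(range(config.negatives), n_adv_neg)) \
        if config.negatives else set()

    cases: list[SyntheticCase] = []

    def emit(spec: FieldSpec, polarity: str, adversarial: bool) -> None:
        case = _render_sound(spec, polarity, adversarial, rng)
        idx = len(cases)
        cases.append(SyntheticCase(
            case_id=f"case-{idx:04d}",
            field_id=case.field_id,
            input_text=case.input_text,
            polarity=case.polarity,
            truth_value=case.truth_value,
            truth_extra=case.truth_extra,
            style_id=case.style_id,
            adversarial=case.adversarial,
            seed=rng.randrange(2 ** 31),
        ))

    for i in range(config.positives):
        emit(pos_fields[i % len(pos_fields)], "positive", i in adv_pos)
    for i in range(config.negatives):
        emit(neg_fields[i % len(neg_fields)], "negative", i in adv_neg)
    return cases


# -- corpus I/O --------------------------------------------------------------


def write_corpus(cases: Sequence[SyntheticCase], outdir: str | Path
                 ) -> tuple[Path, Path]:
    """Write inputs.jsonl and the separate truth.jsonl manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = outdir / "inputs.jsonl"
    truth = outdir / "truth.jsonl"
    with inputs.open("w", encoding="utf-8") as fi, \
            truth.open("w", encoding="utf-8") as ft:
        for c in cases:
            fi.write(json.dumps(
                {"report_id": c.case_id, "field_id": c.field_id,
                 "text": c.input_text},
                ensure_ascii=False, sort_keys=True) + "\n")
            ft.write(json.dumps(
                {"report_id": c.case_id, "field_id": c.field_id,
                 "truth_value": c.truth_value, "truth_extra": c.truth_extra,
                 "polarity": c.polarity, "adversarial": c.adversarial,
                 "style_id": c.style_id, "seed": c.seed},
                ensure_ascii=False, sort_keys=True) + "\n")
    return inputs, truth


def read_corpus(outdir: str | Path) -> list[SyntheticCase]:
    outdir = Path(outdir)
    truths = {}
    with (outdir / "truth.jsonl").open(encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                d = json.loads(line)
                truths[d["report_id"]] = d
    cases = []
    with (outdir / "inputs.jsonl").open(encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            t = truths[d["report_id"]]
            cases.append(SyntheticCase(
                case_id=d["report_id"], field_id=d["field_id"],
                input_text=d["text"], polarity=t["polarity"],
                truth_value=t["truth_value"], truth_extra=t["truth_extra"],
                style_id=t["style_id"], adversarial=t["adversarial"],
                seed=t["seed"],
            ))
    return cases
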