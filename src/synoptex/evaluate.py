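"""Dual-regime scoring: complete truth vs positive-only truth.

Two annotation regimes arise in practice. A synthetic corpus carries
*complete* truth — every case asserts either a value or its absence — so the
full confusion table (TP/FP/TN/FN) and the whole metric suite (sensitivity,
specificity, precision, F1, MCC, accuracy) are computable. Manually curated
clinical truth is typically *positive-only*: annotators record fields that
are present and never assert absence, so FP and TN are unknowable; the only
honest metric is recall = TP/(TP+FN), the fraction of annotated fields
correctly extracted. The "reality gap" is the drop, in percentage points,
from synthetic accuracy to real-world recall.

A prediction is correct when its normalized value exactly equals the
normalized truth (and, for numeric-template fields, the integer extra
matches too). Abstentions and invalid responses on annotated-present fields
both count as FN; on truth-absent fields they count as TN.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from math import sqrt
from typing import Any, Iterable, Mapping, Sequence

from ._text import ABSTAIN, normalize, template_match_form
from .backends import ExtractionRecord

__all__ = [
    "Outcome", "GroundTruthRecord", "ConfusionSummary", "MetricReport",
    "classify", "summarize", "evaluate_records", "recall", "full_metrics",
    "reality_gap", "as_percent", "EvaluationError",
]

COMPLETE = "complete"
POSITIVE_ONLY = "positive_only"


class EvaluationError(ValueError):
    pass


class Outcome(str, Enum):
    TP = "TP"
    FP = "FP"
    TN = "TN"
    FN = "FN"
    SKIP = "skip"


@dataclass(frozen=True)
class GroundTruthRecord:
    """Truth for one (report, field); ``truth_value=None`` asserts absence."""

    report_id: str
    field_id: str
    truth_value: str | None
    truth_extra: int | None = None
    regime: str = COMPLETE

    def __post_init__(self) -> None:
        if self.regime not in (COMPLETE, POSITIVE_ONLY):
            raise EvaluationError(f"unknown regime {self.regime!r}")
        if self.regime == POSITIVE_ONLY and self.truth_value is None:
            raise EvaluationError(
                "positive_only truth records always carry a value; absence is "
                "never asserted in that regime"
            )


@dataclass(frozen=True)
class ConfusionSummary:
    """TP/FP/TN/FN tallies under one annotation regime.

    In the positive_only regime FP and TN are structurally unavailable (zero
    here by construction, reported as unavailable, not as zeros).
    """

    tp: int
    fp: int
    tn: int
    fn: int
    regime: str = COMPLETE

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")
        if self.regime == POSITIVE_ONLY and (self.fp or self.tn):
            raise EvaluationError(
                "positive_only regime cannot produce FP or TN counts"
            )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    """Metric suite; ``None`` marks a metric unavailable (zero denominator
    or positive-only regime), never a zero value."""

    regime: str
    summary: ConfusionSummary
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None
    mcc: float | None
    accuracy: float | None

    def rendered(self) -> dict[str, Any]:
        """Percentages to 1 decimal (half-up), MCC to 3 decimals."""
        out: dict[str, Any] = {"regime": self.regime,
                               "counts": {"tp": self.summary.tp,
                                          "fp": self.summary.fp,
                                          "tn": self.summary.tn,
                                          "fn": self.summary.fn}}
        for name in ("sensitivity", "specificity", "precision", "f1",
                     "accuracy"):
            v = getattr(self, name)
            out[name + "_pct"] = None if v is None else as_percent(v)
        out["mcc"] = None if self.mcc is None else float(
            Decimal(repr(self.mcc)).quantize(Decimal("0.001"),
                                             rounding=ROUND_HALF_UP))
        return out


def as_percent(proportion: float) -> float:
    """Proportion -> percentage rounded half-up to 1 decimal (87.7 style)."""
    return float(
        (Decimal(repr(proportion)) * 100).quantize(Decimal("0.1"),
                                                   rounding=ROUND_HALF_UP)
    )


# -- classification ----------------------------------------------------------


def _values_match(pred: ExtractionRecord, truth: GroundTruthRecord,
                  require_extra_match: bool) -> bool:
    assert truth.truth_value is not None
    if normalize(pred.value) != normalize(truth.truth_value) \
            and template_match_form(pred.value) != template_match_form(truth.truth_value):
        return False
    if require_extra_match and truth.truth_extra is not None:
        return pred.extra == truth.truth_extra
    return True


def classify(
    prediction: ExtractionRecord,
    truth: GroundTruthRecord,
    *,
    require_extra_match: bool = True,
) -> Outcome:
    """Score one prediction against its truth record.

    Complete regime: TP on exact normalized match (value and, when the truth
    carries one, extra); FN when truth is present but the prediction is
    wrong, abstaining or invalid; TN when truth is absent and the prediction
    abstains (or is invalid); FP when truth is absent but a value was
    predicted.
    """
    if (prediction.report_id, prediction.field_id) != \
            (truth.report_id, truth.field_id):
        raise EvaluationError(
            f"prediction {(prediction.report_id, prediction.field_id)} does "
            f"not match truth {(truth.report_id, truth.field_id)}"
        )
    extracted = prediction.status != "invalid" and prediction.value != ABSTAIN
    if truth.truth_value is not None:
        if extracted and _values_match(prediction, truth, require_extra_match):
            return Outcome.TP
        return Outcome.FN
    # truth asserts absence (complete regime only, enforced by the dataclass)
    return Outcome.FP if extracted else Outcome.TN


def summarize(
    outcomes: Iterable[Outcome | tuple[Outcome, str]],
    regime: str = COMPLETE,
) -> ConfusionSummary:
    """Tally outcomes into a confusion summary; ``skip`` is excluded.

    Accepts plain outcomes or (outcome, regime) pairs; mixing regimes in the
    pairs is a contract error.
    """
    counts = {o: 0 for o in Outcome}
    seen_regimes = set()
    for item in outcomes:
        if isinstance(item, tuple):
            outcome, item_regime = item
            seen_regimes.add(item_regime)
        else:
            outcome = item
        counts[outcome] += 1
    if len(seen_regimes) > 1:
        raise EvaluationError(f"mixed regimes in outcomes: {sorted(seen_regimes)}")
    if seen_regimes:
        regime = seen_regimes.pop()
    return ConfusionSummary(
        tp=counts[Outcome.TP], fp=counts[Outcome.FP],
        tn=counts[Outcome.TN], fn=counts[Outcome.FN], regime=regime,
    )


def evaluate_records(
    predictions: Sequence[ExtractionRecord],
    truths: Sequence[GroundTruthRecord],
    *,
    regime: str = COMPLETE,
    require_extra_match: bool = True,
) -> tuple[list[Outcome], ConfusionSummary]:
    """Pair predictions with truths by (report_id, field_id) and score them.

    In the positive_only regime predictions without an annotated truth are
    skipped (only field-sample combinations with definitive ground truth are
    evaluated); in the complete regime every prediction must have a truth.
    """
    truth_map: dict[tuple[str, str], GroundTruthRecord] = {}
    for t in truths:
        if t.regime != regime:
            raise EvaluationError(
                f"truth record {t.report_id}/{t.field_id} has regime "
                f"{t.regime!r}, expected {regime!r}"
            )
        truth_map[(t.report_id, t.field_id)] = t
    outcomes: list[Outcome] = []
    for pred in predictions:
        truth = truth_map.get((pred.report_id, pred.field_id))
        if truth is None:
            if regime == POSITIVE_ONLY:
                outcomes.append(Outcome.SKIP)
                continue
            raise EvaluationError(
                f"no truth for prediction {pred.report_id}/{pred.field_id} "
                "in complete regime"
            )
        outcomes.append(classify(pred, truth,
                                 require_extra_match=require_extra_match))
    return outcomes, summarize(outcomes, regime)


# -- metrics -----------------------------------------------------------------


def recall(summary: ConfusionSummary) -> float:
    """TP/(TP+FN): fraction of annotated fields correctly extracted."""
    denom = summary.tp + summary.fn
    if denom == 0:
        raise EvaluationError("recall undefined: tp + fn = 0")
    return summary.tp / denom


def _ratio(num: int, denom: int) -> float | None:
    return num / denom if denom else None


def full_metrics(summary: ConfusionSummary) -> MetricReport:
    """The complete-regime metric suite from one confusion table.

    Raises in the positive_only regime: precision, specificity, F1 and MCC
    require true-negative knowledge that positive-only truth cannot supply.
    Zero-denominator metrics are marked unavailable (``None``).
    """
    if summary.regime == POSITIVE_ONLY:
        raise EvaluationError(
            "positive-only truth restricts evaluation to recall; precision, "
            "specificity, F1 score and MCC cannot be computed"
        )
    tp, fp, tn, fn = summary.tp, summary.fp, summary.tn, summary.fn
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    prec = _ratio(tp, tp + fp)
    f1 = None
    if prec is not None and sens is not None and (prec + sens) > 0:
        f1 = 2 * prec * sens / (prec + sens)
    mcc_denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / sqrt(mcc_denom) if mcc_denom else None
    acc = _ratio(tp + tn, summary.total)
    return MetricReport(
        regime=summary.regime, summary=summary, sensitivity=sens,
        specificity=spec, precision=prec, f1=f1, mcc=mcc, accuracy=acc,
    )


def reality_gap(synthetic_accuracy: float, real_recall: float) -> float:
    """Synthetic accuracy minus real-world recall, in percentage points.

    Both inputs are percentages in [0, 100]; the result keeps the tables'
    1-decimal rendering.
    """
    for v in (synthetic_accuracy, real_recall):
        if not 0.0 <= v <= 100.0:
            raise EvaluationError(
                f"percentages must lie in [0, 100], got {v!r}"
            )
    gap = Decimal(repr(synthetic_accuracy)) - Decimal(repr(real_recall))
    return float(gap.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
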