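"""Segment classification and the framework's evaluation metrics.

A retrieved entry falls into exactly one segment of the cross-disciplinary
solution set: matched by one discipline's expert query (discipline-specific),
by two or more (expert overlap), or by none despite matching the full query
(a *golden gap* — cross-disciplinary work phrased in generalized language in
at least one scope category).  On top of the segmentation this module
computes relative sensitivity (CRIS true positives over a comparison
strategy's true positives, as a percent), the composition shares of the
deduplicated base, and the stage-wise reduction achieved by screening.

All percentages are rounded half-up to one decimal, the reporting precision
used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .bibio import BibEntry
from .errors import InputError
from .query import QuerySuite, evaluate_query
from .screening import StageSummary

EXPERT_OVERLAP = "expert_overlap"
GOLDEN_GAP = "golden_gap"


def round1(value) -> float:
    """Half-up rounding to one decimal (``2.25 -> 2.3``)."""
    return float(Decimal(str(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _percent(numerator: int, denominator: int) -> float:
    return float(
        (Decimal(100 * numerator) / Decimal(denominator)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


def classify_segments(entries, suite: QuerySuite) -> dict[str, str]:
    """Assign every retrieved entry its segment label.

    Labels are the matching discipline's id (exactly one expert query
    matches), ``expert_overlap`` (two or more match) or ``golden_gap`` (none
    match).  Entries that do not match the full query are not retrieved
    entries and raise :class:`InputError`.
    """
    labels: dict[str, str] = {}
    for entry in entries:
        if not evaluate_query(suite.full, entry):
            raise InputError(
                f"entry {entry.id!r} does not match the full query; "
                "classification is defined on the retrieved set only"
            )
        matching = [
            d for d, q in suite.per_discipline.items() if evaluate_query(q, entry)
        ]
        if len(matching) >= 2:
            labels[entry.id] = EXPERT_OVERLAP
        elif len(matching) == 1:
            labels[entry.id] = matching[0]
        else:
            labels[entry.id] = GOLDEN_GAP
    return labels


def relative_sensitivity(tp_cris: int, tp_other: int) -> float:
    """``100 * tp_cris / tp_other`` as a percent, one decimal, half-up."""
    if tp_other <= 0:
        raise InputError("comparison strategy found no true positives; ratio undefined")
    return _percent(tp_cris, tp_other)


def composition(segment_counts: dict[str, int], base: int) -> dict[str, float]:
    """Per-segment share of the deduplicated base, as percents."""
    if base <= 0:
        raise InputError("composition base must be positive")
    if sum(segment_counts.values()) != base:
        raise InputError(
            f"segment counts {dict(segment_counts)!r} do not sum to base {base}"
        )
    return {label: _percent(count, base) for label, count in segment_counts.items()}


def reduction_stats(stage_counts) -> tuple[list[float], float]:
    """Per-stage and overall removal percentages of a screening chain.

    ``stage_counts`` is the entry count before filtering followed by the
    remainder after each stage; it must be non-increasing.
    """
    counts = list(stage_counts)
    if not counts or counts[0] <= 0:
        raise InputError("stage counts must start with a positive total")
    if any(b > a for a, b in zip(counts, counts[1:])):
        raise InputError(f"stage counts must be non-increasing: {counts}")
    per_stage = [
        _percent(a - b, a) if a else 0.0 for a, b in zip(counts, counts[1:])
    ]
    overall = _percent(counts[0] - counts[-1], counts[0]) if len(counts) > 1 else 0.0
    return per_stage, overall


@dataclass
class EvaluationReport:
    """Aggregate evaluation of one cross-disciplinary search run."""

    base_count: int
    segment_counts: dict[str, int]
    segment_shares: dict[str, float]
    relative_sensitivity: dict[str, float] = field(default_factory=dict)
    reduction_per_stage: list[float] = field(default_factory=list)
    reduction_overall: float | None = None
    filtered_out: int | None = None  # absolute specificity proxy

    def to_dict(self) -> dict:
        return {
            "base_count": self.base_count,
            "segment_counts": dict(self.segment_counts),
            "segment_shares": dict(self.segment_shares),
            "relative_sensitivity": dict(self.relative_sensitivity),
            "reduction_per_stage": list(self.reduction_per_stage),
            "reduction_overall": self.reduction_overall,
            "filtered_out": self.filtered_out,
        }

    def to_markdown(self) -> str:
        lines = ["# Evaluation report", ""]
        lines.append(f"Deduplicated base: {self.base_count} entries")
        lines.append("")
        lines.append("| segment | entries | share |")
        lines.append("|---|---|---|")
        for label, count in self.segment_counts.items():
            lines.append(f"| {label} | {count} | {self.segment_shares[label]}% |")
        if self.relative_sensitivity:
            lines.append("")
            lines.append("| comparison strategy | relative sensitivity |")
            lines.append("|---|---|")
            for strategy, pct in self.relative_sensitivity.items():
                lines.append(f"| {strategy} | {pct}% |")
        if self.reduction_overall is not None:
            lines.append("")
            lines.append(
                f"Screening reduction: {self.reduction_overall}% overall"
                + (
                    f" ({self.filtered_out} entries filtered out)"
                    if self.filtered_out is not None
                    else ""
                )
            )
        return "\n".join(lines) + "\n"


def build_report(
    entries: list[BibEntry],
    suite: QuerySuite,
    tp_cris: int | None = None,
    tp_comparisons: dict[str, int] | None = None,
    stage_summary: StageSummary | None = None,
) -> EvaluationReport:
    """Classify the retrieved set and assemble the full evaluation report.

    True-positive counts are caller-designated (typically the post-screening
    included entries); this module only computes the ratios.
    """
    labels = classify_segments(entries, suite)
    order = list(suite.per_discipline) + [EXPERT_OVERLAP, GOLDEN_GAP]
    counts = {label: 0 for label in order}
    for label in labels.values():
        counts[label] = counts.get(label, 0) + 1
    base = len(entries)
    shares = composition(counts, base) if base else {label: 0.0 for label in counts}
    sens = {}
    if tp_cris is not None and tp_comparisons:
        sens = {
            strategy: relative_sensitivity(tp_cris, tp)
            for strategy, tp in tp_comparisons.items()
        }
    per_stage: list[float] = []
    overall = None
    filtered = None
    if stage_summary is not None and stage_summary.stages:
        chain = stage_summary.counts_chain
        per_stage, overall = reduction_stats(chain)
        filtered = chain[0] - chain[-1]
    return EvaluationReport(
        base_count=base,
        segment_counts=counts,
        segment_shares=shares,
        relative_sensitivity=sens,
        reduction_per_stage=per_stage,
        reduction_overall=overall,
        filtered_out=filtered,
    )
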