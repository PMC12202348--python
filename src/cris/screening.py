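"""Semi-automated screening by sequential term-group filters.

Screening applies named exclusion-term groups (child-related,
disease-related, ...) one after another over titles, abstracts and
keywords.  An entry is excluded at the *first* group any of whose terms
matches, and every exclusion carries the matched terms as evidence so a
reviewer can audit the decision from a highlighted report.  False negatives
are rescued — sticky across re-runs — optionally together with a refined
filter that triggers a re-run of the whole sequence.  The final
include/exclude decision on screened entries follows the cross-disciplinary
consensus rule: an entry stays in if at least one discipline still finds it
relevant after discussion.
"""

from __future__ import annotations

import html as _html
import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ._text import fold_diacritics
from .bibio import BibEntry
from .errors import CellReferenceError, InputError, StateError
from .matrix import DEFAULT_SCOPE, Term, term_from_spec
from .query import match_fields

STATUS_INCLUDED = "included"
STATUS_EXCLUDED = "excluded"
STATUS_RESCUED = "rescued"

VOTE_RELEVANT = "relevant"
VOTE_NEUTRAL = "neutral"
VOTE_EXCLUDED = "excluded"


@dataclass(frozen=True)
class FilterGroup:
    """A named set of exclusion terms applied over the screening scope."""

    name: str
    terms: tuple[Term, ...]
    scope: frozenset = DEFAULT_SCOPE

    def __post_init__(self) -> None:
        if not self.name:
            raise InputError("filter group needs a name")
        if not self.terms:
            raise InputError(f"filter group {self.name!r} has no terms")

    def matches(self, entry: BibEntry) -> list[tuple[str, str]]:
        hits = []
        for term in self.terms:
            hits.extend(match_fields(term, entry, self.scope))
        return hits


def load_filter_groups(source) -> list[FilterGroup]:
    """Load an ordered filter sequence from YAML::

        - name: child-related
          terms: [child*, toddler, girl]
    """
    if isinstance(source, list):
        doc = source
    else:
        text = source
        if isinstance(source, Path) or (
            isinstance(source, str)
            and "\n" not in source
            and source.endswith((".yaml", ".yml", ".json"))
        ):
            text = Path(source).read_text(encoding="utf-8")
        doc = yaml.safe_load(text)
    if not isinstance(doc, list):
        raise InputError("filter document must be a list of groups")
    groups = []
    for item in doc:
        scope = item.get("scope")
        groups.append(
            FilterGroup(
                name=str(item["name"]),
                terms=tuple(term_from_spec(t) for t in item.get("terms", ())),
                scope=frozenset(scope) if scope else DEFAULT_SCOPE,
            )
        )
    names = [g.name for g in groups]
    if len(set(names)) != len(names):
        raise InputError(f"filter group names are not unique: {names}")
    return groups


@dataclass
class ScreeningRecord:
    """Per-entry screening outcome with matched-term evidence and votes."""

    entry_id: str
    status: str = STATUS_INCLUDED
    stage: str = ""
    matched_terms: tuple[tuple[str, str], ...] = ()
    votes: dict = field(default_factory=dict)
    final: bool = True


@dataclass(frozen=True)
class StageStat:
    name: str
    entering: int
    excluded: int

    @property
    def remaining(self) -> int:
        return self.entering - self.excluded


@dataclass(frozen=True)
class StageSummary:
    stages: tuple[StageStat, ...]

    @property
    def remaining_counts(self) -> tuple[int, ...]:
        return tuple(s.remaining for s in self.stages)

    @property
    def counts_chain(self) -> tuple[int, ...]:
        """Entry count entering stage 1 followed by each stage's remainder."""
        if not self.stages:
            return ()
        return (self.stages[0].entering,) + self.remaining_counts


@dataclass
class ScreeningResult:
    """Entries, filters, per-entry records and the stage chain of one run."""

    entries: list[BibEntry]
    filters: list[FilterGroup]
    records: dict[str, ScreeningRecord]
    summary: StageSummary
    passes: list[StageSummary] = field(default_factory=list)

    @property
    def included_ids(self) -> list[str]:
        return [
            r.entry_id for r in self.records.values() if r.final
        ]

    @property
    def excluded_ids(self) -> list[str]:
        return [r.entry_id for r in self.records.values() if not r.final]


def apply_filter_sequence(
    entries: list[BibEntry],
    filters: list[FilterGroup],
    sticky_rescues: frozenset = frozenset(),
) -> ScreeningResult:
    """Run the ordered filter sequence with first-match stage attribution.

    Entries excluded at stage *k* never reach stage *k+1*; rescued entry ids
    in ``sticky_rescues`` keep their included status regardless of matches.
    """
    records = {
        e.id: ScreeningRecord(entry_id=e.id) for e in entries
    }
    active = list(entries)
    stats = []
    for group in filters:
        entering = len(active)
        survivors = []
        excluded_here = 0
        for entry in active:
            hits = group.matches(entry)
            if hits and entry.id not in sticky_rescues:
                records[entry.id] = ScreeningRecord(
                    entry_id=entry.id,
                    status=STATUS_EXCLUDED,
                    stage=group.name,
                    matched_terms=tuple(hits),
                    final=False,
                )
                excluded_here += 1
            else:
                if hits:  # rescued earlier: keep the evidence, stay included
                    records[entry.id] = ScreeningRecord(
                        entry_id=entry.id,
                        status=STATUS_RESCUED,
                        stage=group.name,
                        matched_terms=tuple(hits),
                        final=True,
                    )
                survivors.append(entry)
        stats.append(StageStat(group.name, entering, excluded_here))
        active = survivors
    summary = StageSummary(tuple(stats))
    result = ScreeningResult(
        entries=list(entries),
        filters=list(filters),
        records=records,
        summary=summary,
    )
    result.passes.append(summary)
    return result


# ---------------------------------------------------------------------------
# review reports


def _highlight_pattern(surface: str) -> re.Pattern:
    """Regex locating a matched term in the original prose."""
    tokens = re.findall(r"[0-9a-zA-Z]+", fold_diacritics(surface))
    if not tokens:
        return re.compile(r"(?!x)x")
    joined = r"[^0-9a-zA-Z]+".join(re.escape(t) for t in tokens)
    return re.compile(rf"(?<![0-9a-zA-Z])({joined}[0-9a-zA-Z]*)", re.IGNORECASE)


def highlight(text: str, terms, marker: tuple[str, str] = ("**", "**")) -> str:
    """Wrap every occurrence of the matched terms in highlight markers."""
    opening, closing = marker
    for term in terms:
        if isinstance(term, Term):
            surface, mode = term.surface, term.match_mode
        else:
            surface, mode = str(term), None
        pattern = _highlight_pattern(surface)
        if mode == "word":  # no token-suffix bleed for whole-word terms
            pattern = re.compile(
                rf"(?<![0-9a-zA-Z])({re.escape(surface)})(?![0-9a-zA-Z])",
                re.IGNORECASE,
            )
        text = pattern.sub(lambda m: f"{opening}{m.group(1)}{closing}", text)
    return text


def generate_review_report(
    result: ScreeningResult, stage: str, fmt: str = "markdown"
) -> str:
    """Human-review document for one stage: per excluded entry, the title and
    abstract with the triggering terms highlighted, plus the term list.

    Sections are ordered by entry id; an empty stage yields a valid report
    with zero sections.
    """
    if stage not in {g.name for g in result.filters}:
        raise CellReferenceError(f"unknown screening stage {stage!r}")
    by_id = {e.id: e for e in result.entries}
    excluded = sorted(
        (r for r in result.records.values() if r.stage == stage and not r.final),
        key=lambda r: r.entry_id,
    )
    group = next(g for g in result.filters if g.name == stage)
    surface_terms = {t.surface: t for t in group.terms}

    lines = [f"# Review report — filter '{stage}'", ""]
    lines.append(f"{len(excluded)} entries excluded at this stage.")
    lines.append("")
    for record in excluded:
        entry = by_id[record.entry_id]
        terms = [
            surface_terms.get(surface, surface)
            for surface in dict.fromkeys(s for s, _f in record.matched_terms)
        ]
        lines.append(f"## {record.entry_id}: {highlight(entry.title, terms)}")
        lines.append("")
        lines.append(highlight(entry.abstract, terms))
        lines.append("")
        matched = ", ".join(
            f"{surface} ({fieldname})" for surface, fieldname in record.matched_terms
        )
        lines.append(f"Matched terms: {matched}")
        lines.append("")
    report = "\n".join(lines)
    if fmt == "markdown":
        return report
    if fmt == "html":
        body = _html.escape(report).replace("**", "")
        sections = []
        for record in excluded:
            entry = by_id[record.entry_id]
            terms = [
                surface_terms.get(surface, surface)
                for surface in dict.fromkeys(s for s, _f in record.matched_terms)
            ]
            sections.append(
                f"<h2>{_html.escape(record.entry_id)}: "
                f"{highlight(_html.escape(entry.title), terms, ('<mark>', '</mark>'))}</h2>"
                f"<p>{highlight(_html.escape(entry.abstract), terms, ('<mark>', '</mark>'))}</p>"
            )
        return (
            f"<html><body><h1>Review report — filter '{_html.escape(stage)}'</h1>"
            + "".join(sections)
            + "</body></html>"
        )
    raise InputError(f"unknown report format {fmt!r}")


# ---------------------------------------------------------------------------
# rescue and consensus


def rescue(
    result: ScreeningResult,
    entry_id: str,
    refined_filter: FilterGroup | None = None,
) -> ScreeningResult:
    """Mark a falsely excluded entry as included (sticky), optionally
    replacing the same-named filter with a refined version and re-running.

    The audit trail keeps one :class:`StageSummary` per pass.
    """
    record = result.records.get(entry_id)
    if record is None:
        raise StateError(f"unknown entry {entry_id!r}")
    if record.final:
        raise StateError(f"entry {entry_id!r} is not excluded; nothing to rescue")

    sticky = frozenset(
        {entry_id}
        | {r.entry_id for r in result.records.values() if r.status == STATUS_RESCUED}
    )
    filters = list(result.filters)
    if refined_filter is not None:
        names = [g.name for g in filters]
        if refined_filter.name not in names:
            raise CellReferenceError(
                f"refined filter {refined_filter.name!r} does not replace an "
                f"existing stage {names}"
            )
        filters[names.index(refined_filter.name)] = refined_filter

    rerun = apply_filter_sequence(result.entries, filters, sticky_rescues=sticky)
    # A sticky entry that still matches is marked rescued by the run itself;
    # one the refinement no longer matches is a plain inclusion now.
    rerun.passes = result.passes + [rerun.summary]
    return rerun


def consensus_include(votes: dict) -> tuple[str, bool]:
    """Cross-disciplinary consensus on one screened entry.

    Include iff at least one reviewer (discipline) votes relevant; a
    discussion is flagged whenever the vote set is neither unanimously
    relevant nor unanimously excluded.  Post-discussion votes are resubmitted
    through this same rule.
    """
    if not votes:
        raise InputError("empty vote map")
    values = set(votes.values())
    unknown = values - {VOTE_RELEVANT, VOTE_NEUTRAL, VOTE_EXCLUDED}
    if unknown:
        raise InputError(f"unknown votes {sorted(unknown)!r}")
    decision = "include" if VOTE_RELEVANT in values else "exclude"
    needs_discussion = values not in ({VOTE_RELEVANT}, {VOTE_EXCLUDED})
    return decision, needs_discussion
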