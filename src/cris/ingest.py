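"""Solution-set alignment: cross-database deduplication and record exclusion.

A cross-disciplinary search unions exports from several databases, so the
same article typically appears more than once.  Deduplication runs three
cascading passes — identical DOIs, identical (normalized title, year), and a
fuzzy normalized-title pass guarded by equal year — and keeps, per duplicate
group, the entry from the highest-priority source.  The alignment exclusions
then drop records that fail the review's eligibility rules on metadata
alone: the whole word "review" (or "reviews") in the title, or a book-like
entry type.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from itertools import combinations

from .bibio import BibEntry

#: Entry types treated as books during alignment.
BOOK_TYPES = frozenset({"book", "inbook", "incollection", "proceedings"})
#: Title tokens that mark a review article.
REVIEW_TOKENS = frozenset({"review", "reviews"})

RULE_TITLE_REVIEW = "title-review"
RULE_BOOK_TYPE = "book-type"

REASON_DOI = "doi"
REASON_TITLE_YEAR = "title-year"
REASON_FUZZY = "fuzzy-title"


@dataclass
class DedupReport:
    """Audit record of one deduplication run."""

    kept: tuple[str, ...]
    merged: dict[str, list[tuple[str, str]]]  # kept id -> [(duplicate id, reason)]
    counts_per_source: dict[str, int]

    @property
    def duplicate_count(self) -> int:
        return sum(len(v) for v in self.merged.values())


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[rj] = ri
        return True


def _norm_doi(doi: str) -> str:
    doi = doi.strip().lower()
    for prefix in ("https://doi.org/", "http://doi.org/", "doi:"):
        if doi.startswith(prefix):
            doi = doi[len(prefix) :]
    return doi


def deduplicate(
    entries: list[BibEntry],
    source_priority: list[str] | None = None,
    fuzzy: bool = True,
    fuzzy_threshold: float = 0.95,
) -> tuple[list[BibEntry], DedupReport]:
    """Merge duplicate records across databases.

    Returns the kept entries (each carrying the union of its group's source
    databases) and an audit report.  ``|kept| + |merged| == |input|``.
    """
    n = len(entries)
    uf = _UnionFind(n)
    reasons: dict[int, str] = {}

    def merge(i: int, j: int, reason: str) -> None:
        if uf.union(i, j):
            reasons[j] = reasons.get(j, reason)
        else:
            reasons.setdefault(j, reason)

    by_doi: dict[str, int] = {}
    for i, e in enumerate(entries):
        doi = _norm_doi(e.doi)
        if not doi:
            continue
        if doi in by_doi:
            merge(by_doi[doi], i, REASON_DOI)
        else:
            by_doi[doi] = i

    by_title_year: dict[tuple[str, int | None], int] = {}
    for i, e in enumerate(entries):
        key = (e.norm_title, e.year)
        if not e.norm_title:
            continue
        if key in by_title_year:
            merge(by_title_year[key], i, REASON_TITLE_YEAR)
        else:
            by_title_year[key] = i

    if fuzzy:
        by_year: dict[int | None, list[int]] = {}
        for i, e in enumerate(entries):
            if e.norm_title:
                by_year.setdefault(e.year, []).append(i)
        for group in by_year.values():
            roots = sorted({uf.find(i) for i in group})
            for i, j in combinations(roots, 2):
                if uf.find(i) == uf.find(j):
                    continue
                a, b = entries[i].norm_title, entries[j].norm_title
                matcher = difflib.SequenceMatcher(None, a, b)
                if matcher.real_quick_ratio() < fuzzy_threshold:
                    continue
                if matcher.ratio() >= fuzzy_threshold:
                    merge(i, j, REASON_FUZZY)

    priority = list(source_priority) if source_priority else []

    def rank(e: BibEntry) -> tuple:
        src = e.source_databases[0] if e.source_databases else ""
        pr = priority.index(src) if src in priority else len(priority)
        return (pr, e.id)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)

    kept_entries: list[BibEntry] = []
    merged: dict[str, list[tuple[str, str]]] = {}
    for root, members in groups.items():
        rep_idx = min(members, key=lambda i: rank(entries[i]))
        rep = entries[rep_idx]
        sources: dict[str, None] = {}
        for i in sorted(members, key=lambda i: rank(entries[i])):
            for s in entries[i].source_databases:
                sources.setdefault(s)
        kept = BibEntry(
            id=rep.id,
            entry_type=rep.entry_type,
            title=rep.title,
            abstract=rep.abstract,
            keywords=rep.keywords,
            authors=rep.authors,
            year=rep.year,
            doi=rep.doi,
            source_databases=tuple(sources),
            raw_fields=dict(rep.raw_fields),
        )
        kept_entries.append(kept)
        dups = [i for i in members if i != rep_idx]
        if dups:
            merged[rep.id] = [
                (entries[i].id, reasons.get(i, reasons.get(uf.find(i), REASON_DOI)))
                for i in sorted(dups)
            ]

    order = {e.id: i for i, e in enumerate(entries)}
    kept_entries.sort(key=lambda e: order[e.id])
    counts: dict[str, int] = {}
    for e in entries:
        for s in e.source_databases:
            counts[s] = counts.get(s, 0) + 1
    report = DedupReport(
        kept=tuple(e.id for e in kept_entries),
        merged=merged,
        counts_per_source=counts,
    )
    return kept_entries, report


@dataclass(frozen=True)
class ExclusionRecord:
    entry_id: str
    rule: str
    detail: str = ""


def apply_alignment_exclusions(
    entries: list[BibEntry],
    review_tokens: frozenset = REVIEW_TOKENS,
    book_types: frozenset = BOOK_TYPES,
) -> tuple[list[BibEntry], list[ExclusionRecord]]:
    """Drop reviews (whole-token title match) and book-like entry types.

    Idempotent; ``|retained| + |excluded| == |input|``.
    """
    kept: list[BibEntry] = []
    log: list[ExclusionRecord] = []
    for e in entries:
        title_tokens = set(e.field_tokens("title"))
        hit = title_tokens & review_tokens
        if hit:
            log.append(ExclusionRecord(e.id, RULE_TITLE_REVIEW, sorted(hit)[0]))
        elif e.entry_type in book_types:
            log.append(ExclusionRecord(e.id, RULE_BOOK_TYPE, e.entry_type))
        else:
            kept.append(e)
    return kept, log
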