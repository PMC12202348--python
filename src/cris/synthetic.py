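"""Deterministic synthetic BibTeX corpora with planted ground truth.

Every pipeline stage is testable without live database exports: the
generator emits per-pseudo-database BibTeX files whose titles, abstracts and
keywords embed controlled mixtures of expert, general and filter-trigger
vocabulary drawn from a bundled two-discipline fixture matrix.  Planted
structure covers the four result segments (one term per scope category, in
the voice the segment requires), cross-database duplicates with cosmetic
title variants, review/book records for the alignment exclusions, and
stage-wise screening triggers.  Output is byte-identical for identical seeds,
and the ground truth is self-verifying: re-matching the emitted text against
the matrix queries reproduces the planted labels exactly.

Template prose is deliberately bland and token-disjoint from every query and
filter vocabulary; abstracts are not natural language, which is adequate
because all matching operators are token-level.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources

from .bibio import BibEntry, write_bibtex
from .errors import InputError, SpecError
from .evaluation import EXPERT_OVERLAP, GOLDEN_GAP, classify_segments
from .matrix import FoundationalSearchMatrix, load_matrix
from .query import build_query_suite
from .screening import FilterGroup, load_filter_groups

#: Pseudo-database names used by the corpus generator.
DATABASES = ("alpha", "beta", "gamma")

_OPENERS = (
    "This manuscript outlines a supervised initiative conducted across "
    "several municipal centres.",
    "We summarise a multi-site initiative coordinated by regional partners.",
    "The present account documents a longitudinal municipal effort.",
)
_TERM_SENTENCE = "The investigation foregrounds {terms} throughout."
_TRIGGER_SENTENCE = "Enrolment additionally covered {trigger} cases."
_DISTRACTOR_ABSTRACTS = (
    "This manuscript surveys agricultural irrigation beneath arid climates, "
    "relating soil moisture telemetry to harvest logistics.",
    "We document maritime freight scheduling along seasonal routes and its "
    "dependence on port congestion.",
    "The account profiles volcanic ash dispersal models calibrated against "
    "historic eruption plumes.",
)
_SAFE_KEYWORDS = ("municipal", "initiative", "longitudinal", "regional", "multi-site")
# Title vocabulary: token-disjoint from every query/filter term, and titles
# additionally carry an 8-hex code so distinct entries never approach the
# fuzzy-title dedup threshold.
_TITLE_WORDS = (
    "municipal", "ledger", "survey", "census", "archive", "bulletin",
    "chronicle", "register", "gazette", "almanac", "digest", "compendium",
)
_AUTHOR_POOL = (
    "Alvarez, Nadia", "Bergström, Ulf", "Crespo, José", "Dietrich, Hanna",
    "Eriksen, Mats", "Fontaine, Amélie", "Grieger, Paul", "Hooper, Lena",
)


def fixture_matrix() -> FoundationalSearchMatrix:
    """The bundled two-discipline (hms/uxg), PDICOS-shaped fixture matrix."""
    text = resources.files("cris").joinpath("data/fixture_matrix.yaml").read_text("utf-8")
    return load_matrix(text)


def default_filter_groups() -> list[FilterGroup]:
    """The three screening term groups used by the synthetic study corpus:
    child-related, disease-related and computer-science terms."""
    return load_filter_groups(
        [
            {
                "name": "child-related",
                "terms": ["child*", "toddler*", "girl", "boy",
                          "adolescent*", "pediatric*", "preschool*"],
            },
            {
                "name": "disease-related",
                "terms": ["parkinson*", "dementia", "alzheimer*", "stroke",
                          "osteoporo*", "sclerosis", "arthrit*"],
            },
            {
                "name": "computer-science",
                "terms": ["compiler*", "bytecode", "cryptograph*",
                          "network packet", "sorting algorithm"],
            },
        ]
    )


@dataclass(frozen=True)
class CorpusSpec:
    """Recipe for one synthetic multi-database corpus."""

    seed: int
    matrix: FoundationalSearchMatrix
    segment_counts: dict  # label (discipline id | expert_overlap | golden_gap) -> count
    duplicate_count: int = 0
    review_count: int = 0
    book_count: int = 0
    distractor_count: int = 0
    databases: tuple[str, ...] = DATABASES

    def __post_init__(self) -> None:
        counts = dict(self.segment_counts)
        if any(c < 0 for c in counts.values()):
            raise SpecError("segment counts must be non-negative")
        for n in (self.duplicate_count, self.review_count, self.book_count,
                  self.distractor_count):
            if n < 0:
                raise SpecError("corpus counts must be non-negative")
        total = sum(counts.values())
        if self.duplicate_count > total:
            raise SpecError(
                "cannot plant more duplicates than planted segment entries"
            )
        object.__setattr__(self, "segment_counts", counts)


@dataclass
class GroundTruth:
    """Planted structure of a generated corpus, re-derivable by matching."""

    labels: dict = field(default_factory=dict)  # entry id -> segment label
    duplicates: dict = field(default_factory=dict)  # id -> [variant ids]
    alignment_excluded: dict = field(default_factory=dict)  # id -> rule
    filter_stage: dict = field(default_factory=dict)  # id -> filter name
    distractors: tuple = ()

    @property
    def segment_counts(self) -> dict:
        counts: dict = {}
        for label in self.labels.values():
            counts[label] = counts.get(label, 0) + 1
        return counts

    def expected_label(self, entry_id: str):
        """Planted label of an entry or of any of its duplicate variants."""
        if entry_id in self.labels:
            return self.labels[entry_id]
        for original, copies in self.duplicates.items():
            if entry_id in copies:
                return self.labels[original]
        return None


# ---------------------------------------------------------------------------
# term selection per planted segment


def _expert_cell(matrix, cat, discipline):
    return matrix.cells.get((cat.id, discipline, matrix.own_perspective(discipline)))


def _general_cells(matrix, cat):
    cells = []
    for d in cat.discipline_rows:
        own = matrix.own_perspective(d)
        for p in matrix.perspectives:
            if p == own:
                continue
            ts = matrix.cells.get((cat.id, d, p))
            if ts:
                cells.append(ts)
    return cells


def _segment_terms(matrix, label, rng) -> list[str]:
    """One term per category in the voice the planted segment requires."""
    disciplines = matrix.disciplines
    surfaces = []
    for cat in matrix.categories:
        if label == GOLDEN_GAP:
            cells = _general_cells(matrix, cat)
            if not cells:
                raise SpecError(
                    f"category {cat.id!r} has no general-perspective terms; "
                    "golden-gap entries are unrealizable"
                )
            ts = rng.choice(cells)
            surfaces.append(rng.choice(ts.terms).surface)
        elif label == EXPERT_OVERLAP:
            for d in disciplines:
                ts = _expert_cell(matrix, cat, d)
                if not ts:
                    raise SpecError(
                        f"cell ({cat.id!r}, {d!r}, own perspective) is empty; "
                        "expert-overlap entries are unrealizable"
                    )
                surfaces.append(rng.choice(ts.terms).surface)
        else:  # discipline-specific
            ts = _expert_cell(matrix, cat, label)
            if not ts:
                raise SpecError(
                    f"cell ({cat.id!r}, {label!r}, own perspective) is empty; "
                    f"{label}-specific entries are unrealizable"
                )
            surfaces.append(rng.choice(ts.terms).surface)
    return surfaces


def _planted_abstract(surfaces, rng) -> str:
    listing = ", ".join(surfaces[:-1]) + f" and {surfaces[-1]}" if len(surfaces) > 1 else surfaces[0]
    return rng.choice(_OPENERS) + " " + _TERM_SENTENCE.format(terms=listing)


def _base_entry(i: int, rng, source: str, title: str, abstract: str,
                entry_type: str = "article") -> BibEntry:
    return BibEntry(
        id=f"e{i:04d}{rng.randrange(16**4):04x}",
        entry_type=entry_type,
        title=title,
        abstract=abstract,
        keywords=tuple(rng.sample(_SAFE_KEYWORDS, 2)),
        authors=tuple(rng.sample(_AUTHOR_POOL, 2)),
        year=rng.randint(2006, 2024),
        doi=f"10.9999/synth.{i:05d}.{rng.randrange(16**4):04x}",
        source_databases=(source,),
    )


def _title(rng, prefix: str = "") -> str:
    words = " ".join(rng.sample(_TITLE_WORDS, 3))
    code = f"{rng.randrange(16**8):08x}"
    return f"{prefix}{words} {code}".strip().capitalize()


def _cosmetic_variant(title: str, rng) -> str:
    """Punctuation/casing variant whose normalized title is unchanged."""
    choice = rng.randrange(3)
    if choice == 0:
        return title.upper()
    if choice == 1:
        return title.replace(":", " -") + "."
    return title.title()


def generate_corpus(spec: CorpusSpec) -> tuple[dict[str, str], GroundTruth]:
    """Emit per-pseudo-database BibTeX documents with planted segments,
    duplicates, review/book records and distractors.

    Raises :class:`SpecError`, naming the offending cell, if a requested
    segment cannot be realized from the matrix vocabulary.
    """
    rng = random.Random(spec.seed)
    suite = build_query_suite(spec.matrix)
    truth = GroundTruth()
    entries: list[tuple[str, BibEntry]] = []  # (database, entry)
    i = 0

    planted: list[BibEntry] = []
    for label, count in spec.segment_counts.items():
        if label not in (EXPERT_OVERLAP, GOLDEN_GAP) and label not in spec.matrix.disciplines:
            raise SpecError(f"unknown segment label {label!r}")
        for _ in range(count):
            surfaces = _segment_terms(spec.matrix, label, rng)
            title = _title(rng, "Supervised observations: ")
            entry = _base_entry(i, rng, "", title, _planted_abstract(surfaces, rng))
            truth.labels[entry.id] = label
            planted.append(entry)
            i += 1

    # distribute planted entries over the pseudo-databases
    for entry in planted:
        db = rng.choice(spec.databases)
        entry.source_databases = (db,)
        entries.append((db, entry))

    # cross-database duplicates with cosmetic title variants
    if spec.duplicate_count and len(spec.databases) < 2:
        raise SpecError("duplicates need at least two pseudo-databases")
    for original in rng.sample(planted, spec.duplicate_count):
        other = rng.choice(
            [db for db in spec.databases if db != original.source_databases[0]]
        )
        copy = BibEntry(
            id=original.id + "d",
            entry_type=original.entry_type,
            title=_cosmetic_variant(original.title, rng),
            abstract=original.abstract,
            keywords=original.keywords,
            authors=original.authors,
            year=original.year,
            doi=original.doi,
            source_databases=(other,),
        )
        truth.duplicates.setdefault(original.id, []).append(copy.id)
        entries.append((other, copy))

    for _ in range(spec.review_count):
        title = _title(rng, "A retrospective review: ")
        entry = _base_entry(i, rng, rng.choice(spec.databases), title,
                            rng.choice(_DISTRACTOR_ABSTRACTS))
        truth.alignment_excluded[entry.id] = "title-review"
        entries.append((entry.source_databases[0], entry))
        i += 1
    for _ in range(spec.book_count):
        title = _title(rng, "Handbook: ")
        entry = _base_entry(i, rng, rng.choice(spec.databases), title,
                            rng.choice(_DISTRACTOR_ABSTRACTS), entry_type="book")
        truth.alignment_excluded[entry.id] = "book-type"
        entries.append((entry.source_databases[0], entry))
        i += 1
    distractor_ids = []
    for _ in range(spec.distractor_count):
        title = _title(rng, "Unrelated notes: ")
        entry = _base_entry(i, rng, rng.choice(spec.databases), title,
                            rng.choice(_DISTRACTOR_ABSTRACTS))
        distractor_ids.append(entry.id)
        entries.append((entry.source_databases[0], entry))
        i += 1
    truth.distractors = tuple(distractor_ids)

    _verify_planted(planted, suite, truth)

    documents: dict[str, str] = {}
    for db in spec.databases:
        db_entries = [e for d, e in entries if d == db]
        if db_entries:
            documents[db] = write_bibtex(db_entries)
    return documents, truth


def _verify_planted(planted, suite, truth) -> None:
    """Ground truth must be re-derivable from the emitted text."""
    try:
        recovered = classify_segments(planted, suite)
    except InputError as exc:
        raise SpecError(f"a planted entry does not match the full query: {exc}") from exc
    mismatches = {
        eid: (truth.labels[eid], got)
        for eid, got in recovered.items()
        if truth.labels[eid] != got
    }
    if mismatches:
        raise SpecError(
            f"planted labels not reproduced by matching: {mismatches} "
            "(fixture vocabulary is not disjoint enough)"
        )


def generate_screening_corpus(
    total: int,
    stage_removals: list[int],
    seed: int,
    filters: list[FilterGroup] | None = None,
) -> tuple[str, GroundTruth]:
    """One BibTeX document of ``total`` entries where exactly
    ``stage_removals[k]`` entries carry a stage-*k* trigger term (and no
    other stage's), and the remainder carry none.
    """
    filters = default_filter_groups() if filters is None else list(filters)
    removals = list(stage_removals)
    if len(removals) > len(filters):
        raise SpecError(
            f"{len(removals)} stage removals but only {len(filters)} filters"
        )
    if any(r < 0 for r in removals):
        raise SpecError("stage removals must be non-negative")
    if sum(removals) > total:
        raise SpecError(
            f"stage removals {removals} oversubscribe the corpus total {total}"
        )
    rng = random.Random(seed)
    roles: list[int] = []  # filter index, or -1 for a clean entry
    for k, r in enumerate(removals):
        roles.extend([k] * r)
    roles.extend([-1] * (total - len(roles)))
    rng.shuffle(roles)

    truth = GroundTruth()
    entries = []
    for i, role in enumerate(roles):
        abstract = rng.choice(_DISTRACTOR_ABSTRACTS)
        if role >= 0:
            group = filters[role]
            term = rng.choice(group.terms)
            abstract += " " + _TRIGGER_SENTENCE.format(trigger=term.surface)
            truth.filter_stage[f"s{i:05d}"] = group.name
        entry = _base_entry(i, rng, "screening",
                            f"Screening entry {i:04d}", abstract)
        entry.id = f"s{i:05d}"
        entries.append(entry)

    for entry in entries:
        expected = truth.filter_stage.get(entry.id)
        for group in filters:
            hit = bool(group.matches(entry))
            if hit != (group.name == expected):
                raise SpecError(
                    f"planted trigger structure violated for {entry.id!r} "
                    f"at filter {group.name!r}"
                )
    return write_bibtex(entries), truth


# ---------------------------------------------------------------------------
# study-scale recipes


def composition_study_spec(seed: int) -> CorpusSpec:
    """The composition study conditions: a deduplicated base of 57 entries
    split 24 (hms) / 16 (uxg) / 11 (expert overlap) / 6 (golden gaps), with
    cross-database duplicates and review/book records layered on top."""
    return CorpusSpec(
        seed=seed,
        matrix=fixture_matrix(),
        segment_counts={"hms": 24, "uxg": 16, EXPERT_OVERLAP: 11, GOLDEN_GAP: 6},
        duplicate_count=8,
        review_count=3,
        book_count=2,
        distractor_count=10,
    )


#: Screening study conditions: 1,896 unfiltered entries reduced by the three
#: term-group filters in stages of 283, 783 and 37 exclusions.
SCREENING_TOTAL = 1896
SCREENING_STAGE_REMOVALS = (283, 783, 37)
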