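"""The Foundational Search Matrix (FSM) and database dialect profiles.

The FSM is the central planning artifact of a cross-disciplinary literature
search: a grid of search-term sets indexed by scope category (the PICO-style
elements of the unified research question), discipline (the subcategory each
discipline derives from a category) and perspective (whose viewpoint supplied
the terms).  The cell ``(category, discipline d, perspective d)`` holds
discipline *d*'s own expert vocabulary for its subcategory; cells with a
foreign perspective hold the more general, external-view vocabulary.  All
search strings are generated from this grid.

A :class:`DatabaseProfile` captures what differs between bibliographic
databases: field tags, wildcard and phrase syntax, operator casing, and
controlled-vocabulary terms to merge into specific cells before query
generation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from ._text import fold_diacritics, tokenize
from .errors import (
    CellReferenceError,
    ConfigParseError,
    MatrixValidationError,
    UnsupportedShapeError,
)

logger = logging.getLogger(__name__)

#: Canonical order of searchable metadata fields.
FIELDS = ("title", "abstract", "keywords")
DEFAULT_SCOPE = frozenset(FIELDS)

MATCH_MODES = ("word", "phrase", "prefix")


@dataclass(frozen=True)
class Term:
    """One atomic member of a search term set.

    ``match_mode`` stores matching *semantics*; database dialects render the
    corresponding *syntax* (phrase delimiters, truncation wildcard).
    """

    surface: str
    match_mode: str = "word"
    field_scope: frozenset = DEFAULT_SCOPE

    def __post_init__(self) -> None:
        surface = self.surface.strip()
        if not surface:
            raise MatrixValidationError("term surface is empty after trimming")
        object.__setattr__(self, "surface", surface)
        if self.match_mode not in MATCH_MODES:
            raise MatrixValidationError(
                f"unknown match_mode {self.match_mode!r} for term {surface!r}"
            )
        if self.match_mode == "prefix" and any(ch.isspace() for ch in surface):
            raise MatrixValidationError(
                f"prefix term {surface!r} may not contain whitespace"
            )
        scope = frozenset(self.field_scope)
        if not scope or not scope.issubset(DEFAULT_SCOPE):
            raise MatrixValidationError(
                f"field_scope {sorted(self.field_scope)!r} must be a non-empty "
                f"subset of {FIELDS}"
            )
        object.__setattr__(self, "field_scope", scope)
        if self.match_mode == "word" and len(self.tokens) != 1:
            raise MatrixValidationError(
                f"word-mode term {surface!r} must be a single token "
                "(use phrase mode for multi-word terms)"
            )

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(tokenize(self.surface))

    @property
    def key(self) -> str:
        """Collapse key: folded, lowercased surface."""
        return fold_diacritics(self.surface).lower()


def term_from_spec(spec) -> Term:
    """Build a Term from its config representation.

    Plain strings use compact conventions: a trailing ``*`` declares a
    prefix (truncation) term, internal whitespace declares a phrase,
    anything else is a whole word.  A mapping ``{term, mode, fields}``
    states everything explicitly.
    """
    if isinstance(spec, str):
        s = spec.strip()
        if s.endswith("*"):
            return Term(s[:-1], "prefix")
        if any(ch.isspace() for ch in s):
            return Term(s, "phrase")
        return Term(s, "word")
    if isinstance(spec, Mapping):
        surface = spec.get("term") or spec.get("surface")
        if surface is None:
            raise ConfigParseError(f"term mapping {spec!r} lacks a 'term' key")
        mode = spec.get("mode")
        if mode is None:
            term = term_from_spec(str(surface))
        else:
            term = Term(str(surface), str(mode))
        fields_ = spec.get("fields")
        if fields_ is not None:
            term = replace(term, field_scope=frozenset(str(f) for f in fields_))
        return term
    raise ConfigParseError(f"cannot interpret term spec {spec!r}")


def term_to_spec(term: Term):
    """Inverse of :func:`term_from_spec` (compact string when unambiguous)."""
    if term.field_scope == DEFAULT_SCOPE:
        if term.match_mode == "prefix":
            return term.surface + "*"
        if term.match_mode == "phrase" and " " in term.surface:
            return term.surface
        if term.match_mode == "word" and not term.surface.endswith("*"):
            return term.surface
    spec = {"term": term.surface, "mode": term.match_mode}
    if term.field_scope != DEFAULT_SCOPE:
        spec["fields"] = [f for f in FIELDS if f in term.field_scope]
    return spec


@dataclass(frozen=True)
class TermSet:
    """The term set of one (category, discipline, perspective) cell."""

    category_id: str
    discipline_id: str
    perspective_id: str
    terms: tuple[Term, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", _collapse_duplicates(self.terms, self.cell))

    @property
    def cell(self) -> tuple[str, str, str]:
        return (self.category_id, self.discipline_id, self.perspective_id)

    def __bool__(self) -> bool:
        return bool(self.terms)


def _collapse_duplicates(terms: Iterable[Term], cell) -> tuple[Term, ...]:
    seen: dict[str, Term] = {}
    for term in terms:
        if term.key in seen:
            logger.warning("duplicate term %r collapsed in cell %s", term.surface, cell)
            continue
        seen[term.key] = term
    return tuple(seen.values())


@dataclass(frozen=True)
class Category:
    """A scope element (P, D, I, C, O, S, ...) with its per-discipline rows."""

    id: str
    label: str
    discipline_rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.discipline_rows:
            raise MatrixValidationError(f"category {self.id!r} has no discipline rows")
        if len(set(self.discipline_rows)) != len(self.discipline_rows):
            raise MatrixValidationError(
                f"category {self.id!r} repeats a discipline row"
            )


@dataclass(frozen=True)
class FoundationalSearchMatrix:
    """Category × discipline × perspective grid of search term sets."""

    name: str
    categories: tuple[Category, ...]
    perspectives: tuple[str, ...]
    cells: Mapping[tuple[str, str, str], TermSet]

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", dict(self.cells))
        self.validate()

    # -- structure -------------------------------------------------------

    @property
    def disciplines(self) -> tuple[str, ...]:
        """Global discipline order: first appearance across category rows."""
        seen: dict[str, None] = {}
        for cat in self.categories:
            for d in cat.discipline_rows:
                seen.setdefault(d)
        return tuple(seen)

    def own_perspective(self, discipline: str) -> str:
        """The perspective aligned with a discipline (positional pairing)."""
        disciplines = self.disciplines
        if discipline not in disciplines:
            raise CellReferenceError(f"unknown discipline {discipline!r}")
        idx = disciplines.index(discipline)
        if idx < len(self.perspectives):
            return self.perspectives[idx]
        raise UnsupportedShapeError(
            f"no perspective aligned with discipline {discipline!r}: "
            f"{len(self.perspectives)} perspectives for "
            f"{len(disciplines)} disciplines"
        )

    def category(self, category_id: str) -> Category:
        for cat in self.categories:
            if cat.id == category_id:
                return cat
        raise CellReferenceError(f"unknown category {category_id!r}")

    def cell(self, category_id: str, discipline_id: str, perspective_id: str) -> TermSet:
        key = (category_id, discipline_id, perspective_id)
        try:
            return self.cells[key]
        except KeyError:
            raise CellReferenceError(f"no cell {key!r} in matrix {self.name!r}") from None

    def validate(self) -> None:
        """Every (category, discipline) pair must be searchable somehow."""
        if not self.categories:
            raise MatrixValidationError("matrix has no categories")
        labels = [c.label for c in self.categories]
        if len(set(labels)) != len(labels):
            raise MatrixValidationError("category labels are not unique")
        for cat in self.categories:
            for disc in cat.discipline_rows:
                cells = [
                    self.cells.get((cat.id, disc, p)) for p in self.perspectives
                ]
                if not any(cells):
                    raise MatrixValidationError(
                        f"category {cat.id!r}, discipline {disc!r} has no "
                        "non-empty term set in any perspective"
                    )
        for key in self.cells:
            cat_id, disc, persp = key
            cat = self.category(cat_id)
            if disc not in cat.discipline_rows:
                raise MatrixValidationError(
                    f"cell {key!r} references a discipline outside its category rows"
                )
            if persp not in self.perspectives:
                raise MatrixValidationError(
                    f"cell {key!r} references an undeclared perspective"
                )


# ---------------------------------------------------------------------------
# loading / serialization


def _load_yaml(source) -> dict:
    if isinstance(source, Mapping):
        return dict(source)
    text = source
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and source.endswith((".yaml", ".yml", ".json"))
    ):
        text = Path(source).read_text(encoding="utf-8")
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigParseError(f"malformed document{line}: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise ConfigParseError("document root must be a mapping")
    return dict(doc)


def load_matrix(source) -> FoundationalSearchMatrix:
    """Load a foundational search matrix from YAML/JSON (path, text or dict).

    Document shape::

        name: example
        perspectives: [hms, uxg]
        categories:
          - id: population
            label: P
            rows:
              hms: {hms: [octogenarian, geriatr*], uxg: [older adults]}
              uxg: {uxg: [playtester*], hms: [players]}
    """
    doc = _load_yaml(source)
    perspectives = tuple(str(p) for p in doc.get("perspectives", ()))
    if not perspectives:
        raise ConfigParseError("matrix document declares no perspectives")
    categories = []
    cells: dict[tuple[str, str, str], TermSet] = {}
    for cat_doc in doc.get("categories", ()):
        cat_id = str(cat_doc["id"])
        label = str(cat_doc.get("label", cat_id))
        rows = cat_doc.get("rows") or {}
        if not rows:
            raise ConfigParseError(f"category {cat_id!r} declares no discipline rows")
        categories.append(Category(cat_id, label, tuple(str(d) for d in rows)))
        for disc, per_persp in rows.items():
            for persp, term_specs in (per_persp or {}).items():
                if str(persp) not in perspectives:
                    raise ConfigParseError(
                        f"category {cat_id!r} row {disc!r} uses undeclared "
                        f"perspective {persp!r}"
                    )
                terms = tuple(term_from_spec(t) for t in (term_specs or ()))
                key = (cat_id, str(disc), str(persp))
                cells[key] = TermSet(*key, terms)
    declared = doc.get("disciplines")
    matrix = FoundationalSearchMatrix(
        name=str(doc.get("name", "matrix")),
        categories=tuple(categories),
        perspectives=perspectives,
        cells=cells,
    )
    if declared is not None:
        declared = tuple(str(d) for d in declared)
        if set(declared) != set(matrix.disciplines):
            raise ConfigParseError(
                f"declared disciplines {declared!r} disagree with category rows "
                f"{matrix.disciplines!r}"
            )
    return matrix


def matrix_to_dict(matrix: FoundationalSearchMatrix) -> dict:
    doc = {
        "name": matrix.name,
        "disciplines": list(matrix.disciplines),
        "perspectives": list(matrix.perspectives),
        "categories": [],
    }
    for cat in matrix.categories:
        rows = {}
        for disc in cat.discipline_rows:
            per_persp = {}
            for persp in matrix.perspectives:
                ts = matrix.cells.get((cat.id, disc, persp))
                if ts is not None:
                    per_persp[persp] = [term_to_spec(t) for t in ts.terms]
            rows[disc] = per_persp
        doc["categories"].append({"id": cat.id, "label": cat.label, "rows": rows})
    return doc


def serialize_matrix(matrix: FoundationalSearchMatrix) -> str:
    """YAML serialization; ``load_matrix`` of the output is the identity."""
    return yaml.safe_dump(matrix_to_dict(matrix), sort_keys=False, allow_unicode=True)


# ---------------------------------------------------------------------------
# database profiles


@dataclass(frozen=True)
class DatabaseProfile:
    """Rendering dialect + controlled-vocabulary additions for one database."""

    name: str
    and_token: str = "AND"
    or_token: str = "OR"
    wildcard_symbol: str = "*"
    phrase_delimiters: tuple[str, str] = ('"', '"')
    field_tags: Mapping[str, str] = field(default_factory=dict)
    additions: Mapping[tuple[str, str, str], tuple[Term, ...]] = field(default_factory=dict)
    max_query_length: int | None = None

    def __post_init__(self) -> None:
        if not self.and_token or not self.or_token:
            raise ConfigParseError(f"profile {self.name!r}: empty Boolean token")
        object.__setattr__(self, "field_tags", dict(self.field_tags))
        object.__setattr__(
            self,
            "additions",
            {k: tuple(v) for k, v in dict(self.additions).items()},
        )


def load_profile(source) -> DatabaseProfile:
    """Load a database dialect profile from YAML/JSON (path, text or dict)."""
    doc = _load_yaml(source)
    additions: dict[tuple[str, str, str], tuple[Term, ...]] = {}
    for add in doc.get("additions", ()):
        key = (str(add["category"]), str(add["discipline"]), str(add["perspective"]))
        additions[key] = tuple(term_from_spec(t) for t in add.get("terms", ()))
    delims = doc.get("phrase_delimiters", ['"', '"'])
    return DatabaseProfile(
        name=str(doc.get("name", "unnamed")),
        and_token=str(doc.get("and_token", "AND")),
        or_token=str(doc.get("or_token", "OR")),
        wildcard_symbol=str(doc.get("wildcard", doc.get("wildcard_symbol", "*"))),
        phrase_delimiters=(str(delims[0]), str(delims[1])),
        field_tags={str(k): str(v) for k, v in (doc.get("field_tags") or {}).items()},
        additions=additions,
        max_query_length=doc.get("max_query_length"),
    )


BUILTIN_PROFILES = ("pubmed-like", "wos-like", "acm-like", "generic")


def builtin_profile(name: str) -> DatabaseProfile:
    """One of the bundled example dialects (:data:`BUILTIN_PROFILES`)."""
    if name not in BUILTIN_PROFILES:
        raise CellReferenceError(
            f"unknown builtin profile {name!r}; available: {BUILTIN_PROFILES}"
        )
    text = (
        resources.files("cris").joinpath(f"data/profiles/{name}.yaml").read_text("utf-8")
    )
    return load_profile(text)


# ---------------------------------------------------------------------------
# operations


def specialize_matrix(
    matrix: FoundationalSearchMatrix, profile: DatabaseProfile
) -> FoundationalSearchMatrix:
    """Merge a profile's controlled-vocabulary terms into the matrix cells.

    Pure and idempotent: the input is untouched, every input term is kept,
    and duplicate additions collapse.
    """
    for key in profile.additions:
        if key not in matrix.cells:
            raise CellReferenceError(
                f"profile {profile.name!r} adds terms to unknown cell {key!r}"
            )
    new_cells = {}
    for key, ts in matrix.cells.items():
        extra = profile.additions.get(key, ())
        new_cells[key] = TermSet(*key, tuple(ts.terms) + tuple(extra))
    return FoundationalSearchMatrix(
        name=matrix.name,
        categories=matrix.categories,
        perspectives=matrix.perspectives,
        cells=new_cells,
    )


#: Segment labels of the 2×2 category view.
SEGMENT_DISCIPLINE_SPECIFIC = "discipline_specific"
SEGMENT_EXPERT_OVERLAP = "expert_overlap"
SEGMENT_GENERALISTIC = "generalistic"


def category_term_segments(
    matrix: FoundationalSearchMatrix, category_id: str
) -> dict[str, tuple[TermSet, TermSet]]:
    """The four term-depth segments of a 2-discipline, 2-perspective category.

    Returns the cell pairings used to review whether a category's vocabulary
    is balanced: each discipline's own row across both perspectives
    (discipline-specific), both rows in their own expert voice (expert
    overlap), and both rows in the external voice (generalistic).  Each of
    the four cells participates in exactly two pairings.
    """
    cat = matrix.category(category_id)
    disciplines = matrix.disciplines
    if len(cat.discipline_rows) != 2 or len(matrix.perspectives) != 2:
        raise UnsupportedShapeError(
            "category_term_segments is defined for exactly 2 disciplines and "
            "2 perspectives; invoke per discipline/perspective pair instead"
        )
    d1, d2 = cat.discipline_rows
    p1 = matrix.own_perspective(d1) if d1 in disciplines else matrix.perspectives[0]
    p2 = matrix.own_perspective(d2) if d2 in disciplines else matrix.perspectives[1]

    def cell(d, p):
        return matrix.cells.get((category_id, d, p), TermSet(category_id, d, p))

    return {
        f"{SEGMENT_DISCIPLINE_SPECIFIC}:{d1}": (cell(d1, p1), cell(d1, p2)),
        f"{SEGMENT_DISCIPLINE_SPECIFIC}:{d2}": (cell(d2, p1), cell(d2, p2)),
        SEGMENT_EXPERT_OVERLAP: (cell(d1, p1), cell(d2, p2)),
        SEGMENT_GENERALISTIC: (cell(d1, p2), cell(d2, p1)),
    }
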