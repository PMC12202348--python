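"""Boolean query construction, dialect rendering and local evaluation.

The cross-disciplinary search string for one database is a conjunction over
scope categories of disjunctions over every term of every (discipline,
perspective) cell of that category: an entry is retrieved iff every category
is represented by at least one of its terms, in any voice.  A single
discipline's expert search keeps only that discipline's own rows viewed from
its own perspective.  Rendering turns the same AST into database-specific
syntax; :func:`evaluate_query` applies it locally to normalized BibTeX
records, which stands in for database retrieval when classifying result
segments and validating golden bullets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

from .bibio import BibEntry
from .errors import CellReferenceError, InputError
from .matrix import (
    FIELDS,
    DatabaseProfile,
    FoundationalSearchMatrix,
    Term,
    specialize_matrix,
    term_from_spec,
    term_to_spec,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QueryNode:
    """Node of a Boolean query AST (``and`` / ``or`` / ``leaf``).

    ``label`` optionally names the matrix category a conjunct covers, which
    lets golden-bullet reports point at the failing scope element.
    """

    kind: str
    children: tuple["QueryNode", ...] = ()
    term: Term | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind == "leaf":
            if self.term is None or self.children:
                raise InputError("leaf nodes carry a term and no children")
        elif self.kind in ("and", "or"):
            if not self.children or self.term is not None:
                raise InputError(f"{self.kind} nodes need >= 1 child and no term")
        else:
            raise InputError(f"unknown node kind {self.kind!r}")

    def leaves(self) -> list["QueryNode"]:
        if self.kind == "leaf":
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]


def Leaf(term: Term) -> QueryNode:
    return QueryNode("leaf", term=term)


def And(children, label: str = "") -> QueryNode:
    return QueryNode("and", children=tuple(children), label=label)


def Or(children, label: str = "") -> QueryNode:
    return QueryNode("or", children=tuple(children), label=label)


# ---------------------------------------------------------------------------
# construction from a matrix


def _category_leaves(matrix, category, cells) -> list[QueryNode]:
    """Leaves of one category block in canonical order, duplicates collapsed."""
    seen: dict[tuple, None] = {}
    leaves = []
    for key in cells:
        ts = matrix.cells.get(key)
        if ts is None:
            continue
        for term in ts.terms:
            ident = (term.key, term.match_mode, term.field_scope)
            if ident in seen:
                continue
            seen[ident] = None
            leaves.append(Leaf(term))
    return leaves


def build_full_query(matrix: FoundationalSearchMatrix) -> QueryNode:
    """The full cross-disciplinary query: AND over categories of OR blocks
    spanning every discipline row and every perspective."""
    matrix.validate()
    conjuncts = []
    for cat in matrix.categories:
        cells = [
            (cat.id, d, p) for d in cat.discipline_rows for p in matrix.perspectives
        ]
        leaves = _category_leaves(matrix, cat, cells)
        conjuncts.append(Or(leaves, label=cat.id))
    return _simplify(And(conjuncts))


def build_discipline_query(
    matrix: FoundationalSearchMatrix,
    discipline: str,
    include_all_perspectives: bool = False,
) -> QueryNode:
    """One discipline's independent expert search: its own subcategory rows,
    viewed from its own perspective (optionally from every perspective)."""
    if discipline not in matrix.disciplines:
        raise CellReferenceError(f"unknown discipline {discipline!r}")
    own = matrix.own_perspective(discipline)
    perspectives = matrix.perspectives if include_all_perspectives else (own,)
    conjuncts = []
    for cat in matrix.categories:
        if discipline not in cat.discipline_rows:
            continue
        cells = [(cat.id, discipline, p) for p in perspectives]
        leaves = _category_leaves(matrix, cat, cells)
        if leaves:
            conjuncts.append(Or(leaves, label=cat.id))
    if not conjuncts:
        raise CellReferenceError(
            f"discipline {discipline!r} has no terms in any category"
        )
    return _simplify(And(conjuncts))


def _simplify(node: QueryNode) -> QueryNode:
    """Collapse single-child and/or nodes (keeps the degenerate-tree contract);
    a collapsed node passes its category label down if the child has none."""
    if node.kind == "leaf":
        return node
    children = tuple(_simplify(c) for c in node.children)
    if len(children) == 1:
        child = children[0]
        if node.label and not child.label:
            child = replace(child, label=node.label)
        return child
    return QueryNode(node.kind, children=children, label=node.label)


# ---------------------------------------------------------------------------
# rendering


def _render_token(term: Term, profile: DatabaseProfile) -> str:
    opening, closing = profile.phrase_delimiters
    surface = term.surface
    for delim in {opening, closing}:
        if delim and delim in surface:
            logger.warning(
                "term %r contains the phrase delimiter %r; escaping by removal",
                surface,
                delim,
            )
            surface = surface.replace(delim, "")
    if term.match_mode == "phrase":
        return f"{opening}{surface}{closing}"
    if term.match_mode == "prefix":
        return surface + profile.wildcard_symbol
    return surface


def _render_leaf(term: Term, profile: DatabaseProfile) -> str:
    token = _render_token(term, profile)
    variants = []
    for f in FIELDS:
        if f not in term.field_scope:
            continue
        template = profile.field_tags.get(f)
        variant = template.format(term=token) if template else token
        if variant not in variants:
            variants.append(variant)
    if len(variants) == 1:
        return variants[0]
    return "(" + f" {profile.or_token} ".join(variants) + ")"


def render_query(node: QueryNode, profile: DatabaseProfile) -> str:
    """Deterministic, fully parenthesized dialect rendering of an AST."""
    text = _render_node(node, profile)
    if profile.max_query_length and len(text) > profile.max_query_length:
        logger.warning(
            "rendered query for %s is %d characters, over the profile limit %d",
            profile.name,
            len(text),
            profile.max_query_length,
        )
    return text


def _render_node(node: QueryNode, profile: DatabaseProfile) -> str:
    if node.kind == "leaf":
        return _render_leaf(node.term, profile)
    token = profile.and_token if node.kind == "and" else profile.or_token
    inner = f" {token} ".join(_render_node(c, profile) for c in node.children)
    return f"({inner})"


# ---------------------------------------------------------------------------
# local evaluation


def match_fields(term: Term, entry: BibEntry, scope=None) -> list[tuple[str, str]]:
    """Fields of ``entry`` in which ``term`` matches, as (surface, field) pairs.

    word: whole-token equality; phrase: contiguous token run; prefix: token
    prefix.  Matching is per field, case-insensitive and diacritic-folded.
    """
    scope = term.field_scope if scope is None else scope
    needle = term.tokens
    hits = []
    for f in FIELDS:
        if f not in scope:
            continue
        tokens = entry.field_tokens(f)
        if not tokens or not needle:
            continue
        if term.match_mode == "word":
            matched = needle[0] in tokens
        elif term.match_mode == "prefix":
            matched = any(t.startswith(needle[0]) for t in tokens)
        else:
            k = len(needle)
            matched = any(
                tokens[i : i + k] == needle for i in range(len(tokens) - k + 1)
            )
        if matched:
            hits.append((term.surface, f))
    return hits


def term_matches(term: Term, entry: BibEntry, scope=None) -> bool:
    return bool(match_fields(term, entry, scope))


def evaluate_query(node: QueryNode, entry: BibEntry) -> bool:
    """Apply a query AST to one normalized record (pure; missing fields are
    empty text)."""
    if node.kind == "leaf":
        return term_matches(node.term, entry)
    if node.kind == "and":
        return all(evaluate_query(c, entry) for c in node.children)
    return any(evaluate_query(c, entry) for c in node.children)


# ---------------------------------------------------------------------------
# suites and golden bullets


@dataclass(frozen=True)
class QuerySuite:
    """The full CRIS query plus the per-discipline expert queries for one
    database."""

    full: QueryNode
    per_discipline: dict[str, QueryNode]
    database: str = "generic"


def build_query_suite(
    matrix: FoundationalSearchMatrix, profile: DatabaseProfile | None = None
) -> QuerySuite:
    """Specialize the matrix for a database (if a profile is given) and build
    the full + per-discipline queries."""
    specialized = specialize_matrix(matrix, profile) if profile else matrix
    return QuerySuite(
        full=build_full_query(specialized),
        per_discipline={
            d: build_discipline_query(specialized, d) for d in specialized.disciplines
        },
        database=profile.name if profile else "generic",
    )


@dataclass(frozen=True)
class GoldenBulletReport:
    """Which must-retrieve articles a search string captures."""

    database: str
    matched: tuple[str, ...]
    unmatched: tuple[tuple[str, str], ...]  # (entry id, failing category)

    @property
    def all_captured(self) -> bool:
        return not self.unmatched


def validate_golden_bullets(suite: QuerySuite, bullets) -> GoldenBulletReport:
    """Evaluate every golden bullet against the full query; unmatched bullets
    report the first category conjunct that failed."""
    bullets = list(bullets)
    if not bullets:
        raise InputError("cannot validate against an empty golden-bullet set")
    matched, unmatched = [], []
    conjuncts = (
        suite.full.children if suite.full.kind == "and" else (suite.full,)
    )
    for bullet in bullets:
        if evaluate_query(suite.full, bullet):
            matched.append(bullet.id)
            continue
        failing = ""
        for conjunct in conjuncts:
            if not evaluate_query(conjunct, bullet):
                failing = conjunct.label or "unlabelled-conjunct"
                break
        unmatched.append((bullet.id, failing))
    return GoldenBulletReport(suite.database, tuple(matched), tuple(unmatched))


# ---------------------------------------------------------------------------
# JSON (de)serialization for audit trails


def query_to_dict(node: QueryNode) -> dict:
    if node.kind == "leaf":
        spec = term_to_spec(node.term)
        return {"leaf": spec}
    doc = {node.kind: [query_to_dict(c) for c in node.children]}
    if node.label:
        doc["label"] = node.label
    return doc


def query_from_dict(doc: dict) -> QueryNode:
    if "leaf" in doc:
        return Leaf(term_from_spec(doc["leaf"]))
    kind = "and" if "and" in doc else "or"
    return QueryNode(
        kind,
        children=tuple(query_from_dict(c) for c in doc[kind]),
        label=doc.get("label", ""),
    )


def suite_to_json(suite: QuerySuite) -> str:
    return json.dumps(
        {
            "database": suite.database,
            "full": query_to_dict(suite.full),
            "per_discipline": {
                d: query_to_dict(q) for d, q in suite.per_discipline.items()
            },
        },
        indent=2,
    )


def suite_from_json(text: str) -> QuerySuite:
    doc = json.loads(text)
    return QuerySuite(
        full=query_from_dict(doc["full"]),
        per_discipline={
            d: query_from_dict(q) for d, q in doc["per_discipline"].items()
        },
        database=doc.get("database", "generic"),
    )
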