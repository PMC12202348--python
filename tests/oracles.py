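"""Independent oracles used to cross-check the implementation.

Everything here is deliberately written without reusing the package's
matching or rendering internals: a regex-based term matcher, a brute-force
set-algebra evaluator for full/discipline queries, and a recursive-descent
parser for the generic rendered dialect.
"""

from __future__ import annotations

import random
import re
import unicodedata

from cris.bibio import BibEntry
from cris.matrix import FoundationalSearchMatrix, Term, load_matrix


def _fold(text: str) -> str:
    decomposed = unicodedata.normalize("NFKD", text.lower())
    return "".join(c for c in decomposed if not unicodedata.combining(c))


def regex_term_match(term: Term, entry: BibEntry) -> bool:
    """Regex re-implementation of word/phrase/prefix matching."""
    parts = re.findall(r"[0-9a-z]+", _fold(term.surface))
    if not parts:
        return False
    if term.match_mode == "word":
        pattern = rf"(?<![0-9a-z]){re.escape(parts[0])}(?![0-9a-z])"
    elif term.match_mode == "prefix":
        pattern = rf"(?<![0-9a-z]){re.escape(parts[0])}"
    else:
        body = r"[^0-9a-z]+".join(re.escape(p) for p in parts)
        pattern = rf"(?<![0-9a-z]){body}(?![0-9a-z])"
    rx = re.compile(pattern)
    for field in ("title", "abstract", "keywords"):
        if field not in term.field_scope:
            continue
        if rx.search(_fold(entry.field_text(field))):
            return True
    return False


def brute_force_full_match(matrix: FoundationalSearchMatrix, entries):
    """Entries matched by the full query, by plain set algebra:
    intersection over categories of the union over all cell terms."""
    result = set(e.id for e in entries)
    for cat in matrix.categories:
        hits = set()
        for d in cat.discipline_rows:
            for p in matrix.perspectives:
                ts = matrix.cells.get((cat.id, d, p))
                if ts is None:
                    continue
                for term in ts.terms:
                    hits |= {e.id for e in entries if regex_term_match(term, e)}
        result &= hits
    return result


def brute_force_discipline_match(matrix, discipline, entries):
    result = set(e.id for e in entries)
    own = matrix.own_perspective(discipline)
    for cat in matrix.categories:
        if discipline not in cat.discipline_rows:
            continue
        ts = matrix.cells.get((cat.id, discipline, own))
        hits = set()
        if ts is not None:
            for term in ts.terms:
                hits |= {e.id for e in entries if regex_term_match(term, e)}
        result &= hits
    return result


# ---------------------------------------------------------------------------
# parser for the generic rendered dialect


class GenericDialectParser:
    """Recovers an AST from generic-dialect output: parenthesized AND/OR
    over bare words, '*'-truncated words and double-quoted phrases."""

    def __init__(self, text: str):
        self.tokens = re.findall(r'\(|\)|"[^"]*"|[^\s()]+', text)
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def parse(self):
        node = self._expr()
        assert self.peek() is None, f"trailing tokens at {self.pos}"
        return node

    def _expr(self):
        left = self._atom()
        items = [left]
        op = None
        while self.peek() in ("AND", "OR"):
            tok = self.tokens[self.pos]
            self.pos += 1
            assert op is None or op == tok, "mixed operators without parentheses"
            op = tok
            items.append(self._atom())
        if op is None:
            return left
        return (op.lower(), items)

    def _atom(self):
        tok = self.peek()
        assert tok is not None, "unexpected end of query"
        if tok == "(":
            self.pos += 1
            node = self._expr()
            assert self.peek() == ")", "unbalanced parenthesis"
            self.pos += 1
            return node
        self.pos += 1
        if tok.startswith('"') and tok.endswith('"'):
            return ("term", Term(tok[1:-1], "phrase"))
        if tok.endswith("*"):
            return ("term", Term(tok[:-1], "prefix"))
        return ("term", Term(tok, "word"))


def eval_parsed(node, entry: BibEntry) -> bool:
    kind = node[0]
    if kind == "term":
        return regex_term_match(node[1], entry)
    if kind == "and":
        return all(eval_parsed(c, entry) for c in node[1])
    return any(eval_parsed(c, entry) for c in node[1])


# ---------------------------------------------------------------------------
# random fixtures


_VOCAB = [
    "amble", "brisk", "canter", "dashpot", "ember", "flume", "gusset",
    "hollow", "inkle", "jetty", "kestrel", "lumen", "mantle", "nimbus",
    "osprey", "pylon", "quill", "rampart",
]


def random_matrix(rng: random.Random, n_categories=2) -> FoundationalSearchMatrix:
    """Small 2-discipline matrix over a random slice of an invented vocabulary."""
    words = rng.sample(_VOCAB, min(len(_VOCAB), 4 * n_categories + 4))
    it = iter(words)
    doc = {"name": "random", "perspectives": ["d1", "d2"], "categories": []}
    for c in range(n_categories):
        rows = {}
        for d in ("d1", "d2"):
            rows[d] = {p: [next(it)] for p in ("d1", "d2")}
        doc["categories"].append({"id": f"c{c}", "label": f"L{c}", "rows": rows})
    return load_matrix(doc)


def random_entries(rng: random.Random, vocab, n=30):
    entries = []
    for i in range(n):
        k = rng.randint(0, min(6, len(vocab)))
        words = rng.sample(list(vocab), k)
        entries.append(
            BibEntry(id=f"r{i}", title=f"entry {i}", abstract=" ".join(words))
        )
    return entries
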