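"""BibTeX reading and writing, and the normalized bibliographic record.

Database exports are exchanged as BibTeX, so this module implements a small
reader for the common entry syntax (``@type{key, field = {value}, ...}``
with brace- or quote-delimited values), folds LaTeX accent macros to their
Unicode characters, and normalizes records into :class:`BibEntry`.
``@comment``/``@preamble``/``@string`` blocks are skipped; a record that
cannot be parsed is skipped with a logged warning rather than aborting the
whole file.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path

from ._text import norm_title, tokenize
from .errors import ConfigParseError

logger = logging.getLogger(__name__)

# LaTeX accent macro -> combining character
_ACCENTS = {
    '"': "̈", "'": "́", "`": "̀", "^": "̂", "~": "̃",
    "=": "̄", ".": "̇", "u": "̆", "v": "̌", "H": "̋",
    "c": "̧", "k": "̨", "r": "̊", "b": "̱", "d": "̣",
}
_SYMBOLS = {
    r"\ss": "ß", r"\o": "ø", r"\O": "Ø", r"\l": "ł", r"\L": "Ł",
    r"\ae": "æ", r"\AE": "Æ", r"\oe": "œ", r"\OE": "Œ", r"\aa": "å",
    r"\AA": "Å", r"\i": "ı", r"\&": "&", r"\%": "%", r"\$": "$",
    r"\_": "_", r"\#": "#", r"--": "–", r"---": "—",
}
_ACCENT_RE = re.compile(
    r"\\([\"'`^~=.uvHckrbd])\s*(?:\{\\?([a-zA-Z])\}|\\?([a-zA-Z]))"
)


def delatex(value: str) -> str:
    """Fold LaTeX accent macros and braces to plain Unicode text."""

    def _accent(m: re.Match) -> str:
        mark = _ACCENTS[m.group(1)]
        base = m.group(2) or m.group(3)
        return unicodedata.normalize("NFC", base + mark)

    text = _ACCENT_RE.sub(_accent, value)
    for macro in sorted(_SYMBOLS, key=len, reverse=True):
        text = text.replace(macro, _SYMBOLS[macro])
    text = text.replace("{", "").replace("}", "")
    return re.sub(r"\s+", " ", text).strip()


@dataclass
class BibEntry:
    """A normalized bibliographic record with provenance."""

    id: str
    entry_type: str = "article"
    title: str = ""
    abstract: str = ""
    keywords: tuple[str, ...] = ()
    authors: tuple[str, ...] = ()
    year: int | None = None
    doi: str = ""
    source_databases: tuple[str, ...] = ()
    raw_fields: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._tokens: dict[str, tuple[str, ...]] = {}

    @property
    def norm_title(self) -> str:
        return norm_title(self.title)

    def field_text(self, name: str) -> str:
        if name == "title":
            return self.title
        if name == "abstract":
            return self.abstract
        if name == "keywords":
            return "; ".join(self.keywords)
        raise KeyError(name)

    def field_tokens(self, name: str) -> tuple[str, ...]:
        """Tokens of one searchable field, cached per entry."""
        if name not in self._tokens:
            self._tokens[name] = tuple(tokenize(self.field_text(name)))
        return self._tokens[name]


# ---------------------------------------------------------------------------
# reader


def _scan_value(text: str, pos: int) -> tuple[str, int]:
    """Read one field value starting at ``pos`` (brace, quote or bare)."""
    n = len(text)
    while pos < n and text[pos].isspace():
        pos += 1
    if pos >= n:
        raise ConfigParseError("unexpected end of file in field value")
    ch = text[pos]
    if ch == "{":
        depth, start = 1, pos + 1
        pos += 1
        while pos < n and depth:
            if text[pos] == "{":
                depth += 1
            elif text[pos] == "}":
                depth -= 1
            pos += 1
        if depth:
            raise ConfigParseError("unbalanced braces in field value")
        return text[start : pos - 1], pos
    if ch == '"':
        start = pos + 1
        pos += 1
        while pos < n and text[pos] != '"':
            pos += 1
        if pos >= n:
            raise ConfigParseError("unterminated quoted field value")
        return text[start:pos], pos + 1
    start = pos
    while pos < n and text[pos] not in ",}":
        pos += 1
    return text[start:pos].strip(), pos


def _parse_record(text: str, pos: int) -> tuple[str, str, dict, int]:
    """Parse one ``@type{key, ...}`` record; returns (type, key, fields, end)."""
    assert text[pos] == "@"
    m = re.compile(r"@\s*(\w+)\s*\{").match(text, pos)
    if m is None:
        raise ConfigParseError("malformed entry header")
    entry_type = m.group(1).lower()
    pos = m.end()
    m = re.compile(r"\s*([^,\s{}]+)\s*,").match(text, pos)
    if m is None:
        raise ConfigParseError("missing citation key")
    key = m.group(1)
    pos = m.end()
    fields: dict[str, str] = {}
    n = len(text)
    while pos < n:
        while pos < n and text[pos] in ", \t\r\n":
            pos += 1
        if pos < n and text[pos] == "}":
            return entry_type, key, fields, pos + 1
        m = re.compile(r"([\w-]+)\s*=").match(text, pos)
        if m is None:
            raise ConfigParseError(f"malformed field near offset {pos}")
        name = m.group(1).lower()
        value, pos = _scan_value(text, m.end())
        fields[name] = value
    raise ConfigParseError("unterminated record")


_SKIP_BLOCKS = ("comment", "preamble", "string")


def parse_bibtex_text(text: str, source: str = "") -> list[BibEntry]:
    """Parse BibTeX text into normalized entries.

    Unparseable records are skipped with a warning naming their offset;
    a document yielding zero records raises :class:`ConfigParseError`.
    """
    entries: list[BibEntry] = []
    pos = 0
    n = len(text)
    while True:
        pos = text.find("@", pos)
        if pos == -1 or pos >= n:
            break
        header = re.compile(r"@\s*(\w+)").match(text, pos)
        if header is not None and header.group(1).lower() in _SKIP_BLOCKS:
            pos = header.end()
            continue
        try:
            entry_type, key, fields, pos = _parse_record(text, pos)
        except ConfigParseError as exc:
            line = text.count("\n", 0, pos) + 1
            logger.warning("skipping unparseable record at line %d: %s", line, exc)
            nxt = text.find("@", pos + 1)
            if nxt == -1:
                break
            pos = nxt
            continue
        entries.append(_build_entry(entry_type, key, fields, source))
    if not entries:
        raise ConfigParseError(f"no BibTeX records parsed from {source or 'input'}")
    return entries


def parse_bibtex(path, source: str | None = None) -> list[BibEntry]:
    """Parse a ``.bib`` file; provenance defaults to the file stem."""
    p = Path(path)
    return parse_bibtex_text(p.read_text(encoding="utf-8"), source or p.stem)


def _build_entry(entry_type: str, key: str, fields: dict, source: str) -> BibEntry:
    year_text = fields.get("year", "")
    m = re.search(r"\d{4}", year_text)
    keywords = tuple(
        kw.strip()
        for kw in re.split(r"[;,]", delatex(fields.get("keywords", "")))
        if kw.strip()
    )
    authors = tuple(
        a.strip()
        for a in re.split(r"\s+and\s+", delatex(fields.get("author", "")))
        if a.strip()
    )
    return BibEntry(
        id=key,
        entry_type=entry_type,
        title=delatex(fields.get("title", "")),
        abstract=delatex(fields.get("abstract", "")),
        keywords=keywords,
        authors=authors,
        year=int(m.group()) if m else None,
        doi=fields.get("doi", "").strip(),
        source_databases=(source,) if source else (),
        raw_fields=dict(fields),
    )


# ---------------------------------------------------------------------------
# writer


def _bib_escape(value: str) -> str:
    return value.replace("{", "(").replace("}", ")")


def format_entry(entry: BibEntry) -> str:
    lines = [f"@{entry.entry_type}{{{entry.id},"]
    pairs = [("title", entry.title)]
    if entry.authors:
        pairs.append(("author", " and ".join(entry.authors)))
    if entry.year is not None:
        pairs.append(("year", str(entry.year)))
    if entry.abstract:
        pairs.append(("abstract", entry.abstract))
    if entry.keywords:
        pairs.append(("keywords", ", ".join(entry.keywords)))
    if entry.doi:
        pairs.append(("doi", entry.doi))
    for name, value in pairs:
        lines.append(f"  {name} = {{{_bib_escape(value)}}},")
    lines.append("}")
    return "\n".join(lines)


def write_bibtex(entries, path=None) -> str:
    """Serialize entries to BibTeX text (optionally writing a file)."""
    text = "\n\n".join(format_entry(e) for e in entries) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
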