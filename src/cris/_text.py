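"""Text normalization shared by query evaluation, screening and deduplication.

Tokenization mirrors the default indexing behaviour of the major
bibliographic databases: case-insensitive, diacritics folded to their base
characters, and tokens split on every non-alphanumeric character (so
hyphenated compounds like "exergame-based" yield two tokens).
"""

from __future__ import annotations

import re
import unicodedata

_TOKEN_RE = re.compile(r"[0-9a-z]+")


def fold_diacritics(text: str) -> str:
    """Strip combining marks: ``é`` -> ``e``, ``ö`` -> ``o``."""
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))


def tokenize(text: str) -> list[str]:
    """Lowercased, diacritic-folded alphanumeric tokens."""
    return _TOKEN_RE.findall(fold_diacritics(text).lower())


def norm_title(title: str) -> str:
    """Canonical title key: folded tokens joined by single spaces."""
    return " ".join(tokenize(title))
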