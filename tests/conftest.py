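import pytest

from cris.bibio import BibEntry
from cris.matrix import builtin_profile, load_matrix
from cris.synthetic import fixture_matrix

SMALL_MATRIX_DOC = """
name: two-by-two
disciplines: [alpha, beta]
perspectives: [alpha, beta]
categories:
  - id: cat1
    label: "1"
    rows:
      alpha:
        alpha: [anatomical, gait*]
        beta: [walking pattern]
      beta:
        beta: [avatar, playful*]
        alpha: [screen figure]
  - id: cat2
    label: "2"
    rows:
      alpha:
        alpha: [strength drills]
        beta: [exercise]
      beta:
        beta: [level design]
        alpha: [virtual world]
"""


def make_entry(eid="e1", title="", abstract="", keywords=(), **kwargs) -> BibEntry:
    return BibEntry(id=eid, title=title, abstract=abstract,
                    keywords=tuple(keywords), **kwargs)


@pytest.fixture
def small_matrix():
    return load_matrix(SMALL_MATRIX_DOC)


@pytest.fixture
def pdicos_matrix():
    return fixture_matrix()


@pytest.fixture
def generic_profile():
    return builtin_profile("generic")


@pytest.fixture
def pubmed_profile():
    return builtin_profile("pubmed-like")
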