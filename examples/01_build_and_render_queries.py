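"""Build the cross-disciplinary Boolean query from a search matrix and
render it in two database dialects.

The full query ANDs the scope categories and ORs, within each category,
every term of every discipline and perspective; a discipline query keeps
only that discipline's own expert cells.
"""

from cris import (
    build_query_suite,
    builtin_profile,
    fixture_matrix,
    render_query,
)

matrix = fixture_matrix()
print(f"matrix: {matrix.name} — categories "
      f"{[c.label for c in matrix.categories]}, disciplines {matrix.disciplines}")

suite = build_query_suite(matrix)
generic = builtin_profile("generic")
pubmed = builtin_profile("pubmed-like")

print("\nfull query (generic dialect):")
print(render_query(suite.full, generic))

print("\nhms expert query (generic dialect):")
print(render_query(suite.per_discipline["hms"], generic))

print("\nfirst 300 characters of the pubmed-like rendering, with field tags:")
print(render_query(suite.full, pubmed)[:300], "...")

# The full string is a relaxation of each expert string: anything an expert
# search retrieves, the cross-disciplinary search retrieves too.
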