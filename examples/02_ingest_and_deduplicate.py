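"""Simulate three database exports, then align them: parse the BibTeX,
merge cross-database duplicates and drop reviews/books.

The printed counts show the conservation bookkeeping: parsed = kept +
duplicates, and kept = aligned + excluded.
"""

from cris import (
    apply_alignment_exclusions,
    composition_study_spec,
    deduplicate,
    generate_corpus,
    parse_bibtex_text,
)

documents, truth = generate_corpus(composition_study_spec(seed=7))
entries = [e for db, text in documents.items() for e in parse_bibtex_text(text, db)]
print(f"parsed {len(entries)} records from {len(documents)} pseudo-databases")

kept, report = deduplicate(entries, source_priority=list(documents))
print(f"after deduplication: {len(kept)} kept, "
      f"{report.duplicate_count} duplicates merged")
example_kept, example_dups = next(iter(report.merged.items()))
print(f"  e.g. {example_kept} absorbed {example_dups}")

aligned, exclusions = apply_alignment_exclusions(kept)
print(f"after alignment exclusions: {len(aligned)} retained, "
      f"{len(exclusions)} removed "
      f"({sum(1 for r in exclusions if r.rule == 'title-review')} reviews, "
      f"{sum(1 for r in exclusions if r.rule == 'book-type')} books)")
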