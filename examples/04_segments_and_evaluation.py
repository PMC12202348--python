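"""Full evaluation: classify the retrieved set into discipline-specific,
expert-overlap and golden-gap segments, then compute composition shares,
relative sensitivity and the screening reduction.

True-positive counts are supplied by the caller (here, the study's own
screening outcome counts); the toolkit computes the ratios.
"""

from cris import (
    apply_alignment_exclusions,
    build_report,
    build_query_suite,
    composition_study_spec,
    deduplicate,
    evaluate_query,
    fixture_matrix,
    generate_corpus,
    parse_bibtex_text,
)

documents, _ = generate_corpus(composition_study_spec(seed=7))
entries = [e for db, text in documents.items() for e in parse_bibtex_text(text, db)]
kept, _ = deduplicate(entries, source_priority=list(documents))
aligned, _ = apply_alignment_exclusions(kept)

suite = build_query_suite(fixture_matrix())
retrieved = [e for e in aligned if evaluate_query(suite.full, e)]
print(f"retrieved set after alignment: {len(retrieved)} entries")

report = build_report(
    retrieved,
    suite,
    tp_cris=46,
    tp_comparisons={"expert_overlap_search": 11, "uxg_search": 16,
                    "hms_search": 24},
)
print(report.to_markdown())
# Shares are percents of the deduplicated base; relative sensitivity is the
# ratio of CRIS true positives to each comparison strategy's true positives.
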