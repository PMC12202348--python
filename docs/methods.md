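# Methods

## The search model

A cross-disciplinary search is planned in a foundational search matrix
(FSM): for every scope category (P, D, I, C, O, S-style elements of the
unified research question), every discipline derives a subcategory row, and
every row holds one term set per perspective. The cell
`(category, discipline d, perspective d)` is *d*'s expert vocabulary for its
own subcategory; cells viewed from a foreign perspective hold general,
external-view vocabulary. Perspectives are an ordered list aligned
positionally with the disciplines (perspective *k* is discipline *k*'s
viewpoint), which generalizes the two-discipline a/b labelling to *n*
disciplines.

Query construction is purely structural:

- **full query** — AND over categories of OR over *every* term of *every*
  (discipline, perspective) cell of that category;
- **discipline query** — AND over categories of OR over that discipline's
  own rows seen from its own perspective only (a flag widens this to all
  perspectives).

It follows by construction that every discipline query's matched set is a
subset of the full query's, which is what makes the segment classification
well defined: on the retrieved set (entries matching the full query), an
entry is *expert overlap* if ≥ 2 discipline queries match, *discipline-
specific* if exactly one matches, and a *golden gap* if none does. For more
than two disciplines "overlap" means ≥ 2 matches; per-pair counts can be
derived from the per-discipline match sets if needed. The 2×2
category-segment view (`category_term_segments`) is only defined for two
disciplines and two perspectives, because its four pairings (each cell used
exactly twice) have no canonical n-way generalization; larger matrices get
an explicit unsupported-shape error.

Queries use only AND/OR. Negative criteria are handled downstream by
screening filters, not by NOT clauses in the search string.

## Matching semantics

Local evaluation stands in for database retrieval when classifying segments
and validating golden bullets. Text is folded (lowercase, diacritics
stripped) and tokenized on every non-alphanumeric character, so
"exergame-based" yields two tokens — this mirrors the default indexing of
the major bibliographic databases. Term modes: **word** = whole-token
equality, **phrase** = contiguous token run within a single field,
**prefix** = token prefix ("child" as a prefix matches "children"). Matching
is evaluated per field over the term's field scope (title, abstract,
keywords; default all three). Missing fields are empty text and match
nothing.

Dialect rendering is the inverse concern: profiles define operator tokens,
the truncation wildcard, phrase delimiters and per-field tag templates.
Output is fully parenthesized and deterministic; a term containing a phrase
delimiter is escaped by removing the delimiter, with a logged warning.
Per-database query-length limits are reported as warnings, never enforced by
splitting. Four example dialects ship with the package (`pubmed-like`,
`wos-like`, `acm-like`, `generic`); they are illustrative templates, not
faithful replicas of any vendor syntax.

## Ingest and deduplication

BibTeX is the interchange format. The reader handles the common
`@type{key, field = {...}}` syntax, folds LaTeX accent macros to Unicode,
skips unparseable records with a logged warning, and errors only when a
document yields zero records. Deduplication cascades three passes —
identical non-empty DOIs, identical (normalized title, year), then a fuzzy
normalized-title pass (default threshold 0.95 `SequenceMatcher` ratio,
disabled with `fuzzy=False`) guarded by equal year. The year guard both
prevents merging annual reports and bounds the quadratic fuzzy pass to
per-year groups. The kept representative of a duplicate group is chosen by
(source-priority rank, entry id), which makes the kept identity set
invariant under input permutation; its `source_databases` is the union over
the group. Alignment exclusions drop entries whose title contains the whole
token "review" or "reviews" (configurable; "reviewed"/"reviewing" are
retained) or whose entry type is book-like (`book`, `inbook`,
`incollection`, `proceedings`, configurable).

## Screening

Filters are ordered named term groups applied with **first-match stage
attribution**: an entry is excluded at the first group that matches and
never reaches later stages, so the stage chain satisfies
`entering = excluded + remaining` at every stage, while the *total* excluded
set is independent of filter order. Filter terms default to whole-word
matching; prefix matching must be declared per term, which keeps the audit
trail honest about what actually matched. Every exclusion records its
matched (term, field) evidence, and review reports re-locate those terms in
the original prose with highlight markers (Markdown `**…**`, HTML
`<mark>`). Rescues are sticky: a rescued entry stays included across
re-runs, including re-runs triggered by supplying a refined filter (which
replaces the same-named stage). The consensus rule implements
"include iff ≥ 1 relevant vote"; a discussion is flagged whenever votes are
neither unanimously relevant nor unanimously excluded — the neutral-only and
neutral+excluded cases are not separately specified by the underlying rule,
and flagging them errs toward human review.

## Metrics and rounding

Relative sensitivity is the plain ratio `100 × TP_cris / TP_other`
(undefined at zero denominator). Note that a value of 418.2% is the *ratio*,
not the increase (which would be 318.2%); the toolkit reports the ratio.
True positives are caller-designated — the toolkit never adjudicates
relevance. Composition shares and reduction percentages are computed with
`decimal` arithmetic and rounded **half-up to one decimal**, the reporting
precision used throughout; shares therefore sum to 100.0 ± 0.2. Specificity
is reported only as the absolute filtered-out count, since false negatives
in the unretrieved population are unobservable.

## Synthetic corpora

The generator exists so that every stage is testable without live database
exports. From a bundled 6-category × 2-discipline × 2-perspective fixture
matrix with invented but token-disjoint vocabularies (expert vs. general vs.
filter-trigger vs. template prose), it emits per-pseudo-database BibTeX in
which each planted entry embeds one term per category in the voice its
segment requires: own expert terms (discipline-specific), both disciplines'
expert terms (overlap), or general terms only (golden gap). Vocabulary
disjointness is enforced for the fixture only — user matrices need not obey
it — and the generator *verifies* its ground truth at generation time by
re-classifying the planted entries, raising if any label fails to reproduce.
Duplicates are emitted into a second pseudo-database with the same DOI and a
cosmetic title variant (case/punctuation only); titles carry an 8-hex code
plus randomized title words so distinct entries stay far below the fuzzy
dedup threshold. Abstracts are template prose with embedded terms, not
natural language — adequate because all operators are token-level, but it
means passing tests demonstrate the pipeline's bookkeeping and Boolean
semantics, not robustness to real abstracts' paraphrase, negation or
morphology.

Study-scale defaults reproduce the reference experiment sizes: a
composition corpus whose deduplicated base is 57 entries split
24/16/11/6 across hms/uxg/overlap/gap (plus 8 duplicates, 3 reviews,
2 books, 10 distractors), and a screening corpus of 1,896 entries with
planted stage-wise trigger counts 283/783/37 for the child-related,
disease-related and computer-science filters. Both run in seconds on one
CPU; all randomness flows from a single integer seed and identical seeds
give byte-identical files.

## Pipeline and reproducibility

`cris run` executes validate → build/render queries → (optional golden
bullets) → ingest → screen → classify → evaluate, with a pre-flight check
that fails before any output is written if a referenced file is missing.
The manifest records the tool version, SHA-256 digests of the config and
every input, and per-stage counts, so two runs on identical inputs differ
only in timestamps.

## Known limitations

- Local Boolean evaluation approximates, but is not, vendor retrieval:
  controlled-vocabulary expansion, lemmatization and full-text indexing are
  out of scope, as are live database connectors.
- The dedup fuzzy pass only compares same-year records; exports with
  conflicting years for the same article are not merged.
- The counts 46 (CRIS true positives) and 57 (composition base) are
  treated as independent caller-supplied inputs; the toolkit does not model
  the relationship between a screening outcome and the retrieval base.
- Term discovery (choosing the matrix vocabulary) is a human process and is
  not automated here.
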