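import random

import pytest

from cris.errors import CellReferenceError, InputError
from cris.matrix import Term, load_matrix
from cris.query import (
    build_discipline_query,
    build_full_query,
    build_query_suite,
    evaluate_query,
    Leaf,
    render_query,
    suite_from_json,
    suite_to_json,
    validate_golden_bullets,
)

from conftest import make_entry
from oracles import (
    GenericDialectParser,
    brute_force_discipline_match,
    brute_force_full_match,
    eval_parsed,
    random_entries,
    random_matrix,
    regex_term_match,
)


class TestBuildQueries:
    def test_full_query_is_and_of_per_category_or_blocks(self, small_matrix):
        q = build_full_query(small_matrix)
        assert q.kind == "and"
        assert [c.label for c in q.children] == ["cat1", "cat2"]
        assert all(c.kind == "or" for c in q.children)
        # every cell's terms appear as leaves of its category block
        cat1_surfaces = {leaf.term.surface for leaf in q.children[0].leaves()}
        assert {"anatomical", "gait", "walking pattern", "avatar",
                "playful", "screen figure"} == cat1_surfaces

    def test_degenerate_matrix_collapses_to_single_leaf(self):
        doc = """
name: tiny
perspectives: [a]
categories:
  - id: only
    label: "1"
    rows:
      a: {a: [solo]}
"""
        q = build_full_query(load_matrix(doc))
        assert q.kind == "leaf" and q.term.surface == "solo"

    def test_discipline_query_uses_own_cells_only(self, small_matrix):
        q = build_discipline_query(small_matrix, "alpha")
        surfaces = {leaf.term.surface for leaf in q.leaves()}
        assert surfaces == {"anatomical", "gait", "strength drills"}

    def test_identical_cells_give_identical_discipline_queries(self):
        doc = """
name: sym
perspectives: [a, b]
categories:
  - id: c1
    label: "1"
    rows:
      a: {a: [same], b: [same]}
      b: {a: [same], b: [same]}
"""
        matrix = load_matrix(doc)
        assert build_discipline_query(matrix, "a") == build_discipline_query(matrix, "b")

    def test_unknown_discipline_rejected(self, small_matrix):
        with pytest.raises(CellReferenceError):
            build_discipline_query(small_matrix, "gamma")

    def test_canonical_ordering_independent_of_cell_insertion_order(self, small_matrix):
        from cris.matrix import FoundationalSearchMatrix

        shuffled = FoundationalSearchMatrix(
            name=small_matrix.name,
            categories=small_matrix.categories,
            perspectives=small_matrix.perspectives,
            cells=dict(reversed(list(small_matrix.cells.items()))),
        )
        assert build_full_query(shuffled) == build_full_query(small_matrix)


class TestBruteForceOracles:
    @pytest.mark.parametrize("seed", range(6))
    def test_full_query_equals_set_algebra_oracle(self, seed):
        rng = random.Random(seed)
        matrix = random_matrix(rng, n_categories=rng.randint(1, 3))
        vocab = {t.surface for ts in matrix.cells.values() for t in ts.terms}
        entries = random_entries(rng, vocab, n=40)
        q = build_full_query(matrix)
        got = {e.id for e in entries if evaluate_query(q, e)}
        assert got == brute_force_full_match(matrix, entries)

    @pytest.mark.parametrize("seed", range(6))
    def test_discipline_matches_are_subset_of_full(self, seed):
        rng = random.Random(100 + seed)
        matrix = random_matrix(rng)
        vocab = {t.surface for ts in matrix.cells.values() for t in ts.terms}
        entries = random_entries(rng, vocab, n=40)
        full = build_full_query(matrix)
        full_ids = {e.id for e in entries if evaluate_query(full, e)}
        for d in matrix.disciplines:
            dq = build_discipline_query(matrix, d)
            d_ids = {e.id for e in entries if evaluate_query(dq, e)}
            assert d_ids <= full_ids
            assert d_ids == brute_force_discipline_match(matrix, d, entries)


class TestEvaluate:
    def test_empty_entry_matches_nothing(self):
        entry = make_entry("empty")
        assert not evaluate_query(Leaf(Term("anything")), entry)

    def test_prefix_matches_longer_token(self):
        entry = make_entry("e", abstract="games for children and families")
        assert evaluate_query(Leaf(Term("child", "prefix")), entry)
        assert not evaluate_query(Leaf(Term("child", "word")), entry)

    def test_phrase_requires_contiguous_tokens(self):
        hit = make_entry("hit", abstract="a balance training plan")
        miss = make_entry("miss", abstract="balance and strength training")
        phrase = Leaf(Term("balance training", "phrase"))
        assert evaluate_query(phrase, hit)
        assert not evaluate_query(phrase, miss)

    def test_case_and_diacritics_folded(self):
        entry = make_entry("e", title="Über GERIATRIC Motión")
        assert evaluate_query(Leaf(Term("geriatric")), entry)
        assert evaluate_query(Leaf(Term("motion")), entry)

    def test_hyphen_splits_tokens(self):
        entry = make_entry("e", abstract="an exergame-based approach")
        assert evaluate_query(Leaf(Term("exergame")), entry)

    def test_field_scope_respected(self):
        entry = make_entry("e", abstract="gait speed")
        scoped = Leaf(Term("gait", "word", frozenset({"title"})))
        assert not evaluate_query(scoped, entry)

    def test_agreement_with_regex_oracle_on_random_pairs(self):
        rng = random.Random(7)
        vocab = ["amble", "brisk walk", "cant", "dash"]
        terms = [
            Term("amble"), Term("brisk walk", "phrase"),
            Term("cant", "prefix"), Term("dash", "word"),
        ]
        entries = random_entries(rng, vocab + ["canter", "dashboard"], n=250)
        for entry in entries:
            for term in terms:
                assert evaluate_query(Leaf(term), entry) == regex_term_match(term, entry)


class TestRender:
    def test_single_leaf_render_has_tags_and_no_operators(self, pubmed_profile):
        leaf = Leaf(Term("gait", "word", frozenset({"title"})))
        assert render_query(leaf, pubmed_profile) == "gait[Title]"

    def test_multi_field_leaf_expands_to_or_of_tagged_tokens(self, pubmed_profile):
        leaf = Leaf(Term("gait", "word", frozenset({"title", "abstract"})))
        assert render_query(leaf, pubmed_profile) == "(gait[Title] OR gait[Abstract])"

    def test_operator_casing_follows_profile(self, small_matrix, generic_profile):
        from dataclasses import replace

        lower = replace(generic_profile, and_token="and", or_token="or")
        text = render_query(build_full_query(small_matrix), lower)
        assert " and " in text and " AND " not in text

    def test_rendering_is_deterministic(self, small_matrix, generic_profile):
        q = build_full_query(small_matrix)
        assert render_query(q, generic_profile) == render_query(q, generic_profile)

    def test_delimiter_inside_term_is_escaped_with_warning(self, generic_profile, caplog):
        leaf = Leaf(Term('say "hi" now', "phrase"))
        with caplog.at_level("WARNING"):
            text = render_query(leaf, generic_profile)
        assert text == '"say hi now"'
        assert any("delimiter" in r.message for r in caplog.records)

    @pytest.mark.parametrize("seed", range(5))
    def test_parse_back_roundtrip_preserves_semantics(self, seed, generic_profile):
        rng = random.Random(40 + seed)
        matrix = random_matrix(rng, n_categories=2)
        vocab = {t.surface for ts in matrix.cells.values() for t in ts.terms}
        entries = random_entries(rng, vocab, n=40)
        q = build_full_query(matrix)
        parsed = GenericDialectParser(render_query(q, generic_profile)).parse()
        for entry in entries:
            assert evaluate_query(q, entry) == eval_parsed(parsed, entry)


class TestGoldenBullets:
    def _bullet(self, eid, text):
        return make_entry(eid, abstract=text)

    def test_constructed_pass_matches_all(self, small_matrix):
        suite = build_query_suite(small_matrix)
        bullets = [self._bullet("b1", "anatomical study with strength drills"),
                   self._bullet("b2", "avatar in a virtual world")]
        report = validate_golden_bullets(suite, bullets)
        assert report.all_captured
        assert set(report.matched) == {"b1", "b2"}

    def test_unmatched_bullet_reports_failing_category(self, small_matrix):
        suite = build_query_suite(small_matrix)
        bullet = self._bullet("b", "anatomical observations only")  # lacks cat2
        report = validate_golden_bullets(suite, [bullet])
        assert report.unmatched == (("b", "cat2"),)

    def test_report_partitions_bullet_set(self, small_matrix):
        suite = build_query_suite(small_matrix)
        bullets = [self._bullet("b1", "anatomical exercise"),
                   self._bullet("b2", "nothing relevant"),
                   self._bullet("b3", "avatar level design")]
        report = validate_golden_bullets(suite, bullets)
        matched = set(report.matched)
        unmatched = {eid for eid, _ in report.unmatched}
        assert matched | unmatched == {"b1", "b2", "b3"}
        assert not matched & unmatched

    def test_empty_bullet_set_rejected(self, small_matrix):
        suite = build_query_suite(small_matrix)
        with pytest.raises(InputError):
            validate_golden_bullets(suite, [])


def test_suite_json_roundtrip(small_matrix):
    suite = build_query_suite(small_matrix)
    restored = suite_from_json(suite_to_json(suite))
    entry = make_entry("e", abstract="anatomical study of strength drills")
    assert evaluate_query(restored.full, entry) == evaluate_query(suite.full, entry)
    assert set(restored.per_discipline) == set(suite.per_discipline)
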