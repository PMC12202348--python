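import re

import pytest

from cris.errors import CellReferenceError, InputError, StateError
from cris.screening import (
    FilterGroup,
    apply_filter_sequence,
    consensus_include,
    generate_review_report,
    load_filter_groups,
    rescue,
)
from cris.matrix import Term

from conftest import make_entry


@pytest.fixture
def filters():
    return load_filter_groups([
        {"name": "child-related", "terms": ["child*", "toddler", "girl"]},
        {"name": "disease-related", "terms": ["dementia", "stroke"]},
    ])


@pytest.fixture
def corpus():
    return [
        make_entry("e1", title="Games for healthy older adults",
                   abstract="healthy older adults in community settings"),
        make_entry("e2", title="Play in kindergarten",
                   abstract="a study of toddler play and child development"),
        make_entry("e3", title="Cognition after stroke",
                   abstract="stroke survivors with mild dementia"),
        make_entry("e4", title="Girls and dementia care",
                   abstract="girl caregivers supporting dementia patients"),
        make_entry("e5", title="Neutral entry", abstract="nothing to flag"),
    ]


class TestFilterSequence:
    def test_non_matching_entries_are_included(self, corpus, filters):
        result = apply_filter_sequence(corpus, filters)
        assert result.records["e1"].status == "included"
        assert result.records["e5"].final

    def test_first_match_attribution(self, corpus, filters):
        # e4 matches both groups but is attributed to the first
        result = apply_filter_sequence(corpus, filters)
        assert result.records["e4"].stage == "child-related"
        assert not result.records["e4"].final

    def test_stage_chain_conservation(self, corpus, filters):
        result = apply_filter_sequence(corpus, filters)
        chain = result.summary.counts_chain
        assert chain == (5, 3, 2)
        for stat in result.summary.stages:
            assert stat.entering == stat.excluded + stat.remaining

    def test_total_exclusion_is_order_independent(self, corpus, filters):
        forward = apply_filter_sequence(corpus, filters)
        backward = apply_filter_sequence(corpus, list(reversed(filters)))
        assert set(forward.excluded_ids) == set(backward.excluded_ids)
        # stage attribution differs for the doubly matching entry
        assert backward.records["e4"].stage == "disease-related"

    def test_empty_filter_sequence_includes_everything(self, corpus):
        result = apply_filter_sequence(corpus, [])
        assert result.summary.stages == ()
        assert len(result.included_ids) == len(corpus)

    def test_exclusions_carry_verifiable_evidence(self, corpus, filters):
        result = apply_filter_sequence(corpus, filters)
        by_id = {e.id: e for e in corpus}
        for record in result.records.values():
            if record.final:
                continue
            assert record.matched_terms
            for surface, fieldname in record.matched_terms:
                text = by_id[record.entry_id].field_text(fieldname).lower()
                assert surface.rstrip("*").split()[0] in text


class TestReviewReport:
    def test_sections_and_highlights_per_excluded_entry(self, corpus, filters):
        result = apply_filter_sequence(corpus, filters)
        report = generate_review_report(result, "child-related")
        assert report.count("## ") == 2  # e2, e4
        assert "**toddler**" in report and "**child development**" not in report
        assert "**girl**" in report

    def test_highlight_relocates_the_matched_token_exactly(self, filters):
        entry = make_entry("x", title="Child-centred play",
                           abstract="Every CHILD and their children benefit")
        result = apply_filter_sequence([entry], filters)
        report = generate_review_report(result, "child-related")
        for hit in re.findall(r"\*\*([^*]+)\*\*", report):
            assert hit.lower().startswith("child")
        # prefix term highlights the full surface token
        assert "**CHILD**" in report and "**children**" in report

    def test_zero_exclusion_stage_is_valid_and_empty(self, filters):
        result = apply_filter_sequence([make_entry("a", abstract="clean")], filters)
        report = generate_review_report(result, "disease-related")
        assert "0 entries excluded" in report
        assert "## " not in report

    def test_unknown_stage_rejected(self, corpus, filters):
        result = apply_filter_sequence(corpus, filters)
        with pytest.raises(CellReferenceError):
            generate_review_report(result, "no-such-stage")

    def test_html_report_marks_terms(self, corpus, filters):
        result = apply_filter_sequence(corpus, filters)
        html = generate_review_report(result, "child-related", fmt="html")
        assert "<mark>" in html


class TestRescue:
    def test_rescue_bookkeeping(self, corpus, filters):
        result = apply_filter_sequence(corpus, filters)
        k = len(result.excluded_ids)
        rescued = rescue(result, "e2")
        assert len(rescued.excluded_ids) == k - 1
        assert rescued.records["e2"].status == "rescued"
        assert rescued.records["e2"].final

    def test_refined_filter_rerun_differencing(self, corpus, filters):
        result = apply_filter_sequence(corpus, filters)
        refined = FilterGroup(
            name="child-related",
            terms=(Term("child", "prefix"), Term("girl")),  # 'toddler' removed
        )
        rerun = rescue(result, "e2", refined_filter=refined)
        # e2 matched 'toddler' AND 'child*': still evidenced, but rescued
        assert rerun.records["e2"].final
        # entries matched only by the removed term would now be included
        only_toddler = make_entry("t", abstract="a toddler cohort")
        before = apply_filter_sequence([only_toddler], filters)
        assert not before.records["t"].final
        after = apply_filter_sequence([only_toddler], [refined, filters[1]])
        assert after.records["t"].final
        assert len(rerun.passes) == 2

    def test_rescue_is_sticky_across_identical_reruns(self, corpus, filters):
        result = rescue(apply_filter_sequence(corpus, filters), "e4")
        rerun = rescue(result, "e3")
        assert rerun.records["e4"].final
        assert rerun.records["e4"].status == "rescued"

    def test_rescuing_non_excluded_entry_is_a_state_error(self, corpus, filters):
        result = apply_filter_sequence(corpus, filters)
        with pytest.raises(StateError):
            rescue(result, "e1")


class TestConsensus:
    @pytest.mark.parametrize(
        "votes, decision, discuss",
        [
            ({"A": "relevant", "B": "excluded"}, "include", True),
            ({"A": "excluded", "B": "excluded"}, "exclude", False),
            ({"A": "neutral", "B": "neutral"}, "exclude", True),
            ({"A": "relevant", "B": "relevant"}, "include", False),
            ({"A": "relevant", "B": "neutral", "C": "excluded"}, "include", True),
            ({"A": "neutral", "B": "excluded"}, "exclude", True),
        ],
    )
    def test_at_least_one_relevant_rule(self, votes, decision, discuss):
        assert consensus_include(votes) == (decision, discuss)

    def test_empty_vote_map_rejected(self):
        with pytest.raises(InputError):
            consensus_include({})

    def test_unknown_vote_rejected(self):
        with pytest.raises(InputError):
            consensus_include({"A": "maybe"})


def test_generator_ground_truth_counts():
    from cris.bibio import parse_bibtex_text
    from cris.synthetic import default_filter_groups, generate_screening_corpus

    text, truth = generate_screening_corpus(120, [20, 30, 5], seed=3)
    entries = parse_bibtex_text(text, "screening")
    result = apply_filter_sequence(entries, default_filter_groups())
    assert result.summary.counts_chain == (120, 100, 70, 65)
    for record in result.records.values():
        expected = truth.filter_stage.get(record.entry_id)
        assert record.stage == (expected or "")
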