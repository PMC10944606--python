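"""Canonicalization, unification, design/attribute factoring, hierarchy."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from designminer import (
    DesignMention,
    NoDesignError,
    canonicalize,
    classify_high_level,
    map_to_hierarchy,
    select_representative,
    split_design_attributes,
    standardize_abstract,
    standardize_corpus,
)


def _mention(surface, start=0, pmid="1", term=None):
    return DesignMention(
        pmid=pmid, surface=surface, span=(start, start + len(surface)),
        rule_id="P01", matched_term=term or surface.lower(), sentence_index=0,
    )


class TestCanonicalize:
    @pytest.mark.parametrize(
        "surface,expected",
        [
            ("Randomized Controlled Trial", "randomised controlled trial"),
            ("cross sectional", "cross sectional"),
            ("meta analytic review", "meta-analytic review"),
            ("non-randomized  trial", "nonrandomised trial"),
            ("Cross-Sectional survey", "cross sectional survey"),
            ("RCT", "randomised controlled trial"),
        ],
    )
    def test_canonical_forms(self, lexicon, surface, expected):
        assert canonicalize(surface, lexicon) == expected

    def test_idempotent_on_canonical_strings(self, lexicon):
        for surface in ("randomised controlled trial", "cross sectional",
                        "meta-analysis", "prospective cohort"):
            assert canonicalize(canonicalize(surface, lexicon), lexicon) == \
                canonicalize(surface, lexicon)


class TestRepresentative:
    def test_lengthiest_canonical_wins(self, lexicon):
        mentions = [
            _mention("randomised controlled trial", 50),
            _mention("randomised double blinded controlled trial", 0),
        ]
        rep = select_representative(mentions, lexicon)
        assert rep.surface == "randomised double blinded controlled trial"

    def test_stopwords_do_not_inflate_length(self, lexicon):
        mentions = [_mention("cohort study", 0), _mention("prospective cohort", 40)]
        assert select_representative(mentions, lexicon).surface == "prospective cohort"

    def test_single_mention_is_returned_unchanged(self, lexicon):
        m = _mention("case report")
        assert select_representative([m], lexicon) is m

    def test_empty_list_is_an_error(self, lexicon):
        with pytest.raises(NoDesignError):
            select_representative([], lexicon)

    @settings(max_examples=50, deadline=None)
    @given(st.randoms(use_true_random=False))
    def test_permutation_invariance(self, lexicon, rnd):
        surfaces = ["cohort", "prospective cohort", "randomised controlled trial",
                    "survey", "case-control study", "systematic review"]
        starts = list(range(0, 600, 100))
        mentions = [_mention(s, start) for s, start in zip(surfaces, starts)]
        baseline = select_representative(mentions, lexicon)
        shuffled = mentions[:]
        rnd.shuffle(shuffled)
        assert select_representative(shuffled, lexicon) == baseline

    def test_ties_break_to_earliest_span(self, lexicon):
        mentions = [_mention("case-control", 90), _mention("case control", 10)]
        assert select_representative(mentions, lexicon).span[0] == 10


class TestFactoring:
    @pytest.mark.parametrize(
        "canonical,expected",
        [
            ("prospective cohort", ("cohort", {"prospective"})),
            ("randomised double blinded controlled trial",
             ("randomised controlled", {"double blind"})),
            ("cross sectional descriptive", ("cross sectional descriptive", set())),
            ("retrospective cohort study", ("cohort", {"retrospective"})),
            ("cluster randomised controlled trial", ("cluster randomised controlled", set())),
            ("systematic review", ("systematic", set())),
            ("meta-analysis", ("meta-analysis", set())),
            ("pilot randomised controlled trial", ("randomised controlled", {"pilot"})),
            ("cross sectional survey", ("cross sectional", set())),
            ("analytical study", ("", set())),
            ("systematic approach", ("", set())),
        ],
    )
    def test_greedy_longest_design_then_attributes(self, lexicon, canonical, expected):
        assert split_design_attributes(canonical, lexicon.schema) == expected

    @pytest.mark.parametrize(
        "lower,node",
        [
            ("systematic", "review"),
            ("cluster randomised controlled", "trial"),
            ("analytical study", "miscellaneous"),
            ("", "miscellaneous"),
            ("cohort", "observational"),
        ],
    )
    def test_high_level_classification(self, lexicon, lower, node):
        assert classify_high_level(lower, lexicon.schema) == node


class TestHierarchyMapping:
    def test_worked_examples(self, lexicon):
        examples = {
            "meta-analysis": "meta-analysis",
            "cluster randomised controlled trial": "randomised controlled trial",
            "systematic review": "systematic review",
            "prospective cohort": "cohort",
            "clinical study": "unmappable",
            "randomised design": "unmappable",
        }
        for surface, tier in examples.items():
            sd = standardize_abstract([_mention(surface)], lexicon)
            assert map_to_hierarchy(sd, lexicon.hierarchy).tier == tier, surface

    def test_lexicon_miscellaneous_flag_forces_unmappable(self, lexicon):
        sd = standardize_abstract([_mention("qualitative study")], lexicon)
        assert sd.high_level == "miscellaneous"
        assert sd.lower_level == ""
        assert sd.attributes == frozenset()


class TestUnification:
    def test_one_standardized_design_per_abstract(self, lexicon, engine, synthetic_500):
        mentions = [m for rec in synthetic_500 for m in engine.extract(rec.record)]
        designs = standardize_corpus(mentions, lexicon)
        assert len({sd.pmid for sd in designs}) == len(designs)
        assert {sd.pmid for sd in designs} == {m.pmid for m in mentions}

    def test_partition_over_nodes_and_tiers(self, lexicon, engine, synthetic_500):
        mentions = [m for rec in synthetic_500 for m in engine.extract(rec.record)]
        designs = standardize_corpus(mentions, lexicon)
        node_counts: dict[str, int] = {}
        tier_counts: dict[str, int] = {}
        for sd in designs:
            node_counts[sd.high_level] = node_counts.get(sd.high_level, 0) + 1
            tier = map_to_hierarchy(sd, lexicon.hierarchy).tier
            tier_counts[tier] = tier_counts.get(tier, 0) + 1
        assert sum(node_counts.values()) == len(designs)
        assert sum(tier_counts.values()) == len(designs)
        assert set(node_counts) <= set(lexicon.schema.nodes)

    def test_attributes_always_allowed_for_node(self, lexicon, engine, synthetic_500):
        mentions = [m for rec in synthetic_500 for m in engine.extract(rec.record)]
        for sd in standardize_corpus(mentions, lexicon):
            if sd.high_level == "miscellaneous":
                assert sd.attributes == frozenset()
            else:
                assert sd.attributes <= lexicon.schema.allowed_attributes(sd.high_level)

    def test_representative_is_lengthiest_of_all_mentions(self, lexicon):
        mentions = [_mention("cohort", 0), _mention("prospective cohort", 30),
                    _mention("cohort study", 60)]
        sd = standardize_abstract(mentions, lexicon)
        assert sd.representative_surface == "prospective cohort"
        assert sd.canonical == "prospective cohort"
        assert len(sd.all_mentions) == 3
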