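"""Property segmentation, impact classification, mutant linking and
contradiction resolution."""

import pytest

from mutimpact.ner import (
    MutationMention,
    find_direction_terms,
    find_property_mentions,
    normalize_mutation,
)
from mutimpact.relations import (
    ImpactStatement,
    MutantImpactRelation,
    classify_impact,
    link_mutants,
    resolve_contradictions,
    segment_properties,
)
from mutimpact.textmodel import build_document


def analyse(text, dlex):
    doc = build_document("d", text)
    sent = doc.sentences[0]
    props = find_property_mentions(sent, doc.text, dlex)
    terms = find_direction_terms(sent, dlex)
    segments = segment_properties(sent, doc.text, props)
    return doc, sent, props, terms, segments


class TestSegmentProperties:
    def test_split_at_and(self, dlex):
        text = ("The W125F mutant showed only a slight reduction of activity "
                "(Vmax) and a larger increase of Km with 1,2-dibromoethane.")
        _, _, props, _, segments = analyse(text, dlex)
        assert len(props) == 2
        assert len(segments) == 2
        for prop, (lo, hi) in zip(sorted(props, key=lambda p: p.start),
                                  segments):
            assert lo <= prop.start and prop.end <= hi

    def test_single_property_whole_sentence(self, dlex):
        text = "The mutant showed reduced activity overall."
        _, sent, props, _, segments = analyse(text, dlex)
        assert segments == [(sent.start, sent.end)]

    def test_comma_preferred_over_fallback(self, dlex):
        text = "The mutant lost activity, and its Km also decreased."
        _, _, props, _, segments = analyse(text, dlex)
        assert len(segments) == 2

    def test_fallback_splits_before_later_property(self, dlex):
        text = "The enzyme showed higher activity lower Km overall."
        doc, sent, props, _, segments = analyse(text, dlex)
        assert len(segments) == 2
        later = sorted(props, key=lambda p: p.start)[1]
        assert segments[1][0] == later.start


class TestClassifyImpact:
    def classify_first(self, text, dlex):
        doc, sent, props, terms, segments = analyse(text, dlex)
        prop = sorted(props, key=lambda p: p.start)[0]
        segment = next(s for s in segments
                       if s[0] <= prop.start and prop.end <= s[1])
        return classify_impact(sent, segment, prop, terms)

    def test_reduction_of_activity(self, dlex):
        impact = self.classify_first(
            "a slight reduction of activity (Vmax) was observed", dlex)
        assert impact.direction == "negative"
        assert impact.token_distance == 2
        assert impact.impact_score == 0.5

    def test_adjacent_direction_distance_one(self, dlex):
        impact = self.classify_first(
            "The double mutant had reduced catalytic activity (30-40%) "
            "compared to the wildtype.", dlex)
        assert impact.direction == "negative"
        assert impact.token_distance == 1

    def test_negation_remaps_non_neutral_to_neutral(self, dlex):
        impact = self.classify_first("no effect on the activity was seen", dlex)
        assert impact.direction == "neutral"

    def test_negation_remaps_positive_to_neutral(self, dlex):
        impact = self.classify_first("not increased activity", dlex)
        assert impact.direction == "neutral"

    def test_negation_outside_window_ignored(self, dlex):
        impact = self.classify_first(
            "no change of the clearly increased activity", dlex)
        assert impact.direction == "positive"

    def test_no_direction_term_gives_none(self, dlex):
        assert self.classify_first("the activity of the enzyme", dlex) is None

    def test_nearest_term_wins(self, dlex):
        impact = self.classify_first(
            "enhanced folding but strongly reduced activity", dlex)
        assert impact.direction == "negative"


def impact_at(sentence_index, prop_start=0):
    from mutimpact.ner import PropertyMention
    prop = PropertyMention(kind="kinetic", start=prop_start,
                           end=prop_start + 2, head="Km", variable="KM",
                           sentence_index=sentence_index)
    return ImpactStatement(direction="positive", property=prop,
                           token_distance=1, sentence_index=sentence_index)


class TestLinkMutants:
    def doc_with_sentences(self, n, mutant_sentence):
        """n sentences; a W125F mention placed in sentence *mutant_sentence*."""
        sentences = []
        for i in range(n):
            if i == mutant_sentence:
                sentences.append("The W125F mutant was purified again.")
            else:
                sentences.append("The buffer was exchanged once more.")
        doc = build_document("d", " ".join(sentences))
        mentions = [
            MutationMention("W", 125, "F", a.start, a.end)
            for a in doc.annotations_of("Mutation")
        ]
        from mutimpact.ner import find_mutation_mentions
        return doc, find_mutation_mentions(doc)

    @pytest.mark.parametrize("back, expected_score",
                             [(0, 1.0), (1, 1 / 2), (2, 1 / 3), (3, 1 / 4)])
    def test_sentence_distance_scores(self, back, expected_score):
        doc, mentions = self.doc_with_sentences(5, mutant_sentence=4 - back)
        rels = link_mutants([impact_at(4)], mentions, doc)
        assert len(rels) == 1
        assert rels[0].relation_score == pytest.approx(expected_score)

    def test_window_cap_beyond_three_sentences(self):
        doc, mentions = self.doc_with_sentences(6, mutant_sentence=0)
        assert link_mutants([impact_at(5)], mentions, doc) == []

    def test_following_sentences_never_linked(self):
        doc, mentions = self.doc_with_sentences(4, mutant_sentence=2)
        assert link_mutants([impact_at(0)], mentions, doc) == []

    def test_all_minimal_distance_mutants_receive_impact(self):
        text = ("The W125F and D170N mutants were made. "
                "The Km increased afterwards.")
        doc = build_document("d", text)
        from mutimpact.ner import find_mutation_mentions
        mentions = find_mutation_mentions(doc)
        rels = link_mutants([impact_at(1)], mentions, doc)
        assert {r.mutation.normalized for r in rels} == {"W125F", "D170N"}
        assert {r.sentence_distance for r in rels} == {2}


def relation(direction, sentence_distance, token_distance, similarity=None,
             kind="kinetic", prop_start=0):
    from mutimpact.ner import PropertyMention
    prop = PropertyMention(
        kind=kind, start=prop_start, end=prop_start + 2, head="activity",
        variable="KM" if kind == "kinetic" else None,
        go_id="GO:0000001" if similarity is not None else None,
        similarity=similarity,
    )
    impact = ImpactStatement(direction=direction, property=prop,
                             token_distance=token_distance, sentence_index=0)
    return MutantImpactRelation(
        mutation=normalize_mutation("W125F"),
        impact=impact, sentence_distance=sentence_distance)


class TestScoresAndResolution:
    def test_combined_score_includes_similarity_for_functions(self):
        rel = relation("positive", 1, 2, similarity=0.5, kind="function")
        assert rel.combined_score == pytest.approx((1.0 + 0.5 + 0.5) / 3)

    def test_combined_score_omits_similarity_for_kinetic(self):
        rel = relation("positive", 2, 1)
        assert rel.combined_score == pytest.approx((0.5 + 1.0) / 2)

    def test_scores_monotone_in_distance(self):
        scores = [relation("positive", d, 1).relation_score
                  for d in (1, 2, 3, 4)]
        assert scores == sorted(scores, reverse=True)

    def test_contradiction_keeps_max_score(self):
        strong = relation("positive", 1, 1)     # mean 1.0
        weak = relation("negative", 2, 2)       # mean 0.375... lower
        kept = resolve_contradictions([weak, strong])
        assert len(kept) == 1
        assert kept[0].impact.direction == "positive"

    def test_uncontradicted_relation_unchanged(self):
        rel = relation("negative", 1, 1)
        assert resolve_contradictions([rel]) == [rel]

    def test_different_properties_not_in_conflict(self):
        a = relation("positive", 1, 1, prop_start=0)
        b = relation("negative", 1, 1, prop_start=10, kind="function",
                     similarity=0.4)
        assert len(resolve_contradictions([a, b])) == 2

    def test_at_most_one_direction_per_key_after_resolution(self):
        rels = [relation(d, sd, 1) for d in ("positive", "negative", "neutral")
                for sd in (1, 2)]
        kept = resolve_contradictions(rels)
        keys = [(r.key, r.impact.direction) for r in kept]
        assert len({k for k, _ in keys}) == len(keys) == 1
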