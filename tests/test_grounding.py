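"""Candidate pooling, pairwise-regex mutation grounding (with brute-force
oracle equivalence), token preparation and GO similarity."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from mutimpact.grounding import (
    CandidatePool,
    brute_force_ground,
    build_candidate_pool,
    build_pair_regex,
    ground_function,
    ground_mutations,
    prepare_tokens,
    similarity,
)
from mutimpact.lexicons import ProteinLexicon
from mutimpact.ner import MutationMention, PropertyMention
from mutimpact.pipeline import run_text
from mutimpact.textmodel import build_document
from mutimpact.ner import annotate_document


def mm(raw: str) -> MutationMention:
    from mutimpact.ner import normalize_mutation
    return normalize_mutation(raw)


def pool_of(*accessions: str) -> CandidatePool:
    return CandidatePool(support={a: 1 for a in accessions})


class TestCandidatePool:
    def make_lex(self):
        lex = ProteinLexicon()
        lex.add_record("P1", [], "M" * 60, genes=["DhlA"],
                       organisms=["Xanthobacter autotrophicus"])
        lex.add_record("P2", [], "G" * 60, genes=["LinB"],
                       organisms=["Sphingomonas paucimobilis"])
        lex.add_record("P3", [], "A" * 60, genes=["DhlA2"],
                       organisms=["Xanthobacter autotrophicus"])
        return lex

    def annotated(self, text, lex):
        from mutimpact.lexicons import build_direction_lexicon
        doc = build_document("d", text)
        annotate_document(doc, lex, build_direction_lexicon())
        return doc

    def test_frequency_trimming(self):
        lex = self.make_lex()
        doc = self.annotated("DhlA then DhlA then DhlA and once LinB.", lex)
        pool = build_candidate_pool(doc, lex, fraction=0.5)
        assert "P2" not in pool.support          # support 1 < ceil(0.5*3)
        assert pool.support["P1"] == 3

    def test_suffix_expansion_pools_both(self):
        lex = self.make_lex()
        doc = self.annotated("The DhlA enzyme was purified.", lex)
        pool = build_candidate_pool(doc, lex)
        assert {"P1", "P3"} <= set(pool.support)  # DhlA2 via suffix rule

    def test_organism_filter_discards_foreign_accessions(self):
        lex = self.make_lex()
        doc = self.annotated(
            "DhlA and LinB from Xanthobacter autotrophicus.", lex)
        pool = build_candidate_pool(doc, lex)
        assert pool.organism_filtered
        assert "P2" not in pool.support
        assert "P1" in pool.support

    def test_filter_skipped_without_organism_mention(self):
        lex = self.make_lex()
        doc = self.annotated("DhlA and LinB were compared.", lex)
        pool = build_candidate_pool(doc, lex)
        assert not pool.organism_filtered
        assert {"P1", "P2"} <= set(pool.support)

    def test_empty_filter_falls_back_with_warning(self, caplog):
        lex = self.make_lex()
        lex.organism_names.add("Rhodococcus rhodochrous")
        doc = self.annotated("LinB from Rhodococcus rhodochrous.", lex)
        with caplog.at_level("WARNING"):
            pool = build_candidate_pool(doc, lex)
        assert "P2" in pool.support
        assert not pool.organism_filtered


class TestPairRegex:
    def test_printed_example(self):
        assert build_pair_regex(mm("A378C"), mm("S381L")) == "A..S"

    def test_adjacent_positions(self):
        assert build_pair_regex(mm("A5T"), mm("G6S")) == "AG"

    def test_sorts_by_position_first(self):
        assert build_pair_regex(mm("S381L"), mm("A378C")) == "A..S"

    def test_equal_positions_raise(self):
        with pytest.raises(ValueError):
            build_pair_regex(mm("A5T"), mm("A5G"))


def lex_with(**sequences: str) -> ProteinLexicon:
    lex = ProteinLexicon()
    for acc, seq in sequences.items():
        lex.add_record(acc, [], seq)
    return lex


class TestGroundMutations:
    def test_zero_displacement(self):
        lex = lex_with(P1="MAVSTLAG")
        res = ground_mutations({mm("A2G"), mm("T5P")}, pool_of("P1"), lex)
        assert res.accession == "P1"
        assert res.displacement == 0
        assert {m.normalized for m in res.grounded} == {"A2G", "T5P"}
        assert not res.discarded

    def test_met_cleavage_displacement(self):
        lex = lex_with(P1="AVSTLAG")   # initiator Met absent
        res = ground_mutations({mm("A2G"), mm("T5P")}, pool_of("P1"), lex)
        assert res.displacement == -1
        assert {m.normalized for m in res.grounded} == {"A2G", "T5P"}

    def test_least_displacement_wins_between_sequences(self):
        lex = lex_with(P1="MAVSTLAG", P2="AVSTLAG")
        res = ground_mutations({mm("A2G"), mm("T5P")},
                               pool_of("P1", "P2"), lex)
        assert res.accession == "P1"
        assert res.displacement == 0

    def test_unmatched_mention_discarded(self):
        lex = lex_with(P1="MAVSTLAG")
        res = ground_mutations({mm("A2G"), mm("T5P"), mm("W7C")},
                               pool_of("P1"), lex)
        assert {m.normalized for m in res.grounded} == {"A2G", "T5P"}
        assert {m.normalized for m in res.discarded} == {"W7C"}

    def test_single_mention_raises(self):
        lex = lex_with(P1="MAVSTLAG")
        with pytest.raises(ValueError, match="two point mutations"):
            ground_mutations({mm("A2G")}, pool_of("P1"), lex)

    def test_no_match_anywhere_discards_all(self):
        lex = lex_with(P1="G" * 50)
        res = ground_mutations({mm("A2G"), mm("T5P")}, pool_of("P1"), lex)
        assert res.accession is None
        assert len(res.discarded) == 2

    def test_accession_tie_breaks_lexicographically(self):
        lex = lex_with(P2="MAVSTLAG", P1="MAVSTLAG")
        res = ground_mutations({mm("A2G"), mm("T5P")},
                               pool_of("P1", "P2"), lex)
        assert res.accession == "P1"

    def test_shift_invariance(self):
        base = "MAVSTLAGHKW"
        mset = {mm("A2G"), mm("T5P"), mm("K10R")}
        for k in (1, 3, 7):
            lex = lex_with(P1="G" * 0 + "C" * k + base)
            res = ground_mutations(mset, pool_of("P1"), lex)
            assert res.displacement == k
            assert {m.normalized for m in res.grounded} == \
                   {"A2G", "T5P", "K10R"}

    @given(st.integers(0, 4999))
    @settings(max_examples=120, derandomize=True, deadline=None)
    def test_oracle_equivalence_random_instances(self, seed):
        """The pairwise-regex search must agree with exhaustive brute force
        over (accession, displacement) on accession, displacement and
        grounded set."""
        rng = random.Random(seed)
        lex = ProteinLexicon()
        accs = []
        for i in range(rng.randint(1, 3)):
            acc = f"P{i}"
            accs.append(acc)
            lex.add_record(acc, [], "".join(
                rng.choice("ACDEFGHIKLMNPQRSTVWY")
                for _ in range(rng.randint(30, 200))))
        mset = set()
        while len({m.position for m in mset}) < 2:
            mset = set()
            for _ in range(rng.randint(2, 5)):
                pos = rng.randint(1, 150)
                wt, mut = rng.sample("ACDEFGHIKLMNPQRSTVWY", 2)
                mset.add(MutationMention(wt, pos, mut))
        pool = pool_of(*accs)
        fast = ground_mutations(mset, pool, lex)
        slow = brute_force_ground(mset, pool, lex)
        assert fast.accession == slow.accession
        assert fast.displacement == slow.displacement
        assert fast.grounded == slow.grounded


class TestPrepareTokens:
    @pytest.mark.parametrize(
        "words, expected",
        [
            (["the", "activity"], {"activ"}),
            ([], set()),
            (["binding", "of", "zinc"], {"bind", "zinc"}),
        ],
    )
    def test_examples(self, words, expected):
        assert prepare_tokens(words) == expected


class TestSimilarity:
    def test_identical_sets_score_one(self):
        n = prepare_tokens(["zinc", "ion", "binding"])
        assert similarity(n, n) == 1.0

    def test_disjoint_sets_score_zero(self):
        assert similarity(frozenset({"a"}), frozenset({"b"})) == 0.0

    def test_partial_overlap_jaccard(self):
        n = frozenset({"zinc", "ion", "bind"})
        g = frozenset({"zinc", "bind"})
        assert similarity(n, g) == pytest.approx(2 / 3)

    def test_symmetric_and_bounded(self):
        rng = random.Random(0)
        universe = [f"w{i}" for i in range(10)]
        for _ in range(50):
            a = frozenset(rng.sample(universe, rng.randint(0, 6)))
            b = frozenset(rng.sample(universe, rng.randint(0, 6)))
            s = similarity(a, b)
            assert s == similarity(b, a)
            assert 0.0 <= s <= 1.0

    def test_one_sided_modes(self):
        n = frozenset({"zinc", "ion", "bind"})
        g = frozenset({"zinc", "bind"})
        assert similarity(n, g, mode="over_g") == 1.0
        assert similarity(n, g, mode="over_n") == pytest.approx(2 / 3)


class TestGroundFunction:
    def test_grounds_to_annotated_concept(self, dehalogenase_lexicon, mini_go):
        prop = PropertyMention(
            kind="function", start=0, end=0, head="activity",
            np_tokens=("haloalkane", "dehalogenase", "activity"))
        gf = ground_function(prop, pool_of("P22643"),
                             dehalogenase_lexicon, mini_go)
        assert gf.go_id == "GO:0018786"
        assert gf.similarity == 1.0

    def test_ancestor_concepts_are_candidates(self, dehalogenase_lexicon,
                                              mini_go):
        prop = PropertyMention(
            kind="function", start=0, end=0, head="activity",
            np_tokens=("catalytic", "activity"))
        gf = ground_function(prop, pool_of("P22643"),
                             dehalogenase_lexicon, mini_go)
        assert gf.go_id == "GO:0003824"   # ancestor of the annotated term

    def test_no_overlap_returns_none(self, dehalogenase_lexicon, mini_go):
        prop = PropertyMention(
            kind="function", start=0, end=0, head="affinity",
            np_tokens=("substrate", "affinity"))
        assert ground_function(prop, pool_of("P22643"),
                               dehalogenase_lexicon, mini_go) is None

    def test_unannotated_pool_returns_none(self, mini_go):
        lex = lex_with(P9="M" * 40)
        prop = PropertyMention(
            kind="function", start=0, end=0, head="activity",
            np_tokens=("activity",))
        assert ground_function(prop, pool_of("P9"), lex, mini_go) is None
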