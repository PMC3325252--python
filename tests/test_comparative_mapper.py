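import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bes_survey.core_io import AlignmentHit, GenomicInterval
from bes_survey.comparative_mapper import (
    GeneModel,
    OrthologPair,
    PAIRED,
    Placement,
    SINGLET,
    best_placement,
    call_pairs,
    coding_overlap,
    collinearity_blocks,
    filter_hits,
    gene_density,
    ortholog_pairs,
    rescue_mate,
)
from oracles import brute_force_longest_chain


def hit(identity=80.0, evalue=1e-30, q_span=(1, 600), score=100.0, subject="chr1", s=(1000, 1600)):
    return AlignmentHit(
        "read1", subject, identity, q_span[1] - q_span[0] + 1, 0, 0,
        q_span[0], q_span[1], s[0], s[1], evalue, score,
    )


class TestFilterHits:
    READ_LENGTHS = {"read1": 1000}

    @pytest.mark.parametrize(
        "identity,evalue,q_span,passes",
        [
            (80.0, 1e-30, (1, 600), True),     # all three satisfied
            (70.0, 1e-30, (1, 600), False),    # identity bound
            (80.0, 1e-10, (1, 600), False),    # E bound
            (80.0, 1e-30, (1, 500), False),    # coverage bound (0.5, not >)
            (75.0, 1e-30, (1, 600), True),     # identity boundary inclusive
        ],
    )
    def test_three_filters(self, identity, evalue, q_span, passes):
        out = filter_hits([hit(identity, evalue, q_span)], self.READ_LENGTHS)
        assert bool(out) is passes

    def test_unknown_read_rejected(self):
        with pytest.raises(KeyError, match="read1"):
            filter_hits([hit()], {"other": 500})

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 100), st.floats(1e-40, 1), st.integers(1, 1000)
            ),
            max_size=30,
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_every_survivor_passes_all_filters(self, raw):
        hits = [hit(i, e, (1, span)) for i, e, span in raw]
        for h in filter_hits(hits, self.READ_LENGTHS):
            q0, q1 = h.query_interval()
            assert h.pct_identity >= 75.0
            assert h.evalue < 1e-20
            assert (q1 - q0) / 1000 > 0.5


class TestBestPlacement:
    def test_highest_score_wins(self):
        a, b = hit(score=100.0), hit(score=90.0)
        assert best_placement([a, b]) is a

    def test_tie_broken_by_reference_id(self):
        a, b = hit(subject="chr2"), hit(subject="chr1")
        assert best_placement([a, b]) is b

    def test_single_hit_is_its_own_best(self):
        a = hit()
        assert best_placement([a]) is a

    def test_tie_on_everything_takes_leftmost(self):
        a, b = hit(s=(5000, 5600)), hit(s=(1000, 1600))
        assert best_placement([a, b]) is b


def place(read_id, seq_id, start, end, coding=True):
    return Placement(
        read_id=read_id,
        interval=GenomicInterval(seq_id, start, end),
        score=100.0,
        identity=99.0,
        coverage_of_read=0.9,
        in_coding=coding,
    )


class TestCallPairs:
    def test_ends_within_insert_constraint_pair(self):
        placements = {
            "c1.f": place("c1.f", "chr1", 100_000, 100_800),
            "c1.r": place("c1.r", "chr1", 449_200, 450_000),
        }
        pairs, singlets = call_pairs(placements, {"c1": ("c1.f", "c1.r")})
        assert len(pairs) == 1 and not singlets
        assert pairs[0].span == 350_000
        assert placements["c1.f"].category == PAIRED

    def test_distant_ends_become_singlets(self):
        placements = {
            "c1.f": place("c1.f", "chr1", 0, 800),
            "c1.r": place("c1.r", "chr1", 700_000, 700_800),
        }
        pairs, singlets = call_pairs(placements, {"c1": ("c1.f", "c1.r")})
        assert not pairs and len(singlets) == 2
        assert all(p.category == SINGLET for p in singlets)

    def test_different_chromosomes_never_pair(self):
        placements = {
            "c1.f": place("c1.f", "chr1", 0, 800),
            "c1.r": place("c1.r", "chr2", 100, 900),
        }
        pairs, singlets = call_pairs(placements, {"c1": ("c1.f", "c1.r")})
        assert not pairs and len(singlets) == 2

    def test_pair_count_bounded_by_clones(self):
        placements = {}
        clone_map = {}
        for i in range(5):
            placements[f"c{i}.f"] = place(f"c{i}.f", "chr1", i * 1000, i * 1000 + 500)
            placements[f"c{i}.r"] = place(f"c{i}.r", "chr1", i * 1000 + 600, i * 1000 + 900)
            clone_map[f"c{i}"] = (f"c{i}.f", f"c{i}.r")
        pairs, _ = call_pairs(placements, clone_map)
        assert len(pairs) == 5 <= len(clone_map)


class TestRescue:
    def _reference(self, rng):
        return "".join(rng.choice("ACGT") for _ in range(300_000))

    def test_intergenic_mate_rescued_downstream(self):
        rng = random.Random(0)
        ref = {"chr1": self._reference(rng)}
        mate_seq = ref["chr1"][250_000:250_700]
        placed = place("c1.f", "chr1", 50_000, 50_600)
        rescued = rescue_mate(placed, ("c1.r", mate_seq), ref, max_insert=500_000)
        assert rescued is not None
        assert not rescued.in_coding
        assert abs(rescued.interval.start - 250_000) < 50

    def test_mate_from_elsewhere_not_rescued(self):
        rng = random.Random(1)
        ref = {"chr1": self._reference(rng)}
        foreign = "".join(rng.choice("ACGT") for _ in range(700))
        placed = place("c1.f", "chr1", 50_000, 50_600)
        assert rescue_mate(placed, ("c1.r", foreign), ref) is None

    def test_rescue_requires_coding_partner(self):
        rng = random.Random(2)
        ref = {"chr1": self._reference(rng)}
        placed = place("c1.f", "chr1", 50_000, 50_600, coding=False)
        with pytest.raises(ValueError, match="coding"):
            rescue_mate(placed, ("c1.r", ref["chr1"][:700]), ref)


class TestCodingOverlap:
    GENES = [GenomicInterval("chr1", 1000, 2000), GenomicInterval("chr1", 5000, 7000)]

    def test_all_inside(self):
        ps = [place("a", "chr1", 1100, 1500), place("b", "chr1", 5500, 6000)]
        assert coding_overlap(ps, self.GENES) == 100.0

    def test_none_inside(self):
        ps = [place("a", "chr1", 3000, 3500)]
        assert coding_overlap(ps, self.GENES) == 0.0

    def test_three_of_four(self):
        ps = [
            place("a", "chr1", 1100, 1500),
            place("b", "chr1", 5500, 6000),
            place("c", "chr1", 1900, 2100),  # partial overlap counts
            place("d", "chr1", 3000, 3400),
        ]
        assert coding_overlap(ps, self.GENES) == 75.0


def op(a, b):
    return OrthologPair(pos_a=a, pos_b=b, strand_a="+", strand_b="+")


class TestCollinearity:
    def test_identity_order_single_block(self):
        blocks, rest = collinearity_blocks([op(i, i) for i in range(1, 6)])
        assert len(blocks) == 1 and blocks[0].orientation == "same"
        assert len(blocks[0]) == 5 and not rest

    def test_terminal_inversion_splits_into_two_blocks(self):
        pairs = [op(1, 1), op(2, 2), op(3, 5), op(4, 4), op(5, 3)]
        blocks, rest = collinearity_blocks(pairs, max_gap=2)
        assert [(len(b), b.orientation) for b in blocks] == [
            (2, "same"),
            (3, "inverted"),
        ]
        assert not rest

    def test_empty_list(self):
        assert collinearity_blocks([]) == ([], [])

    def test_duplicate_positions_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            collinearity_blocks([op(1, 1), op(1, 2)])

    @given(st.permutations(list(range(1, 10))), st.integers(1, 3))
    @settings(max_examples=60, deadline=None)
    def test_first_block_matches_longest_chain_oracle(self, perm, max_gap):
        pairs = [op(i + 1, b) for i, b in enumerate(perm)]
        blocks, rest = collinearity_blocks(pairs, max_gap=max_gap)
        expected = brute_force_longest_chain(
            [(p.pos_a, p.pos_b) for p in pairs], max_gap=max_gap
        )
        longest = max((len(b) for b in blocks), default=1)
        assert longest == max(expected, 1) or (expected < 2 and not blocks)
        # every pair is either chained or reported as rearranged
        assert sum(len(b) for b in blocks) + len(rest) == len(pairs)


class TestGeneDensity:
    def test_printed_locus_density(self):
        assert gene_density(439, 7.2e6) == 16.4

    def test_single_gene(self):
        assert gene_density(1, 10_000) == 10.0

    def test_gene_model_count_density(self):
        assert gene_density(451, 7.2e6) == 16.0

    def test_no_loci_undefined(self):
        assert gene_density(0, 10_000) is None


def test_reciprocal_best_orthologs_identity_case():
    rng = random.Random(3)
    aas = "ARNDCQEGHILKMFPSTWYV"
    genes_a = []
    genes_b = []
    for i in range(6):
        pep = "M" + "".join(rng.choice(aas) for _ in range(80))
        iv_a = GenomicInterval("g", i * 1000, i * 1000 + 240, "+")
        iv_b = GenomicInterval("h", i * 2000, i * 2000 + 240, "+")
        genes_a.append(GeneModel(f"a{i}", iv_a, pep))
        genes_b.append(GeneModel(f"b{i}", iv_b, pep))
    pairs = ortholog_pairs(genes_a, genes_b)
    assert [(p.pos_a, p.pos_b) for p in pairs] == [(i, i) for i in range(6)]
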