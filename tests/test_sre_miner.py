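import random

import numpy as np
import pytest

from bes_survey.alignment_engine import revcomp, smith_waterman
from bes_survey.sre_miner import (
    Segment,
    SelfMatchProfile,
    SreCandidate,
    build_consensus,
    extrapolate_copies,
    filter_known,
    matched_segments,
    select_repetitive,
    self_compare,
)


def random_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def mutate(rng, seq, rate):
    return "".join(
        rng.choice([b for b in "ACGT" if b != c]) if rng.random() < rate else c
        for c in seq
    )


class TestSelfCompare:
    def test_shared_planted_segment_counts_all_partners(self):
        rng = random.Random(0)
        elem = random_dna(rng, 150)
        reads = []
        for i in range(8):
            # copies at ~2.5% divergence from consensus are ~95% identical
            # to each other, comfortably above the 90% window rule
            copy = mutate(rng, elem, 0.025)
            reads.append(
                (f"r{i}", random_dna(rng, 200) + copy + random_dna(rng, 200))
            )
        profile = self_compare(reads, evalue_cutoff=1e-10)
        assert all(profile.counts[f"r{i}"] == 7 for i in range(8))

    def test_unique_reads_have_no_matches(self):
        rng = random.Random(1)
        reads = [(f"r{i}", random_dna(rng, 500)) for i in range(12)]
        profile = self_compare(reads)
        assert all(c == 0 for c in profile.counts.values())

    def test_pair_symmetry(self):
        rng = random.Random(2)
        elem = random_dna(rng, 200)
        reads = [
            (f"r{i}", random_dna(rng, 100) + mutate(rng, elem, 0.04) + random_dna(rng, 100))
            for i in range(6)
        ]
        profile = self_compare(reads, evalue_cutoff=1e-10)
        for a, b in profile.pair_matches:
            assert a < b  # stored canonically, i.e. symmetric by construction
        # counts derive from the symmetric pair set
        for rid, _ in reads:
            derived = sum(1 for p in profile.pair_matches if rid in p)
            assert derived == profile.counts[rid]

    def test_masked_copies_do_not_match(self):
        rng = random.Random(3)
        elem = random_dna(rng, 200)
        reads = [
            (
                f"r{i}",
                random_dna(rng, 100) + mutate(rng, elem, 0.04).lower() + random_dna(rng, 100),
            )
            for i in range(6)
        ]
        profile = self_compare(reads)
        assert all(c == 0 for c in profile.counts.values())

    def test_window_below_seed_rejected(self):
        with pytest.raises(ValueError, match="window"):
            self_compare([("r", "ACGT" * 100)], window=10, seed_len=14)

    def test_read_order_does_not_change_counts(self):
        rng = random.Random(4)
        elem = random_dna(rng, 180)
        reads = [
            (f"r{i}", random_dna(rng, 150) + mutate(rng, elem, 0.03) + random_dna(rng, 150))
            for i in range(7)
        ]
        p1 = self_compare(reads, evalue_cutoff=1e-10)
        p2 = self_compare(list(reversed(reads)), evalue_cutoff=1e-10)
        assert p1.counts == p2.counts


class TestSelect:
    def test_six_match_rule(self):
        profile = SelfMatchProfile(
            counts={"a": 7, "b": 6, "c": 5}, pair_matches=set(), segments={}
        )
        assert select_repetitive(profile) == ["a", "b"]

    def test_empty_profile(self):
        profile = SelfMatchProfile(counts={}, pair_matches=set(), segments={})
        assert select_repetitive(profile) == []

    def test_lowering_support_never_shrinks_selection(self):
        counts = {f"r{i}": i for i in range(12)}
        profile = SelfMatchProfile(counts=counts, pair_matches=set(), segments={})
        prev: set[str] = set()
        for support in range(11, -1, -1):
            sel = set(select_repetitive(profile, min_support=support))
            assert prev <= sel
            prev = sel


def _segments_from_copies(rng, elem, n, divergence=0.05, prefix="r"):
    segs = []
    for i in range(n):
        segs.append(
            Segment(f"{prefix}{i}", 0, len(elem), mutate(rng, elem, divergence))
        )
    return segs


class TestConsensus:
    def test_planted_family_recovered_at_high_identity(self):
        rng = random.Random(5)
        elem = random_dna(rng, 200)
        segs = _segments_from_copies(rng, elem, 10, 0.05)
        (cand,) = build_consensus(segs, min_support=6)
        aln = smith_waterman(cand.consensus, elem)
        assert aln.pct_identity >= 98.0
        assert aln.aln_len >= 190
        assert cand.support == 10

    def test_distinct_families_stay_separate(self):
        rng = random.Random(6)
        a = random_dna(rng, 220)
        b = mutate(rng, a, 0.4)  # ~60% mutual identity
        segs = _segments_from_copies(rng, a, 8, 0.03, "a") + _segments_from_copies(
            rng, b, 8, 0.03, "b"
        )
        cands = build_consensus(segs, min_support=6)
        assert len(cands) == 2
        for cand in cands:
            sa = smith_waterman(cand.consensus, a).score if smith_waterman(cand.consensus, a) else 0
            sb = smith_waterman(cand.consensus, b).score if smith_waterman(cand.consensus, b) else 0
            # a clean consensus matches one family far better than the other
            assert max(sa, sb) > 2 * min(sa, sb)

    def test_short_element_below_size_floor(self):
        rng = random.Random(7)
        elem = random_dna(rng, 50)
        segs = _segments_from_copies(rng, elem, 10, 0.02)
        assert build_consensus(segs, min_support=6) == []

    def test_under_supported_cluster_dropped(self):
        rng = random.Random(8)
        elem = random_dna(rng, 200)
        segs = _segments_from_copies(rng, elem, 5, 0.03)
        assert build_consensus(segs, min_support=6) == []


class TestFilterKnown:
    def test_library_copy_removed(self):
        rng = random.Random(9)
        gypsy = random_dna(rng, 300)
        cand = SreCandidate("SRE0001", gypsy[:200], 8)
        assert filter_known([cand], {"lib": [("gypsy", gypsy)]}) == []

    def test_unrelated_candidate_retained(self):
        rng = random.Random(10)
        cand = SreCandidate("SRE0001", random_dna(rng, 200), 8)
        retained = filter_known([cand], {"lib": [("gypsy", random_dna(rng, 300))]})
        assert retained == [cand]

    def test_exactly_known_subset_removed(self):
        rng = random.Random(11)
        known = random_dna(rng, 250)
        cands = [
            SreCandidate("SRE0001", mutate(rng, known[:220], 0.05), 8),
            SreCandidate("SRE0002", random_dna(rng, 220), 8),
            SreCandidate("SRE0003", random_dna(rng, 150), 8),
        ]
        retained = filter_known(cands, {"lib": [("k", known)]})
        assert [c.sre_id for c in retained] == ["SRE0002", "SRE0003"]

    def test_translated_match_removed(self):
        from bes_survey.synthetic_data import _back_translate

        rng = np.random.default_rng(1)
        pep = "MGTKWLVDEQRAHSNYFCIPMGTKWLVDEQRAHSNYFCIP"
        cand = SreCandidate("SRE0001", _back_translate(rng, pep, 0.5), 8)
        assert filter_known([cand], protein_dbs={"prot": [("p1", pep)]}) == []


class TestExtrapolate:
    def test_most_frequent_family_copy_number(self):
        assert extrapolate_copies(548, 0.164) == 3341

    @pytest.mark.parametrize("support,fraction,expected", [(10, 1.0, 10), (10, 0.5, 20)])
    def test_simple_ratios(self, support, fraction, expected):
        assert extrapolate_copies(support, fraction) == expected

    def test_inverse_scaling(self):
        assert extrapolate_copies(30, 0.25) == 2 * extrapolate_copies(30, 0.5)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_copies(10, 0.0)
        with pytest.raises(ValueError):
            extrapolate_copies(10, 1.5)


def test_matched_segments_isolate_supported_region():
    """Bases backed by many partners become segments; flanks do not."""
    spans = {f"p{i}": (100, 300) for i in range(7)}
    segments = {"r0": [(p, a, b) for p, (a, b) in spans.items()] + [("q", 0, 450)]}
    profile = SelfMatchProfile(
        counts={"r0": 8}, pair_matches=set(), segments=segments
    )
    reads = {"r0": "ACGT" * 150}
    (seg,) = matched_segments(profile, reads, ["r0"], min_partner_support=6)
    assert (seg.start, seg.end) == (100, 300)
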