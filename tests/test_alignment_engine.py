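import random

import numpy as np
import pytest

from bes_survey.alignment_engine import (
    ScoringScheme,
    local_align,
    protein_scheme,
    revcomp,
    six_frame_segments,
    smith_waterman,
    smith_waterman_score,
    translated_align,
)
from oracles import brute_force_sw


def random_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestScoringScheme:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ScoringScheme(match=0)
        with pytest.raises(ValueError):
            ScoringScheme(gap_open=1)
        with pytest.raises(ValueError):
            ScoringScheme(lam=0)

    def test_evalue_monotone_in_score_and_search_space(self):
        s = ScoringScheme()
        assert s.evalue(50, 1e3, 1e3) < s.evalue(40, 1e3, 1e3)
        assert s.evalue(50, 1e4, 1e3) > s.evalue(50, 1e3, 1e3)


class TestSmithWaterman:
    def test_matches_brute_force_on_random_pairs(self):
        rng = random.Random(42)
        for _ in range(80):
            m, n = rng.randint(5, 120), rng.randint(5, 120)
            q, s = random_dna(rng, m), random_dna(rng, n)
            if rng.random() < 0.5:
                L = rng.randint(5, min(m, n))
                seg = random_dna(rng, L)
                qi, si = rng.randint(0, m - L), rng.randint(0, n - L)
                q = q[:qi] + seg + q[qi + L:]
                s = s[:si] + seg + s[si + L:]
            assert smith_waterman_score(q, s) == brute_force_sw(q, s)

    def test_alignment_columns_account_for_score(self):
        rng = random.Random(1)
        scheme = ScoringScheme()
        for _ in range(40):
            q, s = random_dna(rng, 80), random_dna(rng, 80)
            aln = smith_waterman(q, s, scheme)
            if aln is None:
                continue
            score = aln.n_match * scheme.match + aln.n_mismatch * scheme.mismatch
            gap_len = int(np.count_nonzero(aln.columns >= 2))
            score += aln.gap_opens * scheme.gap_open + gap_len * scheme.gap_extend
            assert score == aln.score

    def test_score_symmetry(self):
        rng = random.Random(7)
        for _ in range(20):
            q, s = random_dna(rng, 60), random_dna(rng, 90)
            assert smith_waterman_score(q, s) == smith_waterman_score(s, q)

    def test_n_matches_nothing(self):
        assert smith_waterman("NNNN", "NNNN") is None


class TestLocalAlign:
    def test_self_hit_full_span(self):
        seq = "ATGCCGTAGCTTAGGCATCAGGACTT" * 4
        hits = local_align("q", seq, "s", seq, evalue_cutoff=1e3)
        top = max(hits, key=lambda h: h.bit_score)
        assert top.pct_identity == 100.0
        assert (top.q_start, top.q_end) == (1, len(seq))
        assert (top.s_start, top.s_end) == (1, len(seq))
        assert top.subject_strand == "+"

    def test_reverse_complement_found_on_minus_strand(self):
        rng = random.Random(3)
        seq = random_dna(rng, 150)
        hits = local_align("q", seq, "s", revcomp(seq), evalue_cutoff=1e3)
        top = max(hits, key=lambda h: h.bit_score)
        assert top.subject_strand == "-"
        assert top.pct_identity == 100.0

    def test_seeded_equals_full_dp_on_small_pairs(self):
        rng = random.Random(11)
        for _ in range(40):
            q = random_dna(rng, rng.randint(30, 200))
            s = random_dna(rng, rng.randint(30, 200))
            hits = local_align(
                "q", q, "s", s, seed_len=8, evalue_cutoff=float("inf"),
                both_strands=False,
            )
            expected = brute_force_sw(q, s)
            best = max((round(h.bit_score) for h in hits), default=0)
            got_raw = max(
                (h for h in hits), key=lambda h: h.bit_score, default=None
            )
            if expected == 0:
                continue
            scheme = ScoringScheme()
            assert got_raw is not None
            # recover raw score from the bit score
            raw = (got_raw.bit_score * np.log(2) + np.log(scheme.k)) / scheme.lam
            assert round(raw) == expected

    def test_seed_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError, match="seed_len"):
            local_align("q", "ACGT", "s", "ACGTACGTACGTACGT", seed_len=12)

    def test_seeded_path_finds_planted_repeat_in_long_subject(self):
        rng = random.Random(19)
        seg = random_dna(rng, 300)
        subject = random_dna(rng, 3000) + seg + random_dna(rng, 3000)
        query = random_dna(rng, 200) + seg + random_dna(rng, 200)
        hits = local_align("q", query, "s", subject, evalue_cutoff=1e-10)
        top = max(hits, key=lambda h: h.bit_score)
        q0, q1 = top.query_interval()
        assert q1 - q0 >= 290
        assert top.pct_identity > 99.0


class TestTranslatedAlign:
    def test_exact_back_translation_frame_plus_one(self):
        from bes_survey.synthetic_data import _back_translate

        rng = np.random.default_rng(0)
        pep = "MKLVTGAERWIHQDFNCSPYMKLVTGAERW"
        nuc = _back_translate(rng, pep, 0.5)
        (hit,) = translated_align("q", nuc, "s", pep, evalue_cutoff=1e3)
        assert hit.frame == 1
        assert hit.pct_identity == 100.0
        assert hit.query_interval() == (0, len(nuc))

    def test_reverse_complement_hits_minus_frame(self):
        from bes_survey.synthetic_data import _back_translate

        rng = np.random.default_rng(0)
        pep = "MKLVTGAERWIHQDFNCSPYMKLVTGAERW"
        nuc = revcomp(_back_translate(rng, pep, 0.5))
        (hit,) = translated_align("q", nuc, "s", pep, evalue_cutoff=1e3)
        assert hit.frame < 0
        assert hit.pct_identity == 100.0

    def test_protein_scores_match_brute_force(self):
        from Bio.Align import substitution_matrices

        mat = substitution_matrices.load("BLOSUM62")
        scheme = protein_scheme()
        rng = random.Random(2)
        aas = "ARNDCQEGHILKMFPSTWYV"
        for _ in range(30):
            a = "".join(rng.choice(aas) for _ in range(20))
            b = "".join(rng.choice(aas) for _ in range(20))
            aln = smith_waterman(a, b, scheme)
            got = aln.score if aln else 0
            # independent plain-python DP with matrix lookups
            m, n = len(a), len(b)
            NEG = -(10**9)
            H = [[0] * (n + 1) for _ in range(m + 1)]
            E = [[NEG] * (n + 1) for _ in range(m + 1)]
            F = [[NEG] * (n + 1) for _ in range(m + 1)]
            best = 0
            for i in range(1, m + 1):
                for j in range(1, n + 1):
                    E[i][j] = max(E[i][j - 1] - 1, H[i][j - 1] - 12)
                    F[i][j] = max(F[i - 1][j] - 1, H[i - 1][j] - 12)
                    sub = int(mat[a[i - 1], b[j - 1]])
                    H[i][j] = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
                    best = max(best, H[i][j])
            assert got == best

    def test_stops_split_frames(self):
        # TAA in frame +1 splits the translation into two segments
        segs = six_frame_segments("ATGAAATAAATGCCC")
        plus1 = [s for f, _off, s in segs if f == 1]
        assert "MK" in plus1 and "MP" in plus1

    def test_short_query_rejected(self):
        with pytest.raises(ValueError):
            translated_align("q", "AC", "s", "MKLV")
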