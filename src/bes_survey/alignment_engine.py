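"""Seeded local alignment (nucleotide and translated) with E-values.

The core is an affine-gap Smith-Waterman computed with vectorised
row-scans: the insertion state within a row is a prefix-maximum scan, the
deletion state carries over from the previous row, so each row costs a few
numpy operations.  Large problems are first narrowed by exact k-mer seeds
clustered on diagonals; each cluster is aligned inside a padded window.
Small problems skip seeding and run the full dynamic program directly, so
the optimal local alignment is always found there.

Statistics follow the Karlin-Altschul form E = K.m.n.exp(-lambda.S) and
bit score S' = (lambda.S - ln K) / ln 2, with default (lambda, K) the
standard ungapped constants for the default scoring — an approximation,
documented as such; E-values are comparable within a run, not to other
tools.  A gap of length L costs gap_open + L x gap_extend.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .core_io import AlignmentHit

try:  # numba accelerates the DP kernel; the numpy scan is the fallback
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

_NEG = -(1 << 20)

# column codes in LocalAlignment.columns
COL_MATCH, COL_MISMATCH, COL_GAP_Q, COL_GAP_S = 0, 1, 2, 3

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ScoringScheme:
    """Alignment scoring plus the Karlin-Altschul constants used for E.

    ``matrix`` selects a named substitution matrix (protein mode);
    nucleotide mode uses match/mismatch scores.
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    lam: float = 1.28
    k: float = 0.46
    matrix: str | None = None

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("lambda and K must be > 0")

    def bit_score(self, score: float) -> float:
        return (self.lam * score - math.log(self.k)) / math.log(2.0)

    def evalue(self, score: float, m: float, n: float) -> float:
        return self.k * m * n * math.exp(-self.lam * score)


def protein_scheme() -> ScoringScheme:
    """BLOSUM62 scoring with gapped-search constants."""
    return ScoringScheme(
        gap_open=-11, gap_extend=-1, lam=0.267, k=0.041, matrix="BLOSUM62"
    )


_MATRIX_CACHE: dict[str, tuple[np.ndarray, dict[str, int]]] = {}


def _load_matrix(name: str) -> tuple[np.ndarray, dict[str, int]]:
    if name not in _MATRIX_CACHE:
        mat = substitution_matrices.load(name)
        alpha = "".join(mat.alphabet)
        arr = np.array(mat, dtype=np.int32)
        _MATRIX_CACHE[name] = (arr, {c: i for i, c in enumerate(alpha)})
    return _MATRIX_CACHE[name]


def _encode_nuc(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def _encode_protein(seq: str, index: dict[str, int]) -> np.ndarray:
    x = index.get("X", 0)
    return np.array([index.get(c, x) for c in seq.upper()], dtype=np.int32)


@dataclass
class LocalAlignment:
    """A traced-back local alignment between two explicit strings.

    Coordinates are 0-based half-open on the strings that were aligned.
    ``columns`` codes each alignment column: 0 match, 1 mismatch, 2 gap in
    query (subject base consumed), 3 gap in subject.
    """

    score: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    columns: np.ndarray

    @property
    def n_match(self) -> int:
        return int(np.count_nonzero(self.columns == COL_MATCH))

    @property
    def n_mismatch(self) -> int:
        return int(np.count_nonzero(self.columns == COL_MISMATCH))

    @property
    def aln_len(self) -> int:
        return len(self.columns)

    @property
    def gap_opens(self) -> int:
        cols = self.columns
        opens = 0
        prev = -1
        for c in cols:
            if c in (COL_GAP_Q, COL_GAP_S) and c != prev:
                opens += 1
            prev = c
        return opens

    @property
    def pct_identity(self) -> float:
        return 100.0 * self.n_match / self.aln_len if self.aln_len else 0.0


if _HAVE_NUMBA:

    @_njit(cache=False)
    def _dp_kernel(SUB, go, ge, NEG):  # pragma: no cover - jitted
        m, n = SUB.shape
        H = np.zeros((m + 1, n + 1), np.int32)
        E = np.full((m + 1, n + 1), NEG, np.int32)
        F = np.full((m + 1, n + 1), NEG, np.int32)
        for i in range(1, m + 1):
            for j in range(1, n + 1):
                e = max(E[i, j - 1] + ge, H[i, j - 1] + go + ge)
                f = max(F[i - 1, j] + ge, H[i - 1, j] + go + ge)
                h = max(0, H[i - 1, j - 1] + SUB[i - 1, j - 1])
                if e > h:
                    h = e
                if f > h:
                    h = f
                E[i, j] = e
                F[i, j] = f
                H[i, j] = h
        return H, E, F


def _dp_matrices(q: np.ndarray, s: np.ndarray, scheme: ScoringScheme):
    """Fill H, E, F for affine local alignment, row-scan vectorised."""
    m, n = len(q), len(s)
    go, ge = scheme.gap_open, scheme.gap_extend
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), _NEG, dtype=np.int32)
    F = np.full((m + 1, n + 1), _NEG, dtype=np.int32)
    if scheme.matrix is None:
        # q, s are uint8 base codes; N never matches anything (incl. N)
        eq = q[:, None] == s[None, :]
        eq[q == ord("N"), :] = False
        eq[:, s == ord("N")] = False
        SUB = np.where(eq, np.int32(scheme.match), np.int32(scheme.mismatch))
    else:
        mat, _ = _load_matrix(scheme.matrix)
        SUB = mat[np.ix_(q, s)]

    if _HAVE_NUMBA:
        return _dp_kernel(
            np.ascontiguousarray(SUB, dtype=np.int32),
            np.int32(go),
            np.int32(ge),
            np.int32(_NEG),
        )

    def sub_row(i: int) -> np.ndarray:
        return SUB[i]

    ge_ramp = ge * np.arange(1, n + 1, dtype=np.int32)
    tmp = np.empty(n, dtype=np.int32)
    diag = np.empty(n, dtype=np.int32)
    hd = np.empty(n, dtype=np.int32)
    c = np.empty(n, dtype=np.int32)
    for i in range(1, m + 1):
        h_prev = H[i - 1]
        f_i = F[i]
        np.add(h_prev[1:], go, out=tmp)
        np.maximum(F[i - 1, 1:], tmp, out=f_i[1:])
        f_i[1:] += ge
        np.add(h_prev[:n], sub_row(i - 1), out=diag)
        np.maximum(diag, f_i[1:], out=hd)
        np.maximum(hd, 0, out=hd)
        # E within the row is a prefix-max scan over open points
        c[0] = 0  # opening from column 0 (H=0)
        if n > 1:
            np.subtract(hd[:-1], ge_ramp[:-1], out=c[1:])
        np.maximum.accumulate(c, out=c)
        e_i = E[i]
        np.add(c, ge_ramp, out=e_i[1:])
        e_i[1:] += go
        np.maximum(hd, e_i[1:], out=H[i, 1:])
    return H, E, F


def _traceback(
    q: np.ndarray,
    s: np.ndarray,
    scheme: ScoringScheme,
    H: np.ndarray,
    E: np.ndarray,
    F: np.ndarray,
) -> LocalAlignment | None:
    best = int(H.max())
    if best <= 0:
        return None
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    i, j = int(i), int(j)
    q_end, s_end = i, j
    go, ge = scheme.gap_open, scheme.gap_extend
    if scheme.matrix is None:

        def sub(i: int, j: int) -> int:
            a, b = q[i - 1], s[j - 1]
            if a == ord("N") or b == ord("N") or a != b:
                return scheme.mismatch
            return scheme.match

    else:
        mat, _ = _load_matrix(scheme.matrix)

        def sub(i: int, j: int) -> int:
            return int(mat[q[i - 1], s[j - 1]])

    cols: list[int] = []
    state = "H"
    while True:
        if state == "H":
            h = int(H[i, j])
            if h == 0:
                break
            if i > 0 and j > 0 and h == int(H[i - 1, j - 1]) + sub(i, j):
                cols.append(COL_MATCH if sub(i, j) > 0 else COL_MISMATCH)
                i -= 1
                j -= 1
            elif h == int(E[i, j]):
                state = "E"
            elif h == int(F[i, j]):
                state = "F"
            else:  # pragma: no cover - DP consistency guard
                raise AssertionError("inconsistent traceback")
        elif state == "E":
            cols.append(COL_GAP_Q)
            if j > 1 and int(E[i, j]) == int(E[i, j - 1]) + ge:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:  # F
            cols.append(COL_GAP_S)
            if i > 1 and int(F[i, j]) == int(F[i - 1, j]) + ge:
                i -= 1
            else:
                i -= 1
                state = "H"
    cols.reverse()
    columns = np.array(cols, dtype=np.int8)
    # trim terminal gap columns (cannot occur in an optimal SW path, but
    # keep the contract explicit)
    return LocalAlignment(
        score=best, q_start=i, q_end=q_end, s_start=j, s_end=s_end, columns=columns
    )


def smith_waterman(
    query: str | np.ndarray, subject: str | np.ndarray, scheme: ScoringScheme | None = None
) -> LocalAlignment | None:
    """Optimal local alignment of two sequences (full dynamic program)."""
    scheme = scheme or ScoringScheme()
    if scheme.matrix is None:
        q = _encode_nuc(query) if isinstance(query, str) else query
        s = _encode_nuc(subject) if isinstance(subject, str) else subject
    else:
        _, index = _load_matrix(scheme.matrix)
        q = _encode_protein(query, index) if isinstance(query, str) else query
        s = _encode_protein(subject, index) if isinstance(subject, str) else subject
    if len(q) == 0 or len(s) == 0:
        return None
    H, E, F = _dp_matrices(q, s, scheme)
    return _traceback(q, s, scheme, H, E, F)


def smith_waterman_score(
    query: str, subject: str, scheme: ScoringScheme | None = None
) -> int:
    """Optimal local alignment score only."""
    aln = smith_waterman(query, subject, scheme)
    return aln.score if aln else 0


# --- seeding ------------------------------------------------------------


def kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    """Positions of each ACGT-only k-mer in ``seq`` (N/masked excluded)."""
    out: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer and kmer.isupper():
            out[kmer].append(i)
    return dict(out)


def seed_matches(query: str, subject_index: dict[str, list[int]], k: int) -> list[tuple[int, int]]:
    """(query_pos, subject_pos) pairs of exact shared k-mers."""
    pairs = []
    for i in range(len(query) - k + 1):
        kmer = query[i : i + k]
        if "N" in kmer or not kmer.isupper():
            continue
        for j in subject_index.get(kmer, ()):
            pairs.append((i, j))
    return pairs


def cluster_seeds(
    seeds: Sequence[tuple[int, int]],
    k: int,
    band: int = 16,
    max_gap: int = 200,
) -> list[tuple[int, int, int, int, int]]:
    """Group seeds into diagonal clusters.

    Returns (q_lo, q_hi, s_lo, s_hi, n_seeds) per cluster; seeds join a
    cluster when their diagonals differ by <= ``band`` and their query
    positions by <= ``max_gap``.
    """
    if not seeds:
        return []
    ordered = sorted(seeds, key=lambda t: (t[1] - t[0], t[0]))
    clusters = []
    cur = [ordered[0]]
    for qpos, spos in ordered[1:]:
        pd = cur[-1][1] - cur[-1][0]
        if (spos - qpos) - pd <= band and abs(qpos - cur[-1][0]) <= max_gap:
            cur.append((qpos, spos))
        else:
            clusters.append(cur)
            cur = [(qpos, spos)]
    clusters.append(cur)
    out = []
    for cl in clusters:
        qs = [a for a, _ in cl]
        ss = [b for _, b in cl]
        out.append((min(qs), max(qs) + k, min(ss), max(ss) + k, len(cl)))
    return out


def _merge_windows(
    windows: list[tuple[int, int, int, int]]
) -> list[tuple[int, int, int, int]]:
    merged: list[list[int]] = []
    for w in sorted(windows):
        for m in merged:
            if w[0] < m[1] and m[0] < w[1] and w[2] < m[3] and m[2] < w[3]:
                m[0], m[1] = min(m[0], w[0]), max(m[1], w[1])
                m[2], m[3] = min(m[2], w[2]), max(m[3], w[3])
                break
        else:
            merged.append(list(w))
    return [tuple(m) for m in merged]


def _dedupe_hits(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Keep the best-scoring hit among those covering the same region."""
    kept: list[AlignmentHit] = []
    for h in sorted(hits, key=lambda h: -h.bit_score):
        qs, qe = h.query_interval()
        ss, se = h.subject_interval()
        redundant = False
        for other in kept:
            oqs, oqe = other.query_interval()
            oss, ose = other.subject_interval()
            q_ov = max(0, min(qe, oqe) - max(qs, oqs))
            s_ov = max(0, min(se, ose) - max(ss, oss))
            if q_ov > 0.5 * (qe - qs) and s_ov > 0.5 * (se - ss):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def local_align(
    query_id: str,
    query: str,
    subject_id: str,
    subject: str,
    scheme: ScoringScheme | None = None,
    seed_len: int = 12,
    evalue_cutoff: float = 10.0,
    both_strands: bool = True,
    min_seeds: int = 1,
    full_dp_cells: int = 160_000,
    window_margin: int = 60,
    return_alignments: bool = False,
):
    """Seeded gapped local alignment of two nucleotide sequences.

    Hits below the E cutoff are reported as :class:`AlignmentHit` in
    tabular convention (minus-strand hits carry ``s_start > s_end``).
    Small problems (``len(q) x len(s) <= full_dp_cells``) are solved by the
    full dynamic program, so the optimum is exact there.  With
    ``return_alignments`` the traced :class:`LocalAlignment` objects are
    returned alongside each hit (minus-strand alignments are against the
    reverse-complemented subject).
    """
    scheme = scheme or ScoringScheme()
    if scheme.matrix is not None:
        raise ValueError("local_align is nucleotide-mode; use translated_align")
    if min(len(query), len(subject)) < seed_len:
        raise ValueError("seed_len exceeds the shorter sequence")
    query = query.upper()
    m, n = len(query), len(subject)
    results = []
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        subj = subject.upper() if strand == "+" else revcomp(subject.upper())
        if m * n <= full_dp_cells:
            windows = [(0, m, 0, n)]
        else:
            index = kmer_positions(subj, seed_len)
            seeds = seed_matches(query, index, seed_len)
            clusters = [
                c for c in cluster_seeds(seeds, seed_len) if c[4] >= min_seeds
            ]
            windows = _merge_windows(
                [
                    (
                        max(0, ql - window_margin),
                        min(m, qh + window_margin),
                        max(0, sl - window_margin),
                        min(n, sh + window_margin),
                    )
                    for ql, qh, sl, sh, _cnt in clusters
                ]
            )
        for ql, qh, sl, sh in windows:
            aln = smith_waterman(query[ql:qh], subj[sl:sh], scheme)
            if aln is None:
                continue
            aln = replace(
                aln,
                q_start=aln.q_start + ql,
                q_end=aln.q_end + ql,
                s_start=aln.s_start + sl,
                s_end=aln.s_end + sl,
            )
            ev = scheme.evalue(aln.score, m, n)
            if ev > evalue_cutoff:
                continue
            if strand == "+":
                s_start, s_end = aln.s_start + 1, aln.s_end
            else:  # map back to forward subject coordinates
                s_start, s_end = n - aln.s_start, n - aln.s_end + 1
            hit = AlignmentHit(
                query_id=query_id,
                subject_id=subject_id,
                pct_identity=aln.pct_identity,
                aln_len=aln.aln_len,
                mismatches=aln.n_mismatch,
                gap_opens=aln.gap_opens,
                q_start=aln.q_start + 1,
                q_end=aln.q_end,
                s_start=s_start,
                s_end=s_end,
                evalue=ev,
                bit_score=scheme.bit_score(aln.score),
            )
            results.append((hit, aln))
    deduped = _dedupe_hits([h for h, _ in results])
    by_id = {id(h): a for h, a in results}
    if return_alignments:
        return [(h, by_id[id(h)]) for h in deduped]
    return deduped


# --- translated search --------------------------------------------------


def six_frame_segments(nuc: str) -> list[tuple[int, int, str]]:
    """Stop-free peptide segments from all six frames.

    Returns (frame, aa_offset_in_frame, peptide) where frame is +1..+3 or
    -1..-3; minus frames translate the reverse complement.
    """
    nuc = nuc.upper()
    out = []
    for sign, seq in ((1, nuc), (-1, revcomp(nuc))):
        for off in range(3):
            usable = len(seq) - off
            if usable < 3:
                continue
            aa = str(Seq(seq[off : off + usable - usable % 3]).translate())
            pos = 0
            for seg in aa.split("*"):
                if seg:
                    out.append((sign * (off + 1), pos, seg))
                pos += len(seg) + 1
    return out


def _frame_nt_interval(
    frame: int, aa_lo: int, aa_hi: int, nuc_len: int
) -> tuple[int, int]:
    """0-based half-open nt interval on the forward query for aa span."""
    off = abs(frame) - 1
    lo = off + 3 * aa_lo
    hi = off + 3 * aa_hi
    if frame > 0:
        return lo, hi
    return nuc_len - hi, nuc_len - lo


def translated_align(
    query_id: str,
    nuc_query: str,
    subject_id: str,
    peptide: str,
    scheme: ScoringScheme | None = None,
    evalue_cutoff: float = 10.0,
    min_segment: int = 7,
) -> list[AlignmentHit]:
    """Align all six translated frames of a nucleotide query to a peptide.

    Frames with internal stops are split into stop-free segments; hit
    coordinates are reported in nucleotide space of the query with the
    frame recorded.  Subject coordinates are in residues.
    """
    if len(nuc_query) < 3:
        raise ValueError("query must be at least 3 nt")
    scheme = scheme or protein_scheme()
    if scheme.matrix is None:
        raise ValueError("translated_align needs a protein scoring matrix")
    m_eff = max(1.0, len(nuc_query) / 3.0)
    hits = []
    for frame, aa_off, seg in six_frame_segments(nuc_query):
        if len(seg) < min_segment:
            continue
        aln = smith_waterman(seg, peptide, scheme)
        if aln is None:
            continue
        ev = scheme.evalue(aln.score, m_eff, len(peptide))
        if ev > evalue_cutoff:
            continue
        nt_lo, nt_hi = _frame_nt_interval(
            frame, aa_off + aln.q_start, aa_off + aln.q_end, len(nuc_query)
        )
        hits.append(
            AlignmentHit(
                query_id=query_id,
                subject_id=subject_id,
                pct_identity=aln.pct_identity,
                aln_len=aln.aln_len,
                mismatches=aln.n_mismatch,
                gap_opens=aln.gap_opens,
                q_start=nt_lo + 1,
                q_end=nt_hi,
                s_start=aln.s_start + 1,
                s_end=aln.s_end,
                evalue=ev,
                bit_score=scheme.bit_score(aln.score),
                frame=frame,
            )
        )
    return _dedupe_hits(hits)


# --- shared candidate generation for database-style searches ------------


def build_kmer_postings(
    sequences: Iterable[tuple[str, str]], k: int
) -> dict[str, list[str]]:
    """k-mer -> [sequence ids containing it] (masked/N k-mers skipped)."""
    postings: dict[str, list[str]] = defaultdict(list)
    for name, seq in sequences:
        seen = set()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer or not kmer.isupper():
                continue
            if kmer not in seen:
                postings[kmer].append(name)
                seen.add(kmer)
    return dict(postings)


def candidate_subjects(
    query: str,
    postings: dict[str, list[str]],
    k: int,
    min_shared: int = 2,
    include_revcomp: bool = True,
) -> dict[str, int]:
    """Subject ids sharing >= min_shared distinct k-mers with the query."""
    counts: dict[str, int] = defaultdict(int)
    variants = [query]
    if include_revcomp:
        variants.append(revcomp(query))
    for var in variants:
        seen = set()
        for i in range(len(var) - k + 1):
            kmer = var[i : i + k]
            if "N" in kmer or not kmer.isupper() or kmer in seen:
                continue
            seen.add(kmer)
            for sid in postings.get(kmer, ()):
                counts[sid] += 1
    return {sid: c for sid, c in counts.items() if c >= min_shared}
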