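"""De novo discovery of novel repeat families from masked reads.

The chain mirrors how novel repeats are mined from unassembled survey
reads: (1) all-vs-all self-comparison of known-repeat-masked reads, where
a read pair counts as a match only if some local alignment contains a
window of >= 100 columns at >= 90% identity and passes a stringent E
cutoff; (2) reads with at least ``min_support`` distinct partners are
carried forward; (3) their matched segments are clustered by
single-linkage at >= 80% identity, each cluster is star-aligned to its
medoid and a majority consensus is called; (4) consensi matching any
provided known database (nucleotide or translated) are dropped; (5) the
abundance of each family is extrapolated to the genome from the sampled
genome fraction.

The clustering/consensus stage is a deterministic replacement for motif
discovery by EM: it keeps the same deliverable (family consensi with
support counts) while being exactly reproducible.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import alignment_engine as ae
from .core_io import GenomicInterval

logger = logging.getLogger(__name__)


def _unmask_to_n(seq: str) -> str:
    """Masked (lowercase) bases become N so they cannot seed or match."""
    return "".join(c if c.isupper() else "N" for c in seq)


@dataclass
class SelfMatchProfile:
    """Per-read count of distinct other reads matched, plus the segments."""

    counts: dict[str, int]
    pair_matches: set[tuple[str, str]]
    #: matched spans per read as (partner read id, start, end)
    segments: dict[str, list[tuple[str, int, int]]]


@dataclass
class SreCandidate:
    sre_id: str
    consensus: str
    support: int
    member_segments: list[GenomicInterval] = field(default_factory=list)
    genome_copies_est: int = 0


def _window_match(
    columns: np.ndarray, window: int, min_identity: float
) -> bool:
    """True if some stretch of ``window`` columns reaches the identity."""
    if len(columns) < window:
        return False
    is_match = (columns == ae.COL_MATCH).astype(np.int32)
    c = np.concatenate(([0], np.cumsum(is_match)))
    need = math.ceil(window * min_identity / 100.0)
    best = int((c[window:] - c[:-window]).max())
    return best >= need


def self_compare(
    reads: Sequence[tuple[str, str]],
    window: int = 100,
    min_identity: float = 90.0,
    evalue_cutoff: float = 1e-50,
    seed_len: int = 14,
    min_shared_kmers: int = 3,
    scheme: ae.ScoringScheme | None = None,
) -> SelfMatchProfile:
    """All-vs-all comparison of (masked) reads.

    Reads are (id, sequence) with known repeats soft-masked (lowercase);
    masked bases are excluded from seeding and matching.  Candidate pairs
    share at least ``min_shared_kmers`` exact k-mers (either strand) and
    are then aligned; self-matches are excluded and matching is symmetric.
    """
    if window < seed_len:
        raise ValueError("window must be >= seed length")
    scheme = scheme or ae.ScoringScheme()
    processed = [(rid, _unmask_to_n(seq)) for rid, seq in reads]
    by_id = dict(processed)
    postings = ae.build_kmer_postings(processed, seed_len)
    pair_counts: dict[tuple[str, str], int] = defaultdict(int)
    for rid, seq in processed:
        for sid, shared in ae.candidate_subjects(
            seq, postings, seed_len, min_shared=1
        ).items():
            if sid == rid:
                continue
            key = (rid, sid) if rid < sid else (sid, rid)
            pair_counts[key] = max(pair_counts[key], shared)
    candidates = [p for p, c in pair_counts.items() if c >= min_shared_kmers]

    counts: dict[str, int] = {rid: 0 for rid, _ in reads}
    matches: set[tuple[str, str]] = set()
    segments: dict[str, list[tuple[str, int, int]]] = defaultdict(list)
    for a, b in sorted(candidates):
        sa, sb = by_id[a], by_id[b]
        if min(len(sa), len(sb)) < seed_len:
            continue
        pairs = ae.local_align(
            a,
            sa,
            b,
            sb,
            scheme=scheme,
            seed_len=seed_len,
            evalue_cutoff=evalue_cutoff,
            min_seeds=2,
            return_alignments=True,
        )
        matched = False
        for hit, aln in pairs:
            if _window_match(aln.columns, window, min_identity):
                matched = True
                segments[a].append((b, *hit.query_interval()))
                segments[b].append((a, *hit.subject_interval()))
        if matched:
            matches.add((a, b))
            counts[a] += 1
            counts[b] += 1
    return SelfMatchProfile(
        counts=counts, pair_matches=matches, segments=dict(segments)
    )


def select_repetitive(profile: SelfMatchProfile, min_support: int = 6) -> list[str]:
    """Reads matching at least ``min_support`` distinct other reads."""
    return sorted(r for r, c in profile.counts.items() if c >= min_support)


@dataclass
class Segment:
    read_id: str
    start: int
    end: int
    sequence: str


def matched_segments(
    profile: SelfMatchProfile,
    reads: Mapping[str, str],
    selected: Iterable[str],
    min_partner_support: int = 6,
    min_len: int = 80,
) -> list[Segment]:
    """Well-supported matched regions of the selected reads.

    For each selected read a per-base profile of distinct matching
    partners is built from the match spans; maximal runs where at least
    ``min_partner_support`` partners agree become segments.  This
    isolates the repeat portion of a read from flanking sequence it
    shares with reads of the same genomic locus (which contribute only
    one or two partners per base) and keeps distinct co-resident repeat
    families apart.
    """
    out = []
    for rid in selected:
        spans = profile.segments.get(rid, ())
        if not spans:
            continue
        seq = _unmask_to_n(reads[rid])
        cover = np.zeros(len(seq), dtype=np.int32)
        per_partner: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for partner, a, b in spans:
            per_partner[partner].append((a, b))
        for partner, ivs in per_partner.items():
            mask = np.zeros(len(seq), dtype=bool)
            for a, b in ivs:
                mask[a:b] = True
            cover += mask
        good = cover >= min_partner_support
        padded = np.concatenate(([False], good, [False]))
        diff = np.diff(padded.astype(np.int8))
        for a, b in zip(np.flatnonzero(diff == 1), np.flatnonzero(diff == -1)):
            if b - a >= min_len:
                out.append(Segment(rid, int(a), int(b), seq[a:b]))
    return out


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _pair_identity_ok(
    sa: str,
    sb: str,
    cluster_identity: float,
    min_overlap: int,
    scheme: ae.ScoringScheme,
    seed_len: int,
) -> tuple[bool, int]:
    """Whether two segments belong to one family, plus alignment score."""
    if min(len(sa), len(sb)) < seed_len:
        return False, 0
    hits = ae.local_align(
        "a", sa, "b", sb, scheme=scheme, seed_len=seed_len, evalue_cutoff=1e3
    )
    for h in hits:
        q0, q1 = h.query_interval()
        if h.pct_identity >= cluster_identity and q1 - q0 >= min_overlap:
            return True, round(h.bit_score)
    return False, 0


def build_consensus(
    segments: Sequence[Segment],
    min_support: int = 6,
    cluster_identity: float = 80.0,
    min_len: int = 80,
    max_len: int = 300,
    seed_len: int = 12,
    min_shared_kmers: int = 4,
    max_members_for_medoid: int = 30,
    scheme: ae.ScoringScheme | None = None,
) -> list[SreCandidate]:
    """Cluster matched segments into families and call a consensus each.

    Single-linkage clustering joins segments aligning at
    >= ``cluster_identity`` percent identity over >= ``min_len`` bases
    (candidate pairs prefiltered by shared k-mers); each cluster is
    star-aligned to its medoid (highest total similarity, ties to the
    lexicographically smallest read id) and a column-majority consensus is
    called over positions with >= 50% occupancy.  Consensi outside
    [min_len, max_len] and clusters with fewer than ``min_support``
    distinct reads are discarded.
    """
    scheme = scheme or ae.ScoringScheme()
    n = len(segments)
    if n == 0:
        return []
    named = [(str(i), seg.sequence) for i, seg in enumerate(segments)]
    postings = ae.build_kmer_postings(named, seed_len)
    uf = _UnionFind(n)
    pair_scores: dict[tuple[int, int], int] = {}
    for i, (sid, seq) in enumerate(named):
        for other, shared in ae.candidate_subjects(
            seq, postings, seed_len, min_shared=min_shared_kmers
        ).items():
            j = int(other)
            if j <= i:
                continue
            if uf.find(i) == uf.find(j) and (i, j) not in pair_scores:
                # already linked through another member; score lazily later
                continue
            ok, score = _pair_identity_ok(
                seq, segments[j].sequence, cluster_identity, min_len, scheme, seed_len
            )
            if ok:
                uf.union(i, j)
                pair_scores[(i, j)] = score

    clusters: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        clusters[uf.find(i)].append(i)

    candidates = []
    for root in sorted(clusters):
        members = clusters[root]
        reads_in = {segments[i].read_id for i in members}
        if len(reads_in) < min_support:
            logger.info(
                "cluster of %d segments dropped: %d distinct reads < %d",
                len(members),
                len(reads_in),
                min_support,
            )
            continue
        consensus, used = _cluster_consensus(
            [segments[i] for i in sorted(members)],
            max_members_for_medoid,
            scheme,
            seed_len,
        )
        if not (min_len <= len(consensus) <= max_len):
            continue
        candidates.append(
            SreCandidate(
                sre_id=f"SRE{len(candidates) + 1:04d}",
                consensus=consensus,
                support=len(reads_in),
                member_segments=[
                    GenomicInterval(s.read_id, s.start, s.end)
                    for s in (segments[i] for i in sorted(members))
                ],
            )
        )
    return candidates


def _cluster_consensus(
    members: list[Segment],
    cap: int,
    scheme: ae.ScoringScheme,
    seed_len: int,
) -> tuple[str, int]:
    """Medoid star alignment and majority consensus for one cluster."""
    pool = sorted(members, key=lambda s: (s.read_id, s.start))[:cap]
    # medoid = member with the highest total alignment score to the others
    totals = []
    for i, a in enumerate(pool):
        t = 0
        for j, b in enumerate(pool):
            if i == j:
                continue
            aln = ae.smith_waterman(a.sequence, b.sequence, scheme)
            t += aln.score if aln else 0
        totals.append((-t, a.read_id, a.start, i))
    medoid = pool[min(totals)[3]]
    med = medoid.sequence
    L = len(med)
    votes: list[dict[str, int]] = [defaultdict(int) for _ in range(L)]
    occupancy = np.zeros(L, dtype=int)
    for seg in pool:
        aln = ae.smith_waterman(seg.sequence, med, scheme)
        if aln is None:
            continue
        qi, si = aln.q_start, aln.s_start
        for col in aln.columns:
            if col == ae.COL_MATCH or col == ae.COL_MISMATCH:
                votes[si][seg.sequence[qi]] += 1
                occupancy[si] += 1
                qi += 1
                si += 1
            elif col == ae.COL_GAP_S:  # base in member, none in medoid
                qi += 1
            else:  # gap in member: medoid base unsupported by this member
                si += 1
    need = math.ceil(0.5 * len(pool))
    passing = np.flatnonzero(occupancy >= need)
    if len(passing) == 0:
        return "", len(pool)
    lo, hi = int(passing[0]), int(passing[-1]) + 1
    out = []
    for p in range(lo, hi):
        if votes[p]:
            best = max(votes[p].items(), key=lambda kv: (kv[1], kv[0] != "N", kv[0]))
            out.append(best[0] if best[0] != "N" else med[p])
        else:
            out.append(med[p])
    return "".join(out), len(pool)


def filter_known(
    candidates: Sequence[SreCandidate],
    nucleotide_dbs: Mapping[str, Sequence[tuple[str, str]]] | None = None,
    protein_dbs: Mapping[str, Sequence[tuple[str, str]]] | None = None,
    evalue_cutoff: float = 1e-4,
    scheme: ae.ScoringScheme | None = None,
) -> list[SreCandidate]:
    """Drop candidates matching any known database record.

    A candidate is removed if any nucleotide (or translated, for protein
    databases) alignment reaches E <= ``evalue_cutoff``.
    """
    scheme = scheme or ae.ScoringScheme()
    prot = ae.protein_scheme()
    retained = []
    for cand in candidates:
        known = False
        for db in (nucleotide_dbs or {}).values():
            for _name, seq in db:
                if min(len(cand.consensus), len(seq)) < 12:
                    continue
                if ae.local_align(
                    cand.sre_id,
                    cand.consensus,
                    _name,
                    seq,
                    scheme=scheme,
                    evalue_cutoff=evalue_cutoff,
                ):
                    known = True
                    break
            if known:
                break
        if not known:
            for db in (protein_dbs or {}).values():
                for _name, pep in db:
                    if ae.translated_align(
                        cand.sre_id,
                        cand.consensus,
                        _name,
                        pep,
                        scheme=prot,
                        evalue_cutoff=evalue_cutoff,
                    ):
                        known = True
                        break
                if known:
                    break
        if not known:
            retained.append(cand)
    return retained


def extrapolate_copies(support: int, sampled_fraction: float) -> int:
    """Genome-wide copy estimate: floor(support / sampled fraction)."""
    if not (0.0 < sampled_fraction <= 1.0):
        raise ValueError("sampled_fraction must be in (0, 1]")
    return math.floor(support / sampled_fraction)


def mine_sres(
    masked_reads: Sequence[tuple[str, str]],
    sampled_fraction: float,
    min_support: int = 6,
    window: int = 100,
    min_identity: float = 90.0,
    evalue_cutoff: float = 1e-50,
    nucleotide_dbs: Mapping[str, Sequence[tuple[str, str]]] | None = None,
    protein_dbs: Mapping[str, Sequence[tuple[str, str]]] | None = None,
) -> tuple[list[SreCandidate], SelfMatchProfile]:
    """Full mining chain: self-compare, select, consensus, filter, copies."""
    profile = self_compare(
        masked_reads, window=window, min_identity=min_identity,
        evalue_cutoff=evalue_cutoff,
    )
    selected = select_repetitive(profile, min_support=min_support)
    segments = matched_segments(
        profile, dict(masked_reads), selected, min_partner_support=min_support
    )
    candidates = build_consensus(segments, min_support=min_support)
    retained = filter_known(
        candidates, nucleotide_dbs=nucleotide_dbs, protein_dbs=protein_dbs
    )
    frac = min(1.0, sampled_fraction)
    if frac != sampled_fraction:
        logger.warning(
            "sampled fraction %.3f clamped to 1.0 for extrapolation", sampled_fraction
        )
    for cand in retained:
        cand.genome_copies_est = extrapolate_copies(cand.support, frac)
    return retained, profile
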