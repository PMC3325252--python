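"""Placement of BES on an annotated reference and microsynteny calling.

Reads are aligned to reference peptides (translated search), filtered by
the three placement criteria (identity >= 75%, E < 1e-20, read coverage
> 50%), reduced to one best placement per read by score, and paired: a
clone whose two ends place on one reference sequence within the maximum
insert size (500 kb) defines a microsyntenous region.  When only one end
places in coding sequence, the mate is rescued by nucleotide alignment
against the surrounding genomic window.  Gene-order conservation between
two genomes is summarised as collinearity blocks: maximal chains of
ortholog pairs monotone in both genomes (increasing, or decreasing for
inversions) allowing a bounded number of skipped genes.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import alignment_engine as ae
from .core_io import AlignmentHit, GenomicInterval

logger = logging.getLogger(__name__)

PAIRED = "paired"
SINGLET = "high_scoring_singlet"
UNPLACED = "unplaced"

MAX_INSERT_DEFAULT = 500_000


@dataclass
class GeneModel:
    gene_id: str
    interval: GenomicInterval
    peptide: str

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass
class Placement:
    read_id: str
    interval: GenomicInterval
    score: float           # bit score of the supporting alignment
    identity: float
    coverage_of_read: float
    category: str = UNPLACED
    in_coding: bool = True
    gene_id: str | None = None


@dataclass
class PairedPlacement:
    clone_id: str
    forward: Placement
    reverse: Placement

    def __post_init__(self) -> None:
        if self.forward.interval.seq_id != self.reverse.interval.seq_id:
            raise ValueError("paired ends must share a reference sequence")

    @property
    def seq_id(self) -> str:
        return self.forward.interval.seq_id

    @property
    def span(self) -> int:
        """Distance between the outermost coordinates of the two ends."""
        lo = min(self.forward.interval.start, self.reverse.interval.start)
        hi = max(self.forward.interval.end, self.reverse.interval.end)
        return hi - lo

    def region(self) -> GenomicInterval:
        lo = min(self.forward.interval.start, self.reverse.interval.start)
        hi = max(self.forward.interval.end, self.reverse.interval.end)
        return GenomicInterval(self.seq_id, lo, hi)


@dataclass(frozen=True)
class OrthologPair:
    pos_a: int
    pos_b: int
    strand_a: str
    strand_b: str
    gene_a: str = ""
    gene_b: str = ""


@dataclass
class CollinearityBlock:
    pairs: list[OrthologPair]
    orientation: str  # "same" or "inverted"

    def __post_init__(self) -> None:
        a = [p.pos_a for p in self.pairs]
        b = [p.pos_b for p in self.pairs]
        if a != sorted(a):
            raise ValueError("block not ordered in genome A")
        inc = all(x < y for x, y in zip(b, b[1:]))
        dec = all(x > y for x, y in zip(b, b[1:]))
        if len(b) > 1 and not (inc or dec):
            raise ValueError("block not monotone in genome B")

    def __len__(self) -> int:
        return len(self.pairs)


# --- placement ----------------------------------------------------------


def filter_hits(
    hits: Iterable[AlignmentHit],
    read_lengths: Mapping[str, int],
    min_identity: float = 75.0,
    max_evalue: float = 1e-20,
    min_coverage: float = 0.5,
) -> list[AlignmentHit]:
    """Hits passing all three placement filters.

    Coverage is aligned read bases over the full read length (masked
    bases included in the denominator).
    """
    out = []
    for h in hits:
        if h.query_id not in read_lengths:
            raise KeyError(f"hit references unknown read {h.query_id!r}")
        q0, q1 = h.query_interval()
        coverage = (q1 - q0) / read_lengths[h.query_id]
        if h.pct_identity >= min_identity and h.evalue < max_evalue and coverage > min_coverage:
            out.append(h)
    return out


def best_placement(hits: Sequence[AlignmentHit]) -> AlignmentHit:
    """Highest score wins; ties by (lower E, subject id, leftmost coord)."""
    if not hits:
        raise ValueError("no hits to choose from")
    return min(
        hits,
        key=lambda h: (
            -h.bit_score,
            h.evalue,
            h.subject_id,
            min(h.s_start, h.s_end),
        ),
    )


def _protein_postings(peptides: Iterable[tuple[str, str]], k: int) -> dict[str, list[str]]:
    postings: dict[str, list[str]] = defaultdict(list)
    for name, pep in peptides:
        seen = set()
        for i in range(len(pep) - k + 1):
            kmer = pep[i : i + k]
            if kmer not in seen:
                postings[kmer].append(name)
                seen.add(kmer)
    return dict(postings)


def translated_search(
    reads: Sequence[tuple[str, str]],
    genes: Sequence[GeneModel],
    scheme: ae.ScoringScheme | None = None,
    evalue_cutoff: float = 1e-10,
    seed_len_aa: int = 4,
    min_shared: int = 8,
) -> list[AlignmentHit]:
    """Six-frame search of reads against gene peptides.

    Candidate gene models must share at least ``min_shared`` distinct
    amino-acid k-mers with a single translated frame of the read, which
    suppresses chance k-mer collisions across frames.
    """
    scheme = scheme or ae.protein_scheme()
    postings = _protein_postings(((g.gene_id, g.peptide) for g in genes), seed_len_aa)
    by_id = {g.gene_id: g for g in genes}
    hits: list[AlignmentHit] = []
    for read_id, seq in reads:
        if len(seq) < 3:
            continue
        counts: dict[str, int] = defaultdict(int)
        for frame, _off, seg in ae.six_frame_segments(seq):
            frame_counts: dict[str, int] = defaultdict(int)
            seen = set()
            for i in range(len(seg) - seed_len_aa + 1):
                kmer = seg[i : i + seed_len_aa]
                if kmer in seen:
                    continue
                seen.add(kmer)
                for gid in postings.get(kmer, ()):
                    frame_counts[gid] += 1
            for gid, c in frame_counts.items():
                counts[gid] = max(counts[gid], c)
        for gid, shared in counts.items():
            if shared < min_shared:
                continue
            hits.extend(
                ae.translated_align(
                    read_id,
                    seq,
                    gid,
                    by_id[gid].peptide,
                    scheme=scheme,
                    evalue_cutoff=evalue_cutoff,
                )
            )
    return hits


def project_to_genome(hit: AlignmentHit, gene: GeneModel) -> GenomicInterval:
    """Genomic interval of a peptide hit, through the gene's CDS frame."""
    s0, s1 = hit.subject_interval()  # residues, 0-based half-open
    g = gene.interval
    if gene.strand == "-":
        return GenomicInterval(g.seq_id, g.end - 3 * s1, g.end - 3 * s0, "-")
    return GenomicInterval(g.seq_id, g.start + 3 * s0, g.start + 3 * s1, "+")


def place_reads(
    reads: Sequence[tuple[str, str]],
    genes: Sequence[GeneModel],
    min_identity: float = 75.0,
    max_evalue: float = 1e-20,
    min_coverage: float = 0.5,
    scheme: ae.ScoringScheme | None = None,
) -> dict[str, Placement]:
    """One best coding placement per read that passes all filters."""
    read_lengths = {rid: len(seq) for rid, seq in reads}
    hits = translated_search(reads, genes, scheme=scheme, evalue_cutoff=max_evalue)
    passing = filter_hits(
        hits, read_lengths, min_identity, max_evalue, min_coverage
    )
    by_read: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in passing:
        by_read[h.query_id].append(h)
    genes_by_id = {g.gene_id: g for g in genes}
    placements: dict[str, Placement] = {}
    for rid, rhits in by_read.items():
        best = best_placement(rhits)
        gene = genes_by_id[best.subject_id]
        q0, q1 = best.query_interval()
        placements[rid] = Placement(
            read_id=rid,
            interval=project_to_genome(best, gene),
            score=best.bit_score,
            identity=best.pct_identity,
            coverage_of_read=(q1 - q0) / read_lengths[rid],
            in_coding=True,
            gene_id=gene.gene_id,
        )
    return placements


def call_pairs(
    placements: Mapping[str, Placement],
    clone_map: Mapping[str, tuple[str, str]],
    max_insert: int = MAX_INSERT_DEFAULT,
) -> tuple[list[PairedPlacement], list[Placement]]:
    """Pair clones whose two placed ends are within the insert constraint.

    Returns (pairs, singlets); placements not in any pair become
    high-scoring singlets.  The span uses the outermost coordinates.
    """
    pairs: list[PairedPlacement] = []
    in_pair: set[str] = set()
    for clone_id in sorted(clone_map):
        fwd_id, rev_id = clone_map[clone_id]
        pf, pr = placements.get(fwd_id), placements.get(rev_id)
        if pf is None or pr is None:
            continue
        if pf.interval.seq_id != pr.interval.seq_id:
            continue
        candidate = PairedPlacement(clone_id, pf, pr)
        if candidate.span <= max_insert:
            pf.category = pr.category = PAIRED
            pairs.append(candidate)
            in_pair.update((fwd_id, rev_id))
    singlets = []
    for rid, p in sorted(placements.items()):
        if rid not in in_pair:
            p.category = SINGLET
            singlets.append(p)
    return pairs, singlets


def rescue_mate(
    placed: Placement,
    mate_read: tuple[str, str],
    reference: Mapping[str, str],
    max_insert: int = MAX_INSERT_DEFAULT,
    min_identity: float = 75.0,
    min_coverage: float = 0.5,
    scheme: ae.ScoringScheme | None = None,
    seed_len: int = 12,
) -> Placement | None:
    """Nucleotide rescue of an unplaced mate near its placed partner.

    The mate is aligned against the genomic window +-max_insert around the
    placed end; the best hit passing identity and coverage (no E
    constraint inside the window) yields a non-coding placement.  A no-op
    (returns None) when the mate finds nothing acceptable.
    """
    if placed is None or not placed.in_coding:
        raise ValueError("rescue requires a coding-placed partner")
    mate_id, mate_seq = mate_read
    seq_id = placed.interval.seq_id
    ref = reference[seq_id]
    lo = placed.interval.start - max_insert
    hi = placed.interval.end + max_insert
    if lo < 0 or hi > len(ref):
        logger.info(
            "rescue window for %s clipped to reference bounds", mate_id
        )
        lo, hi = max(0, lo), min(len(ref), hi)
    window = ref[lo:hi]
    if min(len(mate_seq), len(window)) < seed_len:
        return None
    hits = ae.local_align(
        mate_id,
        mate_seq,
        seq_id,
        window,
        scheme=scheme or ae.ScoringScheme(),
        seed_len=seed_len,
        evalue_cutoff=float("inf"),
    )
    best: AlignmentHit | None = None
    for h in hits:
        q0, q1 = h.query_interval()
        if h.pct_identity < min_identity:
            continue
        if (q1 - q0) / len(mate_seq) <= min_coverage:
            continue
        if best is None or h.bit_score > best.bit_score:
            best = h
    if best is None:
        return None
    s0, s1 = best.subject_interval()
    q0, q1 = best.query_interval()
    return Placement(
        read_id=mate_id,
        interval=GenomicInterval(
            seq_id, lo + s0, lo + s1, best.subject_strand
        ),
        score=best.bit_score,
        identity=best.pct_identity,
        coverage_of_read=(q1 - q0) / len(mate_seq),
        in_coding=False,
    )


def coding_overlap(
    placements: Iterable[Placement],
    coding_intervals: Iterable[GenomicInterval],
) -> float:
    """Percent of placements overlapping a coding feature, 2 decimals."""
    by_seq: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in coding_intervals:
        by_seq[iv.seq_id].append(iv)
    placements = list(placements)
    if not placements:
        return 0.0
    n_in = 0
    for p in placements:
        for iv in by_seq.get(p.interval.seq_id, ()):
            if p.interval.start < iv.end and iv.start < p.interval.end:
                n_in += 1
                break
    return round(100.0 * n_in / len(placements), 2)


# --- collinearity -------------------------------------------------------


def _chain_step_ok(p: OrthologPair, q: OrthologPair, direction: int, max_gap: int) -> bool:
    da = q.pos_a - p.pos_a
    db = direction * (q.pos_b - p.pos_b)
    return 1 <= da <= max_gap + 1 and 1 <= db <= max_gap + 1


def _longest_chain(
    pairs: list[OrthologPair], max_gap: int
) -> tuple[list[int], int]:
    """Best monotone chain: indices into ``pairs`` and its direction.

    Chains allow up to ``max_gap`` skipped positions per step on each
    side; the best chain maximises length, then minimises total skipped
    positions, then starts leftmost, preferring the same orientation.
    """
    n = len(pairs)
    best_key = None
    best = ([], 1)
    for direction in (1, -1):
        length = [1] * n
        gaps = [0] * n
        prev = [-1] * n
        for i in range(n):
            for j in range(i):
                if _chain_step_ok(pairs[j], pairs[i], direction, max_gap):
                    step_gap = (pairs[i].pos_a - pairs[j].pos_a - 1) + abs(
                        pairs[i].pos_b - pairs[j].pos_b
                    ) - 1
                    cand = (length[j] + 1, -(gaps[j] + step_gap))
                    if cand > (length[i], -gaps[i]):
                        length[i] = length[j] + 1
                        gaps[i] = gaps[j] + step_gap
                        prev[i] = j
        for i in range(n):
            chain = []
            k = i
            while k != -1:
                chain.append(k)
                k = prev[k]
            chain.reverse()
            key = (
                length[i],
                -gaps[i],
                -pairs[chain[0]].pos_a,
                1 if direction == 1 else 0,
            )
            if best_key is None or key > best_key:
                best_key = key
                best = (chain, direction)
    return best


def collinearity_blocks(
    pairs: Sequence[OrthologPair], max_gap: int = 2
) -> tuple[list[CollinearityBlock], list[OrthologPair]]:
    """Maximal monotone chains of ortholog pairs, plus unchained pairs.

    Chains are extracted greedily by repeated longest-chain search
    (increasing = same orientation, decreasing = inverted); chains must
    contain at least two pairs, all remaining pairs are reported as
    rearranged/absent.  Duplicate positions on either genome are an
    error.
    """
    pairs = sorted(pairs, key=lambda p: p.pos_a)
    if len({p.pos_a for p in pairs}) != len(pairs) or len(
        {p.pos_b for p in pairs}
    ) != len(pairs):
        raise ValueError("duplicate positions in ortholog pairs")
    remaining = list(pairs)
    blocks: list[CollinearityBlock] = []
    while len(remaining) >= 2:
        chain_idx, direction = _longest_chain(remaining, max_gap)
        if len(chain_idx) < 2:
            break
        chain = [remaining[i] for i in chain_idx]
        blocks.append(
            CollinearityBlock(
                pairs=chain,
                orientation="same" if direction == 1 else "inverted",
            )
        )
        chosen = set(chain_idx)
        remaining = [p for i, p in enumerate(remaining) if i not in chosen]
    blocks.sort(key=lambda b: b.pairs[0].pos_a)
    return blocks, remaining


def ortholog_pairs(
    genes_a: Sequence[GeneModel],
    genes_b: Sequence[GeneModel],
    scheme: ae.ScoringScheme | None = None,
    seed_len_aa: int = 5,
    min_shared: int = 3,
) -> list[OrthologPair]:
    """Reciprocal-best peptide matches as position-indexed ortholog pairs.

    Positions are coordinate ranks within each genome (sorted by
    sequence id, then start).
    """
    scheme = scheme or ae.protein_scheme()
    order_a = sorted(genes_a, key=lambda g: (g.interval.seq_id, g.interval.start))
    order_b = sorted(genes_b, key=lambda g: (g.interval.seq_id, g.interval.start))
    rank_a = {g.gene_id: i for i, g in enumerate(order_a)}
    rank_b = {g.gene_id: i for i, g in enumerate(order_b)}
    postings = _protein_postings(((g.gene_id, g.peptide) for g in order_b), seed_len_aa)
    by_id_b = {g.gene_id: g for g in order_b}
    best_ab: dict[str, tuple[int, str]] = {}
    best_ba: dict[str, tuple[int, str]] = {}
    for g in order_a:
        counts: dict[str, int] = defaultdict(int)
        seen = set()
        for i in range(len(g.peptide) - seed_len_aa + 1):
            kmer = g.peptide[i : i + seed_len_aa]
            if kmer in seen:
                continue
            seen.add(kmer)
            for gid in postings.get(kmer, ()):
                counts[gid] += 1
        for gid, shared in sorted(counts.items()):
            if shared < min_shared:
                continue
            aln = ae.smith_waterman(g.peptide, by_id_b[gid].peptide, scheme)
            if aln is None:
                continue
            if g.gene_id not in best_ab or aln.score > best_ab[g.gene_id][0]:
                best_ab[g.gene_id] = (aln.score, gid)
            if gid not in best_ba or aln.score > best_ba[gid][0]:
                best_ba[gid] = (aln.score, g.gene_id)
    out = []
    genes_a_by_id = {g.gene_id: g for g in order_a}
    for ga, (_score, gb) in sorted(best_ab.items()):
        if best_ba.get(gb, (0, None))[1] == ga:
            a = genes_a_by_id[ga]
            b = by_id_b[gb]
            out.append(
                OrthologPair(
                    pos_a=rank_a[ga],
                    pos_b=rank_b[gb],
                    strand_a=a.strand,
                    strand_b=b.strand,
                    gene_a=ga,
                    gene_b=gb,
                )
            )
    return sorted(out, key=lambda p: p.pos_a)


def gene_density(locus_count: int, corpus_bases: float) -> float | None:
    """kb of sequence per gene locus at one decimal; None for no loci."""
    if locus_count == 0:
        return None
    return round(corpus_bases / 1000.0 / locus_count, 1)
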