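"""Homology-based repeat identification, masking and summarization.

Reads are searched against a class-labelled repeat library (FASTA with
RepeatMasker-dialect headers ``name#class/subclass``) with the seeded
local aligner; passing hits to the same element that are fragmented by
insertions are merged and counted as one element.  Summaries mirror the
classic repeat-landscape table: per-class element counts, bases occupied
(on interval unions, so no double counting within a class) and percent of
the corpus, with transposon classes rolled up as interspersed repeats.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import alignment_engine as ae
from .core_io import GenomicInterval, read_fasta

logger = logging.getLogger(__name__)

#: top-level class groups counted as interspersed (transposon) repeats
INTERSPERSED_GROUPS = ("Retroelements", "DNATransposons", "Unclassified")


@dataclass(frozen=True)
class RepeatLibraryEntry:
    name: str
    class_path: str  # e.g. Retroelements/LTR/Ty3-Gypsy
    sequence: str


@dataclass
class AnnotationParams:
    min_identity: float = 70.0
    min_length: int = 50          # minimum hit span on the read, bp
    evalue_cutoff: float = 1e-5
    merge_gap_read: int = 100     # fragment merge gap on the read
    merge_gap_element: int = 500  # and on the library element
    seed_len: int = 12
    min_shared_kmers: int = 2
    hard_mask: bool = False


@dataclass
class RepeatHit:
    """One (possibly fragment-merged) repeat element found on a read."""

    read_id: str
    interval: GenomicInterval          # bounding span on the read
    entry: RepeatLibraryEntry
    element_start: int                 # bounding span on the library element
    element_end: int
    pct_identity: float
    strand: str
    merged_from: int = 1
    fragments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.merged_from < 1:
            raise ValueError("merged_from must be >= 1")
        if not self.fragments:
            self.fragments = [(self.interval.start, self.interval.end)]


def load_repeat_library(path: str | Path) -> list[RepeatLibraryEntry]:
    """Read a library FASTA with ``name#class/subclass`` headers."""
    entries = []
    for name, seq in read_fasta(path):
        base, _, class_path = name.partition("#")
        entries.append(RepeatLibraryEntry(base, class_path or "Unclassified", seq))
    return entries


def _merge_fragments(
    hits: list[tuple[int, int, int, int, float, int]],
    gap_read: int,
    gap_element: int,
    minus: bool,
) -> list[list[tuple[int, int, int, int, float, int]]]:
    """Chain fragments (q0, q1, s0, s1, identity, score) of one element.

    Fragments merge when consecutive on the read within ``gap_read`` and
    consistently ordered/spaced on the element within ``gap_element``.
    """
    hits = sorted(hits)
    chains: list[list[tuple[int, int, int, int, float, int]]] = []
    for h in hits:
        for chain in chains:
            last = chain[-1]
            if not (0 - last[1] + h[0] <= gap_read and h[0] >= last[1] - 20):
                continue
            if minus:
                elem_ok = last[2] - h[3] <= gap_element and h[3] <= last[2] + 20
            else:
                elem_ok = h[2] - last[3] <= gap_element and h[2] >= last[3] - 20
            if elem_ok:
                chain.append(h)
                break
        else:
            chains.append([h])
    return chains


def annotate_repeats(
    reads: Sequence[tuple[str, str]],
    library: Sequence[RepeatLibraryEntry],
    params: AnnotationParams | None = None,
    scheme: ae.ScoringScheme | None = None,
) -> tuple[list[RepeatHit], dict[str, str]]:
    """Identify known repeats on reads and return (hits, masked reads).

    Masked reads have hit bases lowercased (soft) or replaced by N (hard,
    per ``params.hard_mask``).  An empty library is an error.
    """
    if not library:
        raise ValueError("repeat library is empty")
    params = params or AnnotationParams()
    scheme = scheme or ae.ScoringScheme()
    postings = ae.build_kmer_postings(
        ((e.name, e.sequence) for e in library), params.seed_len
    )
    by_name = {e.name: e for e in library}
    all_hits: list[RepeatHit] = []
    masked: dict[str, str] = {}
    for read_id, seq in reads:
        if set(seq.upper()) <= {"N"}:
            masked[read_id] = seq
            continue
        # already-masked (lowercase) bases must neither seed nor extend
        search_seq = "".join(c if c.isupper() else "N" for c in seq)
        cands = ae.candidate_subjects(
            search_seq, postings, params.seed_len, params.min_shared_kmers
        )
        frag_by_key: dict[tuple[str, str], list] = defaultdict(list)
        for entry_name in cands:
            entry = by_name[entry_name]
            if min(len(seq), len(entry.sequence)) < params.seed_len:
                continue
            pairs = ae.local_align(
                read_id,
                search_seq,
                entry.name,
                entry.sequence,
                scheme=scheme,
                seed_len=params.seed_len,
                evalue_cutoff=params.evalue_cutoff,
                return_alignments=True,
            )
            for hit, _aln in pairs:
                q0, q1 = hit.query_interval()
                if hit.pct_identity < params.min_identity:
                    continue
                if q1 - q0 < params.min_length:
                    continue
                s0, s1 = hit.subject_interval()
                frag_by_key[(entry.name, hit.subject_strand)].append(
                    (q0, q1, s0, s1, hit.pct_identity, round(hit.bit_score))
                )
        read_hits: list[RepeatHit] = []
        for (entry_name, strand), frags in frag_by_key.items():
            entry = by_name[entry_name]
            for chain in _merge_fragments(
                frags,
                params.merge_gap_read,
                params.merge_gap_element,
                minus=(strand == "-"),
            ):
                q0 = min(f[0] for f in chain)
                q1 = max(f[1] for f in chain)
                s0 = min(f[2] for f in chain)
                s1 = max(f[3] for f in chain)
                span = sum(f[1] - f[0] for f in chain)
                ident = sum(f[4] * (f[1] - f[0]) for f in chain) / span
                read_hits.append(
                    RepeatHit(
                        read_id=read_id,
                        interval=GenomicInterval(read_id, q0, q1, strand),
                        entry=entry,
                        element_start=s0,
                        element_end=s1,
                        pct_identity=ident,
                        strand=strand,
                        merged_from=len(chain),
                        fragments=[(f[0], f[1]) for f in chain],
                    )
                )
        all_hits.extend(read_hits)
        masked[read_id] = mask_sequence(
            seq,
            [iv for h in read_hits for iv in h.fragments],
            hard=params.hard_mask,
        )
    return all_hits, masked


def mask_sequence(
    seq: str, intervals: Iterable[tuple[int, int]], hard: bool = False
) -> str:
    """Lowercase (soft) or N-out (hard) the given intervals of ``seq``."""
    chars = list(seq)
    for a, b in intervals:
        for i in range(max(0, a), min(len(chars), b)):
            chars[i] = "N" if hard else chars[i].lower()
    return "".join(chars)


def union_length(intervals: Iterable[tuple[int, int]]) -> int:
    total = 0
    end = -1
    for a, b in sorted(intervals):
        a = max(a, end)
        if b > a:
            total += b - a
            end = b
        end = max(end, b)
    return total


def detect_low_complexity(
    seq: str,
    window: int = 64,
    step: int = 32,
    entropy_threshold: float = 1.4,
) -> list[tuple[int, int]]:
    """Windows of low trinucleotide Shannon entropy, merged into intervals.

    Entropy is computed in bits over overlapping trinucleotides of each
    window; windows containing N contribute only their N-free trinucs.
    """
    seq = seq.upper()
    n = len(seq)
    if n < 3:
        return []
    flagged: list[tuple[int, int]] = []
    starts = list(range(0, max(1, n - window + 1), step))
    if starts and starts[-1] + window < n:
        starts.append(n - window)
    for a in starts:
        b = min(n, a + window)
        counts: dict[str, int] = defaultdict(int)
        for i in range(a, b - 2):
            tri = seq[i : i + 3]
            if "N" not in tri:
                counts[tri] += 1
        total = sum(counts.values())
        if total == 0:
            continue
        ent = -sum(
            (c / total) * math.log2(c / total) for c in counts.values()
        )
        if ent < entropy_threshold:
            flagged.append((a, b))
    # merge touching/overlapping windows
    merged: list[list[int]] = []
    for a, b in sorted(flagged):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


@dataclass
class RepeatSummary:
    """Per-class repeat landscape over a corpus.

    ``rows`` maps a class path to (element_count, bases_occupied); bases
    are computed on per-read interval unions within the class.
    """

    rows: dict[str, tuple[int, int]]
    corpus_bases: int

    def __post_init__(self) -> None:
        if self.corpus_bases <= 0:
            raise ValueError("corpus_bases must be > 0")

    def count(self, prefix: str) -> int:
        return sum(
            c
            for path, (c, _b) in self.rows.items()
            if path == prefix or path.startswith(prefix + "/")
        )

    def bases(self, prefix: str) -> int:
        return sum(
            b
            for path, (_c, b) in self.rows.items()
            if path == prefix or path.startswith(prefix + "/")
        )

    def pct(self, prefix: str) -> float:
        """Percent of corpus bases occupied by a class, 2 decimals."""
        return round(100.0 * self.bases(prefix) / self.corpus_bases, 2)

    def interspersed_bases(self) -> int:
        return sum(self.bases(g) for g in INTERSPERSED_GROUPS)

    def interspersed_pct(self) -> float:
        return round(100.0 * self.interspersed_bases() / self.corpus_bases, 2)

    # derived ratios of the transposon landscape
    def class_i_share(self) -> float:
        """Retroelement share of all classified transposons, percent."""
        retro = self.count("Retroelements")
        dna = self.count("DNATransposons")
        return round(100.0 * retro / (retro + dna), 1)

    def ltr_share(self) -> float:
        """LTR-element share of retroelements, percent."""
        return round(100.0 * self.count("Retroelements/LTR") / self.count("Retroelements"), 1)

    def gypsy_copia_ratio(self) -> float:
        copia = self.count("Retroelements/LTR/Ty1-Copia")
        gypsy = self.count("Retroelements/LTR/Ty3-Gypsy-DIRS1")
        if copia == 0:
            raise ZeroDivisionError("no Copia elements")
        return gypsy / copia

    def subclass_share(self, parent: str, child: str) -> float:
        """Element-count share of ``child`` within ``parent``, percent."""
        return round(100.0 * self.count(child) / self.count(parent), 1)


def summarize_repeats(
    hits: Sequence[RepeatHit],
    corpus_bases: int,
    extra_rows: dict[str, tuple[int, int]] | None = None,
) -> RepeatSummary:
    """Aggregate merged hits per class path.

    ``extra_rows`` lets non-homology sections (e.g. LowComplexity from
    :func:`detect_low_complexity`) join the same table; such sections are
    reported alongside but never counted as interspersed repeats.
    """
    if corpus_bases <= 0:
        raise ValueError("corpus_bases must be > 0")
    counts: dict[str, int] = defaultdict(int)
    frags: dict[str, dict[str, list[tuple[int, int]]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for h in hits:
        counts[h.entry.class_path] += 1
        frags[h.entry.class_path][h.read_id].extend(h.fragments)
    rows: dict[str, tuple[int, int]] = {}
    for path, per_read in frags.items():
        bases = sum(union_length(ivs) for ivs in per_read.values())
        rows[path] = (counts[path], bases)
    if extra_rows:
        for path, row in extra_rows.items():
            rows[path] = row
    return RepeatSummary(rows=rows, corpus_bases=corpus_bases)
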