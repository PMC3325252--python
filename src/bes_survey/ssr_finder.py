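"""Maximal perfect tandem repeat (SSR / microsatellite) detection.

An SSR here is a maximal perfect tandem run of a primitive 1-6 bp motif:
mono- to trinucleotide runs must span at least 12 nt, and tetra- to
hexanucleotide runs must contain at least four repeat units.  Fractional
trailing units count toward the run length.  Runs are broken at N bases,
and a run is reported once, under its smallest primitive period.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core_io import GenomicInterval

MAX_PERIOD = 6
MIN_LEN_SHORT = 12  # periods 1-3: minimum run length in nt
MIN_UNITS_LONG = 4  # periods 4-6: minimum repeat units

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SsrLocus:
    """One maximal perfect tandem repeat on a read."""

    read_id: str
    interval: GenomicInterval
    motif: str  # primitive unit in its as-occurring phase

    def __post_init__(self) -> None:
        if not (1 <= len(self.motif) <= MAX_PERIOD):
            raise ValueError(f"motif period out of range: {self.motif}")
        if not is_primitive(self.motif):
            raise ValueError(f"motif {self.motif} is not primitive")
        if len(self.interval) < len(self.motif):
            raise ValueError("locus shorter than its motif")

    @property
    def period(self) -> int:
        return len(self.motif)

    @property
    def length(self) -> int:
        return len(self.interval)

    @property
    def unit_count(self) -> float:
        return self.length / self.period


@dataclass
class SsrSummary:
    total_count: int
    total_bases: int           # bases inside SSR loci
    corpus_bases: int          # denominator for density (all corpus bases)
    density_kb_per_ssr: float | None  # None when no loci were found
    by_period: dict[int, int]
    by_motif_class: dict[str, int]
    count_over_20nt: int


def is_primitive(motif: str) -> bool:
    """True if the motif is not a whole-number repetition of a shorter one."""
    p = len(motif)
    for d in range(1, p):
        if p % d == 0 and motif == motif[:d] * (p // d):
            return False
    return True


def canonical_motif_class(motif: str) -> str:
    """Strand-collapsed motif class label, e.g. GGC -> "GCC/GGC".

    The class pairs a motif with its reverse complement (sorted
    lexicographically); rotational phases are deliberately NOT merged, so
    GCC/GGC and CGC/GCG remain distinct classes.
    """
    if not is_primitive(motif):
        raise ValueError(f"motif {motif} is not primitive")
    rc = revcomp(motif)
    a, b = sorted((motif, rc))
    return f"{a}/{b}"


def _passes_threshold(
    period: int, length: int, min_len_short: int, min_units_long: int
) -> bool:
    if period <= 3:
        return length >= min_len_short
    return length >= min_units_long * period


def find_ssrs(
    sequence: str,
    read_id: str = "seq",
    seq_id: str | None = None,
    min_len_short: int = MIN_LEN_SHORT,
    min_units_long: int = MIN_UNITS_LONG,
) -> list[SsrLocus]:
    """All maximal perfect tandem repeats passing the period-class thresholds.

    Runs containing N are broken at the N.  Implementation: for each period
    p, vectorised comparison of the sequence with itself shifted by p;
    maximal blocks of equality of length L yield tandem runs of length
    L + p.  A run whose leading unit is non-primitive is a pure
    smaller-period run and is reported there instead; identical intervals
    arising at several periods are kept once, under the smallest period.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < 2:
        return []
    seq_id = seq_id if seq_id is not None else read_id
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_n = arr == ord("N")

    found: dict[tuple[int, int], SsrLocus] = {}
    for p in range(1, MAX_PERIOD + 1):
        if n < p + 1:
            break
        eq = (arr[:-p] == arr[p:]) & ~is_n[:-p] & ~is_n[p:]
        if not eq.any():
            continue
        # boundaries of maximal True blocks in eq
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)  # exclusive in eq-space
        for a, b in zip(starts, ends):
            length = (b - a) + p
            if length < 2 * p:
                continue  # fewer than two units: not a tandem run at p
            if not _passes_threshold(p, length, min_len_short, min_units_long):
                continue
            motif = seq[a : a + p]
            if not is_primitive(motif):
                continue  # reported at its smaller primitive period
            key = (int(a), int(a) + int(length))
            prev = found.get(key)
            if prev is None or p < prev.period:
                found[key] = SsrLocus(
                    read_id,
                    GenomicInterval(seq_id, int(a), int(a) + int(length)),
                    motif,
                )
    return sorted(found.values(), key=lambda l: (l.interval.start, l.period))


def find_ssrs_in_corpus(
    records: Iterable[tuple[str, str]]
) -> tuple[list[SsrLocus], int]:
    """Run :func:`find_ssrs` over (id, sequence) pairs; returns (loci, bases)."""
    loci: list[SsrLocus] = []
    total = 0
    for name, seq in records:
        loci.extend(find_ssrs(seq, read_id=name))
        total += len(seq)
    return loci, total


def summarize_ssrs(loci: Sequence[SsrLocus], corpus_bases: int) -> SsrSummary:
    """Corpus-level SSR summary.

    Density is reported as kb of corpus sequence per SSR at one decimal;
    the denominator is the full corpus (masked/N bases included).  With no
    loci the density is undefined (``None``) rather than an error.
    """
    count = len(loci)
    by_period = Counter(l.period for l in loci)
    by_class = Counter(canonical_motif_class(l.motif) for l in loci)
    density = None
    if count > 0:
        density = round(corpus_bases / 1000.0 / count, 1)
    return SsrSummary(
        total_count=count,
        total_bases=sum(l.length for l in loci),
        corpus_bases=corpus_bases,
        density_kb_per_ssr=density,
        by_period=dict(sorted(by_period.items())),
        by_motif_class=dict(by_class.most_common()),
        count_over_20nt=sum(1 for l in loci if l.length > 20),
    )


def ssr_gff3_features(loci: Iterable[SsrLocus]):
    """Loci as (interval, type, attributes) tuples for the GFF3 writer."""
    for l in loci:
        yield (
            l.interval,
            "microsatellite",
            {
                "motif": l.motif,
                "period": str(l.period),
                "units": f"{l.unit_count:.2f}",
            },
        )
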