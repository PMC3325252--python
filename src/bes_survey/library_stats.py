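"""Library coverage mathematics and screening-based contamination estimates.

The central result is the Clarke-Carbon relation between the number of
clones N in a large-insert library, the mean insert size I, the haploid
genome size GS, and the probability P that a given single-copy locus is
represented at least once:

    N = ln(1 - P) / ln(1 - I/GS)        <=>        P = 1 - (1 - I/GS)^N

Genome equivalents are the effective total insert length (discounting empty
and organellar clones) divided by the genome size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from .core_io import LibraryMetadata


@dataclass(frozen=True)
class HybridizationScreen:
    """Result of a colony-filter hybridization: positives among screened."""

    probe_set: str
    positives: int
    clones_screened: int

    def __post_init__(self) -> None:
        if self.clones_screened <= 0:
            raise ValueError("clones_screened must be > 0")
        if not (0 <= self.positives <= self.clones_screened):
            raise ValueError("positives must be in [0, clones_screened]")


@dataclass
class CoverageReport:
    genome_equivalents: float
    p_find: float
    effective_clones: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_find <= 1.0):
            raise ValueError("p_find must be a probability")
        if self.genome_equivalents < 0:
            raise ValueError("genome_equivalents must be >= 0")


def round_half_up(value: float, decimals: int) -> float:
    """Decimal half-up rounding (0.565 -> 0.57 at 2 decimals)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def contamination_rate(screen: HybridizationScreen, decimals: int = 2) -> float:
    """Percent of screened clones that hybridized, rounded half-up."""
    return round_half_up(100.0 * screen.positives / screen.clones_screened, decimals)


def genome_equivalents(meta: LibraryMetadata) -> float:
    """Effective haploid genome equivalents represented by one library.

    Empty and organellar clones carry no nuclear insert and are discounted:
    equivalents = N x (1 - empty - organellar) x I / GS.
    """
    lost = meta.empty_fraction + meta.organellar_fraction
    if lost >= 1.0:
        raise ValueError(
            f"empty + organellar fractions must be < 1, got {lost}"
        )
    return meta.clone_count * (1.0 - lost) * meta.mean_insert / meta.genome_size


def p_find(n_clones: float, insert: float, genome_size: float) -> float:
    """P = 1 - (1 - I/GS)^N: chance a given locus is in the library."""
    if n_clones < 0:
        raise ValueError("n_clones must be >= 0")
    if not (0 < insert < genome_size):
        raise ValueError("require 0 < insert < genome_size")
    return -math.expm1(n_clones * math.log1p(-insert / genome_size))


def p_find_combined(
    libraries: Sequence[tuple[float, float]], genome_size: float
) -> float:
    """Joint representation probability over several libraries.

    ``libraries`` is a sequence of (n_clones, mean_insert); a locus is
    missed only if missed by every library independently.
    """
    log_miss = 0.0
    for n, insert in libraries:
        if n < 0:
            raise ValueError("n_clones must be >= 0")
        if not (0 < insert < genome_size):
            raise ValueError("require 0 < insert < genome_size")
        log_miss += n * math.log1p(-insert / genome_size)
    return -math.expm1(log_miss)


def clarke_carbon_clones(p: float, insert: float, genome_size: float) -> int:
    """Smallest clone count N with p_find(N, I, GS) >= P."""
    if not (0.0 < p < 1.0):
        raise ValueError("P must be in (0, 1)")
    if not (0 < insert < genome_size):
        raise ValueError("require 0 < insert < genome_size")
    n = math.log1p(-p) / math.log1p(-insert / genome_size)
    n_int = max(1, math.ceil(n))
    # guard against float edge cases on either side of the ceiling
    while n_int > 1 and p_find(n_int - 1, insert, genome_size) >= p:
        n_int -= 1
    while p_find(n_int, insert, genome_size) < p:
        n_int += 1
    return n_int


def coverage_report(meta: LibraryMetadata) -> CoverageReport:
    eq = genome_equivalents(meta)
    eff = meta.clone_count * (1.0 - meta.empty_fraction - meta.organellar_fraction)
    return CoverageReport(
        genome_equivalents=eq,
        p_find=p_find(eff, meta.mean_insert, meta.genome_size) if eff > 0 else 0.0,
        effective_clones=eff,
    )


def insert_size_from_digest(
    fragment_sizes: Sequence[float],
    vector_size: float,
    tolerance: float = 0.5,
) -> float:
    """Insert size (kb) of one clone from its restriction-digest fragments.

    Exactly one fragment must match the vector band within ``tolerance``
    kb; the insert is the sum of the remaining fragments.
    """
    matches = [
        i for i, f in enumerate(fragment_sizes) if abs(f - vector_size) <= tolerance
    ]
    if not matches:
        raise ValueError(
            f"no fragment within {tolerance} kb of the {vector_size} kb vector band"
        )
    vector_idx = matches[0]
    return float(sum(f for i, f in enumerate(fragment_sizes) if i != vector_idx))


def insert_histogram(
    inserts: Sequence[float], bin_width: float
) -> list[tuple[float, int]]:
    """Left-closed histogram of insert sizes: [(bin left edge, count), ...]."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if len(inserts) == 0:
        return []
    arr = np.asarray(inserts, dtype=float)
    left = np.floor(arr / bin_width).astype(int)
    counts = np.bincount(left - left.min())
    lo = left.min()
    return [
        (float((lo + i) * bin_width), int(c)) for i, c in enumerate(counts) if c > 0
    ]
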