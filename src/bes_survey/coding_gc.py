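"""GC content, coding/non-coding partitioning, and GO-term tabulation.

A read region counts as coding when it carries a protein signature — an
interval covered by a passing translated-homology hit.  GC percentages
exclude N bases from the denominator; the overall GC of a corpus equals
the base-weighted mean of its coding and non-coding fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

GO_NAMESPACES = ("molecular_function", "biological_process", "cellular_component")


@dataclass
class GcPartition:
    overall_gc: float
    coding_gc: float | None
    noncoding_gc: float | None
    coding_bases: int
    noncoding_bases: int
    signature_fraction: float  # percent of reads with >= 1 signature


def gc_content(sequence: str) -> float | None:
    """GC percent over A+C+G+T; N excluded; None for an all-N sequence."""
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        return None
    return 100.0 * gc / acgt


def weighted_overall_gc(
    coding_bases: float,
    coding_gc: float,
    noncoding_bases: float,
    noncoding_gc: float,
) -> float:
    """Base-weighted mean GC of the two fractions, one decimal."""
    total = coding_bases + noncoding_bases
    if total <= 0:
        raise ValueError("no bases")
    return round(
        (coding_bases * coding_gc + noncoding_bases * noncoding_gc) / total, 1
    )


def _gc_counts(seq: str) -> tuple[int, int]:
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    return gc, acgt


def partition_gc(
    reads: Sequence[tuple[str, str]],
    signatures: Mapping[str, Sequence[tuple[int, int]]],
) -> GcPartition:
    """Split the corpus at protein-signature intervals and profile GC.

    ``signatures`` maps read id -> half-open intervals of translated-hit
    unions on that read.  Coding bases are those inside intervals,
    non-coding the rest; N bases count to neither GC denominator but the
    partition itself is positional.
    """
    gc_cod = acgt_cod = gc_non = acgt_non = 0
    coding_bases = noncoding_bases = 0
    n_with = 0
    for rid, seq in reads:
        seq = seq.upper()
        ivs = sorted(signatures.get(rid, ()))
        for a, b in ivs:
            if a < 0 or b > len(seq) or a >= b:
                raise ValueError(
                    f"signature interval ({a}, {b}) outside read {rid}"
                )
        if ivs:
            n_with += 1
        pos = 0
        for a, b in ivs:
            a = max(a, pos)
            g, t = _gc_counts(seq[pos:a])
            gc_non += g
            acgt_non += t
            noncoding_bases += a - pos
            g, t = _gc_counts(seq[a:b])
            gc_cod += g
            acgt_cod += t
            coding_bases += b - a
            pos = b
        g, t = _gc_counts(seq[pos:])
        gc_non += g
        acgt_non += t
        noncoding_bases += len(seq) - pos
    overall_den = acgt_cod + acgt_non
    return GcPartition(
        overall_gc=100.0 * (gc_cod + gc_non) / overall_den if overall_den else 0.0,
        coding_gc=100.0 * gc_cod / acgt_cod if acgt_cod else None,
        noncoding_gc=100.0 * gc_non / acgt_non if acgt_non else None,
        coding_bases=coding_bases,
        noncoding_bases=noncoding_bases,
        signature_fraction=100.0 * n_with / len(reads) if reads else 0.0,
    )


def signature_intervals_from_hits(hits, merge_gap: int = 10) -> dict[str, list[tuple[int, int]]]:
    """Union of translated-hit query spans per read."""
    by_read: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        by_read.setdefault(h.query_id, []).append(h.query_interval())
    out = {}
    for rid, ivs in by_read.items():
        merged: list[list[int]] = []
        for a, b in sorted(ivs):
            if merged and a <= merged[-1][1] + merge_gap:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        out[rid] = [(a, b) for a, b in merged]
    return out


def tabulate_go(
    table: pd.DataFrame,
    namespaces: Iterable[str] = GO_NAMESPACES,
) -> pd.DataFrame:
    """Per-namespace GO term counts and percentages.

    ``table`` has columns (read_id, term_id, namespace); the result has
    one row per (namespace, term_id) with the number of distinct reads
    and the percent of that namespace's read-term associations.  Unknown
    namespaces are an error.
    """
    allowed = set(namespaces)
    required = {"read_id", "term_id", "namespace"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if len(table) == 0:
        return pd.DataFrame(columns=["namespace", "term_id", "reads", "pct"])
    unknown = set(table["namespace"]) - allowed
    if unknown:
        raise ValueError(f"unknown namespaces: {sorted(unknown)}")
    counts = (
        table.drop_duplicates(["read_id", "term_id", "namespace"])
        .groupby(["namespace", "term_id"])
        .size()
        .rename("reads")
        .reset_index()
    )
    counts["pct"] = counts.groupby("namespace")["reads"].transform(
        lambda s: (100.0 * s / s.sum()).round(2)
    )
    return counts.sort_values(
        ["namespace", "reads", "term_id"], ascending=[True, False, True]
    ).reset_index(drop=True)
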