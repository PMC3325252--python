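"""Domain types and readers/writers for the formats the survey touches.

Coordinates are 0-based half-open everywhere inside the package; the GFF3
writer/reader is the single site where the 1-based inclusive convention of
that format is applied (``gff_start = start + 1``, ``gff_end = end``).
Tabular alignments use the 12-column BLAST ``outfmt 6`` field order with its
1-based inclusive coordinates.
"""

from __future__ import annotations

import logging
import re
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")
# IUPAC ambiguity codes other than N collapse to N; anything else is rejected.
_AMBIGUITY = set("RYSWKMBDHV")
_AMBIG_TABLE = str.maketrans({c: "N" for c in _AMBIGUITY})

FORWARD = "forward"
REVERSE = "reverse"

#: default read-id pattern: clone id plus a trailing ".f" / ".r" end tag
DEFAULT_END_PATTERN = r"^(?P<clone>.+)\.(?P<end>[fr])$"


class FastaParseError(ValueError):
    """Malformed FASTA input; the message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A located feature: 0-based half-open [start, end) on ``seq_id``."""

    seq_id: str
    start: int
    end: int
    strand: str = "."  # '+', '-', or '.' for unstranded

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class BesRecord:
    """One end-read of a BAC clone."""

    read_id: str
    clone_id: str
    end: str  # FORWARD or REVERSE
    library_id: str
    sequence: str

    def __post_init__(self) -> None:
        if self.end not in (FORWARD, REVERSE):
            raise ValueError(f"end must be forward/reverse, got {self.end!r}")
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for read {self.read_id}")
        bad = set(self.sequence.upper()) - _VALID_BASES
        if bad:
            raise ValueError(
                f"read {self.read_id}: non-ACGTN characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class AlignmentHit:
    """One local alignment, in the 12-column tabular convention.

    Coordinates are 1-based inclusive; on the subject minus strand
    ``s_start > s_end`` (the outfmt-6 convention). ``frame`` is set by
    translated searches (+1..+3 / -1..-3) and 0 for nucleotide searches.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float
    frame: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(f"pct_identity out of range: {self.pct_identity}")
        if self.aln_len < 1:
            raise ValueError(f"aln_len must be >= 1, got {self.aln_len}")
        if self.evalue < 0:
            raise ValueError(f"negative evalue: {self.evalue}")

    @property
    def subject_strand(self) -> str:
        return "+" if self.s_start <= self.s_end else "-"

    def query_interval(self) -> tuple[int, int]:
        """Query span as a 0-based half-open interval (strand-folded)."""
        lo, hi = sorted((self.q_start, self.q_end))
        return lo - 1, hi

    def subject_interval(self) -> tuple[int, int]:
        """Subject span as a 0-based half-open interval (strand-folded)."""
        lo, hi = sorted((self.s_start, self.s_end))
        return lo - 1, hi


@dataclass
class LibraryMetadata:
    """Per-library facts feeding the coverage equations.

    ``mean_insert`` and ``genome_size`` are in bases; ``empty_fraction``
    and ``organellar_fraction`` are proportions of clones carrying no
    nuclear insert.
    """

    library_id: str
    clone_count: int
    mean_insert: float
    empty_fraction: float
    organellar_fraction: float
    genome_size: float

    def __post_init__(self) -> None:
        if self.clone_count < 0:
            raise ValueError("clone_count must be >= 0")
        if self.genome_size <= 0:
            raise ValueError("genome_size must be > 0")
        for name in ("empty_fraction", "organellar_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of (id, uppercase sequence).

    IUPAC ambiguity codes other than N are mapped to N with a logged
    warning.  Raises :class:`FastaParseError` for an empty file or a file
    whose first non-blank line is not a header, naming the line number.
    """
    path = Path(path)
    with open(path) as fh:
        lineno = 0
        for line in fh:
            lineno += 1
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected FASTA header, "
                        f"got {line.strip()[:40]!r}"
                    )
                break
        else:
            raise FastaParseError(f"{path}: empty FASTA file (line {lineno or 1})")

    out: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        cleaned = seq.translate(_AMBIG_TABLE)
        if cleaned != seq:
            n_amb = sum(a != b for a, b in zip(seq, cleaned))
            logger.warning(
                "record %s: %d ambiguity base(s) mapped to N", rec.id, n_amb
            )
        bad = set(cleaned) - _VALID_BASES
        if bad:
            raise FastaParseError(
                f"{path}: record {rec.id}: invalid characters {sorted(bad)}"
            )
        out.append((rec.id, cleaned))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def parse_read_id(read_id: str, pattern: str = DEFAULT_END_PATTERN) -> tuple[str, str]:
    """Split a read id into (clone_id, end) using ``pattern``.

    The pattern must expose ``clone`` and ``end`` groups; end group values
    beginning with f/F (after stripping) map to forward, r/R to reverse.
    """
    m = re.match(pattern, read_id)
    if not m:
        raise ValueError(f"read id {read_id!r} does not match pattern {pattern!r}")
    end_tag = m.group("end").lower()
    if end_tag.startswith("f"):
        end = FORWARD
    elif end_tag.startswith("r"):
        end = REVERSE
    else:
        raise ValueError(f"read id {read_id!r}: cannot interpret end tag {end_tag!r}")
    return m.group("clone"), end


def pair_bes(
    records: Sequence[BesRecord],
) -> tuple[dict[str, dict[str, BesRecord]], list[BesRecord], float]:
    """Group end-reads by clone.

    Returns (clone map for clones with both ends, reads from incomplete
    clones, paired fraction in percent).  The paired fraction is
    100 x (reads belonging to clones with both ends) / total reads.
    Duplicate (clone, end) combinations are an error.
    """
    by_clone: dict[str, dict[str, BesRecord]] = {}
    dupes: list[str] = []
    for rec in records:
        slot = by_clone.setdefault(rec.clone_id, {})
        if rec.end in slot:
            dupes.append(f"{rec.clone_id}/{rec.end}")
        slot[rec.end] = rec
    if dupes:
        raise ValueError(f"duplicate clone/end combinations: {', '.join(sorted(dupes))}")
    if not records:
        return {}, [], 0.0
    paired = {c: ends for c, ends in by_clone.items() if len(ends) == 2}
    unpaired = [
        rec for c, ends in by_clone.items() if len(ends) < 2 for rec in ends.values()
    ]
    frac = 100.0 * (2 * len(paired)) / len(records)
    return paired, unpaired, frac


# --- GFF3 ---------------------------------------------------------------

_GFF_RESERVED = re.compile(r"[;=&,\t\n]")
_GFF_HEADER = "##gff-version 3"


def write_gff3(
    features: Iterable[tuple[GenomicInterval, str, Mapping[str, str]]],
    path: str | Path,
    source: str = "bes_survey",
) -> None:
    """Write features as GFF3, converting to 1-based inclusive coordinates.

    Attribute keys/values containing an unescaped reserved character
    (``; = & ,`` tab or newline) raise ``ValueError``; percent-escape them
    first (:func:`escape_gff3`) if needed.
    """
    with open(path, "w") as fh:
        fh.write(_GFF_HEADER + "\n")
        for interval, ftype, attrs in features:
            parts = []
            for k, v in attrs.items():
                if _GFF_RESERVED.search(k) or _GFF_RESERVED.search(str(v)):
                    raise ValueError(
                        f"unescaped reserved character in attribute {k}={v!r}"
                    )
                parts.append(f"{k}={v}")
            attr_col = ";".join(parts) if parts else "."
            fh.write(
                "\t".join(
                    [
                        interval.seq_id,
                        source,
                        ftype,
                        str(interval.start + 1),
                        str(interval.end),
                        ".",
                        interval.strand if interval.strand != "." else ".",
                        ".",
                        attr_col,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[tuple[GenomicInterval, str, dict[str, str]]]:
    """Companion reader for :func:`write_gff3`; restores 0-based intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: expected 9 GFF3 columns, got {len(cols)}")
            seq_id, _source, ftype, start, end, _score, strand, _phase, attr_col = cols
            attrs: dict[str, str] = {}
            if attr_col != ".":
                for part in attr_col.split(";"):
                    if part:
                        k, _, v = part.partition("=")
                        attrs[k] = v
            interval = GenomicInterval(seq_id, int(start) - 1, int(end), strand if strand in "+-" else ".")
            out.append((interval, ftype, attrs))
    return out


def escape_gff3(value: str) -> str:
    """Percent-escape GFF3 reserved characters in an attribute value."""
    return urllib.parse.quote(value, safe=" |:/().-_")


# --- 12-column tabular alignments --------------------------------------

TABULAR_COLUMNS = [
    "query_id",
    "subject_id",
    "pct_identity",
    "aln_len",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bit_score",
]


def read_tabular_hits(path: str | Path) -> list[AlignmentHit]:
    """Read a 12-column (BLAST outfmt-6 field order) alignment table."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(cols)}"
                )
            hits.append(
                AlignmentHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    pct_identity=float(cols[2]),
                    aln_len=int(cols[3]),
                    mismatches=int(cols[4]),
                    gap_opens=int(cols[5]),
                    q_start=int(cols[6]),
                    q_end=int(cols[7]),
                    s_start=int(cols[8]),
                    s_end=int(cols[9]),
                    evalue=float(cols[10]),
                    bit_score=float(cols[11]),
                )
            )
    return hits


def write_tabular_hits(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:.2f}",
                        str(h.aln_len),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        f"{h.evalue:.2e}",
                        f"{h.bit_score:.1f}",
                    ]
                )
                + "\n"
            )


def records_from_fasta(
    path: str | Path,
    library_id: str = "lib",
    pattern: str = DEFAULT_END_PATTERN,
) -> list[BesRecord]:
    """Read BES reads from FASTA, parsing clone/end identity from read ids."""
    out = []
    for name, seq in read_fasta(path):
        clone, end = parse_read_id(name, pattern)
        out.append(BesRecord(name, clone, end, library_id, seq))
    return out
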