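"""Deterministic simulator for genomes, BAC clones and end-reads.

The generator produces the complete test bed the survey needs without any
download: a background genome at a configured GC content with planted SSR
loci, repeat families of known copy number and divergence, GC-rich
single-exon genes (GC-biased codon choice when back-translating random
peptides), organellar contaminant sequences; BAC clones with
truncated-normal insert sizes and two inward-facing end-reads each
(reverse end reverse-complemented, per-base substitution errors); and a
rearranged related reference (inversions, translocations to separate
chromosomes, indels) with every operation recorded and the gene
annotation lifted through it.  Everything is a pure function of
(config, seed): the same seed gives byte-identical output.

The default read-length model is a truncated normal, mean 761 and bounds
[100, 1000], echoing the read-length distribution of large Sanger BES
sets; clone counts and genome sizes are scaled down by configuration.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .comparative_mapper import GeneModel, OrthologPair
from .core_io import BesRecord, FORWARD, REVERSE, GenomicInterval

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_CODONS: dict[str, list[str]] = {}


def _codon_table() -> dict[str, list[str]]:
    if not _CODONS:
        from Bio.Data.CodonTable import standard_dna_table

        for codon, aa in standard_dna_table.forward_table.items():
            _CODONS.setdefault(aa, []).append(codon)
        for aas in _CODONS.values():
            aas.sort()
    return _CODONS


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# --- configuration ------------------------------------------------------


@dataclass
class RepeatFamilySpec:
    name: str
    class_path: str
    length: int
    copy_number: int
    divergence: float = 0.05  # per-base substitution rate per copy

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence <= 1.0):
            raise ValueError("divergence must be in [0, 1]")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")


@dataclass
class SsrSpec:
    motif: str
    count: int
    min_units: int = 6
    max_units: int = 12


@dataclass
class GeneSpec:
    count: int
    peptide_min: int = 150
    peptide_max: int = 450
    gc3_bias: float = 0.9  # probability of choosing a G/C-ending codon
    #: "random" scatters genes by rejection sampling (sparse genomes);
    #: "tiled" lays them out sequentially with intergenic gaps drawn from
    #: ``gap_range`` (gene-dense reference regions)
    arrangement: str = "random"
    gap_range: tuple[int, int] = (200, 400)
    tiled_offset: int = 1000


@dataclass
class OrganellarSpec:
    n_sequences: int = 1
    seq_length: int = 120_000
    clone_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.clone_fraction <= 1.0):
            raise ValueError("clone_fraction must be in [0, 1]")


@dataclass
class CloneModel:
    count: int = 1500
    insert_mean: float = 120_000
    insert_sd: float = 25_000
    insert_min: float = 30_000
    insert_max: float = 280_000


@dataclass
class ReadModel:
    length_mean: float = 761
    length_sd: float = 120
    length_min: int = 100
    length_max: int = 1000
    #: post-trim high-quality Sanger base error (~Q27)
    error_rate: float = 0.002


@dataclass
class RearrangementSpec:
    n_inversions: int = 0
    inversion_len: tuple[int, int] = (50_000, 150_000)
    n_translocations: int = 0
    translocation_len: tuple[int, int] = (50_000, 150_000)
    n_deletions: int = 0
    deletion_len: tuple[int, int] = (500, 5_000)
    n_insertions: int = 0
    insertion_len: tuple[int, int] = (500, 5_000)
    max_retries: int = 200


@dataclass
class SimConfig:
    seed: int = 0
    genome_length: int = 2_000_000
    background_gc: float = 0.45
    repeat_families: list[RepeatFamilySpec] = field(default_factory=list)
    ssrs: list[SsrSpec] = field(default_factory=list)
    genes: GeneSpec | None = None
    organellar: OrganellarSpec = field(default_factory=OrganellarSpec)
    clone_model: CloneModel = field(default_factory=CloneModel)
    read_model: ReadModel = field(default_factory=ReadModel)
    rearrangement: RearrangementSpec = field(default_factory=RearrangementSpec)
    library_id: str = "SimAB"

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        kwargs = dict(raw)
        kwargs["repeat_families"] = [
            RepeatFamilySpec(**d) for d in raw.get("repeat_families", [])
        ]
        kwargs["ssrs"] = [SsrSpec(**d) for d in raw.get("ssrs", [])]
        if raw.get("genes"):
            d = dict(raw["genes"])
            if "gap_range" in d:
                d["gap_range"] = tuple(d["gap_range"])
            kwargs["genes"] = GeneSpec(**d)
        for key, klass in (
            ("organellar", OrganellarSpec),
            ("clone_model", CloneModel),
            ("read_model", ReadModel),
        ):
            if raw.get(key):
                kwargs[key] = klass(**raw[key])
        if raw.get("rearrangement"):
            d = dict(raw["rearrangement"])
            for k in ("inversion_len", "translocation_len", "deletion_len", "insertion_len"):
                if k in d:
                    d[k] = tuple(d[k])
            kwargs["rearrangement"] = RearrangementSpec(**d)
        return cls(**kwargs)


# --- truth --------------------------------------------------------------


@dataclass
class PlantedRepeat:
    family: str
    class_path: str
    interval: GenomicInterval
    sequence: str  # the mutated copy as planted


@dataclass
class PlantedSsr:
    interval: GenomicInterval
    motif: str


@dataclass
class CloneTruth:
    clone_id: str
    source_id: str  # "genome" or an organellar sequence id
    start: int
    end: int
    contaminant: bool


@dataclass
class RearrangementOp:
    op: str  # inversion | translocation | deletion | insertion
    start: int  # original genome coordinates (insertion: point)
    end: int
    target: str  # destination sequence id


@dataclass
class TruthSet:
    ssr_loci: list[PlantedSsr] = field(default_factory=list)
    repeat_copies: list[PlantedRepeat] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)
    family_consensus: dict[str, str] = field(default_factory=dict)
    organellar_seqs: dict[str, str] = field(default_factory=dict)
    clones: list[CloneTruth] = field(default_factory=list)


# --- genome -------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _back_translate(rng: np.random.Generator, peptide: str, gc3_bias: float) -> str:
    table = _codon_table()
    codons = []
    for aa in peptide:
        options = table[aa]
        gc_end = [c for c in options if c[2] in "GC"]
        at_end = [c for c in options if c[2] not in "GC"]
        if gc_end and (not at_end or rng.random() < gc3_bias):
            codons.append(gc_end[int(rng.integers(len(gc_end)))])
        else:
            codons.append(at_end[int(rng.integers(len(at_end)))])
    return "".join(codons)


class _Placer:
    """Non-overlapping placement of features with a safety margin."""

    def __init__(self, rng: np.random.Generator, genome_length: int, margin: int = 12):
        self.rng = rng
        self.length = genome_length
        self.margin = margin
        self.taken: list[tuple[int, int]] = []

    def place(self, feat_len: int, retries: int = 400) -> int:
        if feat_len + 2 * self.margin >= self.length:
            raise ValueError("feature longer than the genome")
        for _ in range(retries):
            start = int(self.rng.integers(self.margin, self.length - feat_len - self.margin))
            lo, hi = start - self.margin, start + feat_len + self.margin
            if all(hi <= a or b <= lo for a, b in self.taken):
                self.taken.append((lo, hi))
                return start
        raise RuntimeError(
            "could not place feature without overlap; genome too crowded"
        )


def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None) -> tuple[str, TruthSet]:
    """Background genome with planted SSRs, repeat families and genes."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    planned = sum(f.length * f.copy_number for f in config.repeat_families)
    planned += sum(s.count * len(s.motif) * s.max_units for s in config.ssrs)
    if config.genes and config.genes.arrangement != "tiled":
        # tiled genes self-limit to the genome; only scattered genes
        # compete with other plantings for space
        planned += config.genes.count * (config.genes.peptide_max + 2) * 3
    if planned >= config.genome_length:
        raise ValueError(
            f"requested plantings ({planned} bp) exceed genome length"
        )
    genome = list(_random_seq(rng, config.genome_length, config.background_gc))
    placer = _Placer(rng, config.genome_length)
    truth = TruthSet()

    for fam in config.repeat_families:
        consensus = _random_seq(rng, fam.length, 0.5)
        truth.family_consensus[fam.name] = consensus
        for _copy in range(fam.copy_number):
            copy_seq = _mutate(rng, consensus, fam.divergence)
            start = placer.place(fam.length)
            genome[start : start + fam.length] = copy_seq
            truth.repeat_copies.append(
                PlantedRepeat(
                    fam.name,
                    fam.class_path,
                    GenomicInterval("genome", start, start + fam.length),
                    copy_seq,
                )
            )

    if config.genes:
        gs = config.genes
        aa_alpha = sorted(_codon_table().keys() - {"M"})
        cursor = gs.tiled_offset
        for gi in range(gs.count):
            pep_len = int(rng.integers(gs.peptide_min, gs.peptide_max + 1))
            body = "".join(
                aa_alpha[int(rng.integers(len(aa_alpha)))] for _ in range(pep_len - 1)
            )
            peptide = "M" + body
            cds = _back_translate(rng, peptide, gs.gc3_bias) + "TGA"
            strand = "+" if rng.random() < 0.5 else "-"
            planted = cds if strand == "+" else revcomp(cds)
            if gs.arrangement == "tiled":
                start = cursor + int(rng.integers(gs.gap_range[0], gs.gap_range[1] + 1))
                cursor = start + len(cds)
                if cursor >= config.genome_length:
                    # tiled mode fills the genome; count is an upper bound
                    break
                placer.taken.append((start, cursor))
            else:
                start = placer.place(len(cds))
            genome[start : start + len(cds)] = planted
            truth.genes.append(
                GeneModel(
                    gene_id=f"g{gi + 1:04d}",
                    interval=GenomicInterval("genome", start, start + len(cds), strand),
                    peptide=peptide,
                )
            )

    for spec in config.ssrs:
        p = len(spec.motif)
        for _ in range(spec.count):
            units = int(rng.integers(spec.min_units, spec.max_units + 1))
            run = spec.motif * units
            start = placer.place(len(run))
            genome[start : start + len(run)] = run
            # break the periodicity at both flanks so the planted locus is
            # exactly the maximal run
            left = start - 1
            if left >= 0 and genome[left] == genome[left + p]:
                genome[left] = _other_base(rng, genome[left + p])
            right = start + len(run)
            if right < len(genome) and genome[right] == genome[right - p]:
                genome[right] = _other_base(rng, genome[right - p])
            truth.ssr_loci.append(
                PlantedSsr(
                    GenomicInterval("genome", start, start + len(run)), spec.motif
                )
            )

    org = config.organellar
    for i in range(org.n_sequences):
        truth.organellar_seqs[f"organelle{i + 1}"] = _random_seq(
            rng, org.seq_length, 0.38
        )
    return "".join(genome), truth


def _other_base(rng: np.random.Generator, base: str) -> str:
    options = [b for b in "ACGT" if b != base]
    return options[int(rng.integers(3))]


# --- clones and reads ---------------------------------------------------


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(mean, lo, hi))


def simulate_bes(
    genome: str,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    truth: TruthSet | None = None,
) -> tuple[list[BesRecord], list[CloneTruth]]:
    """Paired end-reads from uniformly placed clones, plus clone truth.

    Two inward-facing reads per clone; the reverse-end read is
    reverse-complemented.  Contaminant clones are drawn from the
    organellar sequences at the configured fraction.  Per-base
    substitution errors are applied at the read error rate.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    cm, rm, org = config.clone_model, config.read_model, config.organellar
    if cm.insert_mean >= len(genome):
        raise ValueError("insert mean must be smaller than the genome")
    organellar = truth.organellar_seqs if truth is not None else {}
    records: list[BesRecord] = []
    clones: list[CloneTruth] = []
    for i in range(cm.count):
        clone_id = f"{config.library_id}_{i + 1:06d}"
        contaminant = bool(organellar) and rng.random() < org.clone_fraction
        if contaminant:
            source_id = sorted(organellar)[int(rng.integers(len(organellar)))]
            source = organellar[source_id]
        else:
            source_id, source = "genome", genome
        insert = int(
            _truncated_normal(
                rng, cm.insert_mean, cm.insert_sd, cm.insert_min, min(cm.insert_max, len(source))
            )
        )
        insert = min(insert, len(source))
        start = int(rng.integers(0, len(source) - insert + 1))
        end = start + insert
        clones.append(CloneTruth(clone_id, source_id, start, end, contaminant))
        for end_tag, endedness in ((".f", FORWARD), (".r", REVERSE)):
            rlen = int(
                _truncated_normal(rng, rm.length_mean, rm.length_sd, rm.length_min, rm.length_max)
            )
            rlen = min(rlen, insert)
            if endedness == FORWARD:
                raw = source[start : start + rlen]
            else:
                raw = revcomp(source[end - rlen : end])
            seq = _mutate(rng, raw, rm.error_rate)
            records.append(
                BesRecord(
                    read_id=clone_id + end_tag,
                    clone_id=clone_id,
                    end=endedness,
                    library_id=config.library_id,
                    sequence=seq,
                )
            )
    return records, clones


# --- rearranged related reference ---------------------------------------


@dataclass
class RelatedReference:
    chromosomes: dict[str, str]
    genes: list[GeneModel]  # lifted annotation (same gene ids)
    ledger: list[RearrangementOp]

    def orthology(self, original_genes: Sequence[GeneModel]) -> list[OrthologPair]:
        """Ortholog pairs between original and lifted gene orders."""
        lifted = {g.gene_id: g for g in self.genes}
        order_a = sorted(
            original_genes, key=lambda g: (g.interval.seq_id, g.interval.start)
        )
        order_b = sorted(
            self.genes, key=lambda g: (g.interval.seq_id, g.interval.start)
        )
        rank_b = {g.gene_id: i for i, g in enumerate(order_b)}
        out = []
        for i, g in enumerate(order_a):
            if g.gene_id in lifted:
                out.append(
                    OrthologPair(
                        pos_a=i,
                        pos_b=rank_b[g.gene_id],
                        strand_a=g.strand,
                        strand_b=lifted[g.gene_id].strand,
                        gene_a=g.gene_id,
                        gene_b=g.gene_id,
                    )
                )
        return out


def _breakpoint_candidates(genome_length: int, genes: Sequence[GeneModel]) -> list[int]:
    """Positions between genes where the genome may be cut cleanly."""
    margin = 50
    ordered = sorted(genes, key=lambda g: g.interval.start)
    cands = []
    prev_end = 0
    for g in ordered:
        if g.interval.start - prev_end > 2 * margin:
            cands.append((prev_end + g.interval.start) // 2)
        prev_end = max(prev_end, g.interval.end)
    if genome_length - prev_end > 2 * margin:
        cands.append((prev_end + genome_length) // 2)
    return cands


def _pick_segment(
    rng: np.random.Generator,
    genome_length: int,
    length_range: tuple[int, int],
    taken: list[tuple[int, int]],
    breakpoint_pool: Sequence[int],
    retries: int,
) -> tuple[int, int]:
    """A segment cut at intergenic breakpoints, avoiding other operations."""
    pool = np.asarray(sorted(breakpoint_pool))
    if len(pool) < 2:
        raise RuntimeError("no intergenic breakpoints available")
    for _ in range(retries):
        start = int(pool[int(rng.integers(len(pool)))])
        ends = pool[
            (pool >= start + length_range[0]) & (pool <= start + length_range[1])
        ]
        if len(ends) == 0:
            continue
        end = int(ends[int(rng.integers(len(ends)))])
        if any(start < b and a < end for a, b in taken):
            continue
        taken.append((start, end))
        return start, end
    raise RuntimeError("could not place rearrangement without overlap")


def simulate_related_reference(
    genome: str,
    genes: Sequence[GeneModel],
    spec: RearrangementSpec,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> RelatedReference:
    """Apply recorded rearrangements to derive a related reference.

    Inversions flip a segment in place; translocations move a segment to
    its own new chromosome; deletions remove intergenic sequence;
    insertions add novel sequence.  Gene annotation is lifted through the
    block structure (inverted genes strand-flip and order-reverse);
    deleted genes disappear from the annotation.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = len(genome)
    pool = _breakpoint_candidates(n, genes)
    taken: list[tuple[int, int]] = []
    ops: list[RearrangementOp] = []
    for _ in range(spec.n_translocations):
        a, b = _pick_segment(rng, n, spec.translocation_len, taken, pool, spec.max_retries)
        ops.append(RearrangementOp("translocation", a, b, ""))
    for _ in range(spec.n_inversions):
        a, b = _pick_segment(rng, n, spec.inversion_len, taken, pool, spec.max_retries)
        ops.append(RearrangementOp("inversion", a, b, "chr1"))
    for _ in range(spec.n_deletions):
        a, b = _pick_segment(rng, n, spec.deletion_len, taken, pool, spec.max_retries)
        ops.append(RearrangementOp("deletion", a, b, ""))
    insert_seqs: dict[int, str] = {}
    for _ in range(spec.n_insertions):
        a, b = _pick_segment(rng, n, spec.insertion_len, taken, pool, spec.max_retries)
        # reuse the segment pick for a collision-free insertion point a
        insert_seqs[a] = _random_seq(rng, b - a, 0.45)
        ops.append(RearrangementOp("insertion", a, a, "chr1"))

    # block decomposition of the original genome
    cuts = sorted({0, n} | {c for op in ops for c in (op.start, op.end)})
    blocks = [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)]
    op_at = {}
    for op in ops:
        if op.op != "insertion":
            op_at[(op.start, op.end)] = op

    chromosomes: dict[str, list[str]] = {"chr1": []}
    offsets: dict[tuple[int, int], tuple[str, int, bool]] = {}
    t_index = 0
    pos = {"chr1": 0}
    for a, b in blocks:
        op = op_at.get((a, b))
        if op is None or op.op == "inversion":
            if a in insert_seqs:
                ins = insert_seqs[a]
                chromosomes["chr1"].append(ins)
                pos["chr1"] += len(ins)
            inverted = op is not None
            seq = genome[a:b]
            chromosomes["chr1"].append(revcomp(seq) if inverted else seq)
            offsets[(a, b)] = ("chr1", pos["chr1"], inverted)
            pos["chr1"] += b - a
        elif op.op == "translocation":
            t_index += 1
            chrom = f"chrT{t_index}"
            op.target = chrom
            chromosomes[chrom] = [genome[a:b]]
            offsets[(a, b)] = (chrom, 0, False)
            pos[chrom] = b - a
        elif op.op == "deletion":
            continue
    # trailing insertion at position n
    if n in insert_seqs:
        chromosomes["chr1"].append(insert_seqs[n])

    lifted: list[GeneModel] = []
    for g in genes:
        home = None
        for (a, b), dest in offsets.items():
            if a <= g.interval.start and g.interval.end <= b:
                home = ((a, b), dest)
                break
        if home is None:
            continue  # gene fell in a deleted block
        (a, b), (chrom, off, inverted) = home
        if inverted:
            new_start = off + (b - g.interval.end)
            new_end = off + (b - g.interval.start)
            new_strand = "-" if g.strand == "+" else "+"
        else:
            new_start = off + (g.interval.start - a)
            new_end = off + (g.interval.end - a)
            new_strand = g.strand
        lifted.append(
            GeneModel(
                gene_id=g.gene_id,
                interval=GenomicInterval(chrom, new_start, new_end, new_strand),
                peptide=g.peptide,
            )
        )
    return RelatedReference(
        chromosomes={k: "".join(v) for k, v in chromosomes.items()},
        genes=lifted,
        ledger=ops,
    )


def breakpoints(ledger: Sequence[RearrangementOp]) -> list[int]:
    """Original-genome coordinates where contiguity is broken."""
    out = []
    for op in ledger:
        if op.op == "insertion":
            out.append(op.start)
        else:
            out.extend((op.start, op.end))
    return sorted(set(out))
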