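"""Shared fixtures: synthetic benchmarks built once per session."""

from __future__ import annotations

import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from bes_survey import synthetic_data as sd


@dataclass
class RepeatBench:
    """2 Mbp genome with 20 novel families, 3 known families and SSRs.

    ``control_reads`` carry an injected 200 bp element present in exactly
    five reads, below the novel-repeat support rule.
    """

    config: sd.SimConfig
    genome: str
    truth: sd.TruthSet
    reads: list
    clones: list
    read_tuples: list[tuple[str, str]]
    novel_families: list[str]
    known_families: list[str]
    control_seq: str
    control_reads: list[str]
    corpus_bases: int


@pytest.fixture(scope="session")
def repeat_bench() -> RepeatBench:
    rng0 = np.random.default_rng(101)
    novel = [
        sd.RepeatFamilySpec(
            f"sre{i:02d}", "novel", int(rng0.integers(150, 301)), int(rng0.integers(25, 46)), 0.03
        )
        for i in range(20)
    ]
    known = [
        sd.RepeatFamilySpec("gypsy1", "Retroelements/LTR/Ty3-Gypsy-DIRS1", 1200, 60, 0.08),
        sd.RepeatFamilySpec("copia1", "Retroelements/LTR/Ty1-Copia", 900, 30, 0.08),
        sd.RepeatFamilySpec("enspm1", "DNATransposons/En-Spm", 700, 25, 0.08),
    ]
    config = sd.SimConfig(
        seed=101,
        genome_length=2_000_000,
        background_gc=0.44,
        repeat_families=known + novel,
        ssrs=[
            sd.SsrSpec("AGC", 60, 5, 10),
            sd.SsrSpec("AT", 60, 7, 12),
            sd.SsrSpec("GCC", 60, 4, 9),
            sd.SsrSpec("AAG", 60, 5, 9),
        ],
        clone_model=sd.CloneModel(
            count=1000, insert_mean=100_000, insert_sd=20_000,
            insert_min=40_000, insert_max=200_000,
        ),
        read_model=sd.ReadModel(error_rate=0.002),
    )
    genome, truth = sd.simulate_genome(config)
    reads, clones = sd.simulate_bes(genome, config, truth=truth)
    control = sd._random_seq(np.random.default_rng(999), 200, 0.5)
    # control reads must carry no planted repeat and share no >=50 bp
    # genomic overlap with any other read, so their only self-matches
    # come from the injected element
    by_clone = {c.clone_id: c for c in clones}

    def interval(r):
        c = by_clone[r.clone_id]
        if r.end == "forward":
            return (c.start, c.start + r.length)
        return (c.end - r.length, c.end)

    ivs = {r.read_id: interval(r) for r in reads}

    def isolated(r):
        a, b = ivs[r.read_id]
        if any(
            min(b, rc.interval.end) - max(a, rc.interval.start) > 0
            for rc in truth.repeat_copies
        ):
            return False
        return not any(
            other != r.read_id
            and min(b, ivs[other][1]) - max(a, ivs[other][0]) >= 50
            for other in ivs
        )

    chosen = [r.read_id for r in reads if r.length > 400 and isolated(r)][:5]
    read_tuples = []
    for r in reads:
        seq = r.sequence
        if r.read_id in chosen:
            seq = seq[:100] + control + seq[100 + len(control):]
        read_tuples.append((r.read_id, seq))
    return RepeatBench(
        config=config,
        genome=genome,
        truth=truth,
        reads=reads,
        clones=clones,
        read_tuples=read_tuples,
        novel_families=[f.name for f in novel],
        known_families=[f.name for f in known],
        control_seq=control,
        control_reads=chosen,
        corpus_bases=sum(len(s) for _, s in read_tuples),
    )


@dataclass
class SyntenyBench:
    """Gene-dense 600 kb genome plus a rearranged related reference."""

    config: sd.SimConfig
    genome: str
    truth: sd.TruthSet
    reference: sd.RelatedReference
    reads: list
    clones: list
    read_tuples: list[tuple[str, str]]
    max_insert: int


@pytest.fixture(scope="session")
def synteny_bench() -> SyntenyBench:
    config = sd.SimConfig(
        seed=11,
        genome_length=600_000,
        background_gc=0.44,
        genes=sd.GeneSpec(
            count=500, peptide_min=420, peptide_max=500, gc3_bias=0.9,
            arrangement="tiled", gap_range=(150, 250),
        ),
        clone_model=sd.CloneModel(
            count=250, insert_mean=40_000, insert_sd=6_000,
            insert_min=25_000, insert_max=60_000,
        ),
        read_model=sd.ReadModel(error_rate=0.002),
        rearrangement=sd.RearrangementSpec(
            n_inversions=1, inversion_len=(170_000, 190_000),
            n_translocations=2, translocation_len=(60_000, 120_000),
        ),
    )
    genome, truth = sd.simulate_genome(config)
    reference = sd.simulate_related_reference(
        genome, truth.genes, config.rearrangement, seed=12
    )
    reads, clones = sd.simulate_bes(genome, config, truth=truth)
    return SyntenyBench(
        config=config,
        genome=genome,
        truth=truth,
        reference=reference,
        reads=reads,
        clones=clones,
        read_tuples=[(r.read_id, r.sequence) for r in reads],
        max_insert=100_000,
    )
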