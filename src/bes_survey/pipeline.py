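"""End-to-end survey orchestration and report generation.

``run_survey`` executes the stages in the canonical order — library
statistics, SSR detection, known-repeat masking, novel-repeat mining, GC
partitioning, comparative mapping — skipping (with a logged reason) any
stage whose inputs are absent, and emits a plain-text report plus a
machine-readable manifest.  Stage outputs are pure functions of
(inputs, config, seed); a rerun with the same seed reproduces the report
byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import (
    coding_gc,
    comparative_mapper as cm,
    core_io,
    library_stats,
    repeat_annotator,
    sre_miner,
    ssr_finder,
)
from .core_io import BesRecord, LibraryMetadata
from .library_stats import HybridizationScreen
from .repeat_annotator import RepeatLibraryEntry

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage thresholds; defaults are the survey's canonical values."""

    genome_size: float
    out_dir: Path | str = "survey_out"
    seed: int = 0
    # SSR rules: 1-3 nt motifs need >= 12 nt, 4-6 nt motifs >= 4 units
    ssr_min_len_short: int = 12
    ssr_min_units_long: int = 4
    # repeat annotation
    repeat_min_identity: float = 70.0
    repeat_min_length: int = 50
    # novel-repeat self-comparison
    sre_window: int = 100
    sre_min_identity: float = 90.0
    sre_evalue: float = 1e-50
    sre_min_support: int = 6
    # comparative mapping
    map_min_identity: float = 75.0
    map_max_evalue: float = 1e-20
    map_min_coverage: float = 0.5
    max_insert: int = 500_000
    collinearity_max_gap: int = 2


@dataclass
class SurveyInputs:
    reads: Sequence[BesRecord] | None = None
    library_meta: Sequence[LibraryMetadata] | None = None
    screens: Sequence[HybridizationScreen] | None = None
    repeat_library: Sequence[RepeatLibraryEntry] | None = None
    ref_genes: Sequence[cm.GeneModel] | None = None
    ref_genome: dict[str, str] | None = None
    go_table: pd.DataFrame | None = None


@dataclass
class SurveyResult:
    report_text: str
    manifest: dict
    ssr_summary: ssr_finder.SsrSummary | None = None
    repeat_summary: repeat_annotator.RepeatSummary | None = None
    sre_candidates: list | None = None
    gc_partition: coding_gc.GcPartition | None = None
    pairs: list | None = None
    singlets: list | None = None
    masked_reads: dict[str, str] | None = None


def _fmt(value, nd=2) -> str:
    if value is None:
        return "NA"
    return f"{value:.{nd}f}"


def run_survey(config: PipelineConfig, inputs: SurveyInputs) -> SurveyResult:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines: list[str] = ["# BAC-end sequence survey report", ""]
    manifest: dict = {"seed": config.seed, "genome_size": config.genome_size, "stages": {}}
    result = SurveyResult(report_text="", manifest=manifest)

    reads = list(inputs.reads) if inputs.reads else []
    read_tuples = [(r.read_id, r.sequence) for r in reads]
    corpus_bases = sum(r.length for r in reads)

    # --- library statistics --------------------------------------------
    if inputs.library_meta or inputs.screens:
        lines.append("## Library statistics")
        for screen in inputs.screens or ():
            rate = library_stats.contamination_rate(screen)
            lines.append(
                f"screen {screen.probe_set}: {screen.positives}/"
                f"{screen.clones_screened} positive = {_fmt(rate)}% contamination"
            )
        combined = []
        for meta in inputs.library_meta or ():
            eq = library_stats.genome_equivalents(meta)
            lines.append(
                f"library {meta.library_id}: {eq:.2f} genome equivalents "
                f"(~{round(eq)}X)"
            )
            eff = meta.clone_count * (
                1 - meta.empty_fraction - meta.organellar_fraction
            )
            combined.append((eff, meta.mean_insert))
        if combined:
            gs = (inputs.library_meta or [None])[0].genome_size
            p = library_stats.p_find_combined(combined, gs)
            lines.append(
                f"combined probability of finding a given sequence: {_fmt(100 * p, 5)}%"
            )
            manifest["stages"]["stats"] = {"p_find_pct": 100 * p}
        lines.append("")
    else:
        logger.info("stats stage skipped: no library metadata or screens")

    # --- reads-derived stages ------------------------------------------
    if reads:
        lines.append("## Corpus")
        lines.append(f"reads: {len(reads)}; bases: {corpus_bases}")
        _pairs_map, _unpaired, paired_frac = core_io.pair_bes(reads)
        lines.append(f"paired reads: {_fmt(paired_frac, 1)}%")
        genome_fraction = 100.0 * corpus_bases / config.genome_size
        lines.append(f"genome fraction sampled: {_fmt(genome_fraction)}%")
        lines.append("")

        # SSRs
        loci, _ = ssr_finder.find_ssrs_in_corpus(read_tuples)
        ssr_summary = ssr_finder.summarize_ssrs(loci, corpus_bases)
        result.ssr_summary = ssr_summary
        lines.append("## SSRs")
        lines.append(
            f"total SSRs: {ssr_summary.total_count}; bases: {ssr_summary.total_bases}"
        )
        lines.append(
            "density: one SSR per "
            f"{_fmt(ssr_summary.density_kb_per_ssr, 1)} kb"
        )
        for period, count in ssr_summary.by_period.items():
            pct = 100.0 * count / ssr_summary.total_count if ssr_summary.total_count else 0.0
            lines.append(f"period {period}: {count} ({_fmt(pct, 1)}%)")
        lines.append(f"SSRs longer than 20 nt: {ssr_summary.count_over_20nt}")
        core_io.write_gff3(
            ssr_finder.ssr_gff3_features(loci), out_dir / "ssrs.gff3"
        )
        manifest["stages"]["ssr"] = {
            "count": ssr_summary.total_count,
            "density_kb_per_ssr": ssr_summary.density_kb_per_ssr,
        }
        lines.append("")

        # known repeats
        masked_tuples = read_tuples
        if inputs.repeat_library:
            hits, masked = repeat_annotator.annotate_repeats(
                read_tuples,
                inputs.repeat_library,
                repeat_annotator.AnnotationParams(
                    min_identity=config.repeat_min_identity,
                    min_length=config.repeat_min_length,
                ),
            )
            rep_summary = repeat_annotator.summarize_repeats(hits, corpus_bases)
            result.repeat_summary = rep_summary
            result.masked_reads = masked
            masked_tuples = [(rid, masked[rid]) for rid, _ in read_tuples]
            lines.append("## Known repeats")
            for path in sorted(rep_summary.rows):
                count, bases = rep_summary.rows[path]
                lines.append(
                    f"{path}: {count} elements, {bases} bp, {_fmt(rep_summary.pct(path))}%"
                )
            lines.append(
                f"total interspersed repeats: {rep_summary.interspersed_bases()} bp "
                f"({_fmt(rep_summary.interspersed_pct())}%)"
            )
            manifest["stages"]["repeats"] = {
                "interspersed_pct": rep_summary.interspersed_pct()
            }
            core_io.write_fasta(masked_tuples, out_dir / "masked.fasta")
            lines.append("")
        else:
            logger.info("mask stage skipped: no repeat library")

        # novel repeats
        sampled_fraction = min(1.0, corpus_bases / config.genome_size)
        candidates, profile = sre_miner.mine_sres(
            masked_tuples,
            sampled_fraction,
            min_support=config.sre_min_support,
            window=config.sre_window,
            min_identity=config.sre_min_identity,
            evalue_cutoff=config.sre_evalue,
            nucleotide_dbs=(
                {"repeat_library": [(e.name, e.sequence) for e in inputs.repeat_library]}
                if inputs.repeat_library
                else None
            ),
        )
        result.sre_candidates = candidates
        n_matched = sum(1 for c in profile.counts.values() if c > 0)
        lines.append("## Novel repeat elements")
        lines.append(
            f"reads matching at least one other read: {n_matched} "
            f"({_fmt(100.0 * n_matched / len(reads), 1)}%)"
        )
        lines.append(f"families retained: {len(candidates)}")
        for cand in candidates:
            lines.append(
                f"{cand.sre_id}: length {len(cand.consensus)}, support "
                f"{cand.support}, est. genome copies {cand.genome_copies_est}"
            )
        core_io.write_fasta(
            [(c.sre_id, c.consensus) for c in candidates], out_dir / "sre.fasta"
        )
        manifest["stages"]["sre"] = {"families": len(candidates)}
        lines.append("")

        # GC partition via protein signatures on the reference peptides
        signatures: dict[str, list[tuple[int, int]]] = {}
        if inputs.ref_genes:
            tx_hits = cm.translated_search(
                read_tuples, list(inputs.ref_genes), evalue_cutoff=config.map_max_evalue
            )
            signatures = coding_gc.signature_intervals_from_hits(tx_hits)
        partition = coding_gc.partition_gc(read_tuples, signatures)
        result.gc_partition = partition
        lines.append("## GC content")
        lines.append(f"overall GC: {_fmt(partition.overall_gc, 1)}%")
        if signatures:
            lines.append(f"coding GC: {_fmt(partition.coding_gc, 1)}%")
            lines.append(f"non-coding GC: {_fmt(partition.noncoding_gc, 1)}%")
            lines.append(
                f"reads with a protein signature: {_fmt(partition.signature_fraction, 1)}%"
            )
        manifest["stages"]["gc"] = {"overall_gc": partition.overall_gc}
        lines.append("")

        # comparative mapping
        if inputs.ref_genes:
            placements = cm.place_reads(
                read_tuples,
                list(inputs.ref_genes),
                min_identity=config.map_min_identity,
                max_evalue=config.map_max_evalue,
                min_coverage=config.map_min_coverage,
            )
            clone_map = {}
            for clone_id, ends in core_io.pair_bes(reads)[0].items():
                clone_map[clone_id] = (
                    ends[core_io.FORWARD].read_id,
                    ends[core_io.REVERSE].read_id,
                )
            if inputs.ref_genome:
                read_seqs = dict(read_tuples)
                for clone_id, (fid, rid) in sorted(clone_map.items()):
                    placed, missing = None, None
                    if fid in placements and rid not in placements:
                        placed, missing = placements[fid], rid
                    elif rid in placements and fid not in placements:
                        placed, missing = placements[rid], fid
                    if placed is None or not placed.in_coding:
                        continue
                    rescued = cm.rescue_mate(
                        placed,
                        (missing, read_seqs[missing]),
                        inputs.ref_genome,
                        max_insert=config.max_insert,
                        min_identity=config.map_min_identity,
                        min_coverage=config.map_min_coverage,
                    )
                    if rescued is not None:
                        placements[missing] = rescued
            pairs, singlets = cm.call_pairs(
                placements, clone_map, max_insert=config.max_insert
            )
            result.pairs, result.singlets = pairs, singlets
            lines.append("## Comparative mapping")
            lines.append(
                f"placed reads: {len(placements)} of {len(reads)} "
                f"({_fmt(100.0 * len(placements) / len(reads), 1)}%)"
            )
            lines.append(f"paired-end placements: {len(pairs)}")
            lines.append(f"high-scoring singlets: {len(singlets)}")
            coding = cm.coding_overlap(
                list(placements.values()),
                [g.interval for g in inputs.ref_genes],
            )
            lines.append(f"placements in coding sequence: {_fmt(coding)}%")
            manifest["stages"]["map"] = {
                "pairs": len(pairs),
                "singlets": len(singlets),
            }
            lines.append("")
        else:
            logger.info("map stage skipped: no reference genes")

    # GO tabulation from a provided read->term table
    if inputs.go_table is not None:
        go = coding_gc.tabulate_go(inputs.go_table)
        go.to_csv(out_dir / "go_summary.tsv", sep="\t", index=False)
        lines.append("## GO annotation")
        lines.append(
            f"terms: {go['term_id'].nunique() if len(go) else 0}; "
            f"annotated associations: {int(go['reads'].sum()) if len(go) else 0}"
        )
        lines.append("")

    report = "\n".join(lines).rstrip() + "\n"
    (out_dir / "report.txt").write_text(report)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    result.report_text = report
    result.manifest = manifest
    return result
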