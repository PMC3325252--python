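import numpy as np
import pytest

from bes_survey import synthetic_data as sd
from bes_survey.core_io import FORWARD, REVERSE


def small_config(**overrides):
    base = dict(
        seed=5,
        genome_length=120_000,
        repeat_families=[sd.RepeatFamilySpec("famA", "novel", 200, 10, 0.05)],
        ssrs=[sd.SsrSpec("AGC", 8, 5, 9)],
        genes=sd.GeneSpec(count=4, peptide_min=100, peptide_max=150),
        clone_model=sd.CloneModel(
            count=60, insert_mean=20_000, insert_sd=4_000,
            insert_min=8_000, insert_max=40_000,
        ),
        organellar=sd.OrganellarSpec(n_sequences=1, seq_length=30_000, clone_fraction=0.2),
    )
    base.update(overrides)
    return sd.SimConfig(**base)


class TestGenome:
    def test_empty_config_pure_background(self):
        cfg = sd.SimConfig(seed=1, genome_length=10_000)
        genome, truth = sd.simulate_genome(cfg)
        assert len(genome) == 10_000
        assert not truth.ssr_loci and not truth.repeat_copies and not truth.genes

    def test_same_seed_byte_identical(self):
        g1, t1 = sd.simulate_genome(small_config())
        g2, t2 = sd.simulate_genome(small_config())
        assert g1 == g2
        assert [r.sequence for r in t1.repeat_copies] == [
            r.sequence for r in t2.repeat_copies
        ]

    def test_truth_intervals_reproduce_planted_sequence(self):
        genome, truth = sd.simulate_genome(small_config())
        for rc in truth.repeat_copies:
            assert genome[rc.interval.start : rc.interval.end] == rc.sequence
        for s in truth.ssr_loci:
            seq = genome[s.interval.start : s.interval.end]
            assert seq.startswith(s.motif)
            p = len(s.motif)
            assert all(seq[i] == seq[i % p] for i in range(len(seq)))

    def test_planted_ssrs_are_maximal(self):
        genome, truth = sd.simulate_genome(small_config())
        for s in truth.ssr_loci:
            p = len(s.motif)
            a, b = s.interval.start, s.interval.end
            assert genome[a - 1] != genome[a - 1 + p]
            assert genome[b] != genome[b - p]

    def test_divergence_matches_observed_identity(self):
        cfg = small_config(
            repeat_families=[sd.RepeatFamilySpec("famA", "novel", 400, 40, 0.05)],
            ssrs=[], genes=None,
        )
        genome, truth = sd.simulate_genome(cfg)
        cons = truth.family_consensus["famA"]
        mism = [
            sum(a != b for a, b in zip(rc.sequence, cons)) / len(cons)
            for rc in truth.repeat_copies
        ]
        # binomial: mean 0.05, se ~ 0.0017 over 40 copies of 400 bp
        assert abs(np.mean(mism) - 0.05) < 3 * np.sqrt(0.05 * 0.95 / (40 * 400))

    def test_gene_peptides_translate_back(self):
        from Bio.Seq import Seq

        genome, truth = sd.simulate_genome(small_config())
        for g in truth.genes:
            cds = genome[g.interval.start : g.interval.end]
            if g.strand == "-":
                cds = sd.revcomp(cds)
            assert str(Seq(cds).translate()) == g.peptide + "*"

    def test_overfull_genome_rejected(self):
        cfg = small_config(
            genome_length=3_000,
            repeat_families=[sd.RepeatFamilySpec("famA", "novel", 200, 40, 0.05)],
        )
        with pytest.raises(ValueError, match="exceed"):
            sd.simulate_genome(cfg)


class TestBes:
    def test_error_free_reads_equal_genomic_substrings(self):
        cfg = small_config(
            read_model=sd.ReadModel(error_rate=0.0),
            organellar=sd.OrganellarSpec(clone_fraction=0.0),
        )
        genome, truth = sd.simulate_genome(cfg)
        reads, clones = sd.simulate_bes(genome, cfg, truth=truth)
        by_clone = {c.clone_id: c for c in clones}
        for r in reads:
            c = by_clone[r.clone_id]
            if r.end == FORWARD:
                assert r.sequence == genome[c.start : c.start + r.length]
            else:
                assert r.sequence == sd.revcomp(genome[c.end - r.length : c.end])

    def test_contaminant_fraction_recovered(self):
        cfg = small_config(
            clone_model=sd.CloneModel(count=2000, insert_mean=15_000, insert_sd=2_000,
                                      insert_min=8_000, insert_max=25_000),
            organellar=sd.OrganellarSpec(n_sequences=1, seq_length=30_000, clone_fraction=0.5),
        )
        genome, truth = sd.simulate_genome(cfg)
        _, clones = sd.simulate_bes(genome, cfg, truth=truth)
        frac = np.mean([c.contaminant for c in clones])
        se = np.sqrt(0.5 * 0.5 / 2000)
        assert abs(frac - 0.5) < 3 * se

    def test_mean_insert_recovered(self):
        cfg = small_config(clone_model=sd.CloneModel(
            count=1000, insert_mean=20_000, insert_sd=3_000,
            insert_min=10_000, insert_max=30_000,
        ))
        genome, truth = sd.simulate_genome(cfg)
        _, clones = sd.simulate_bes(genome, cfg, truth=truth)
        sizes = [c.end - c.start for c in clones if c.source_id == "genome"]
        se = 3_000 / np.sqrt(len(sizes))
        assert abs(np.mean(sizes) - 20_000) < 2.5 * se

    def test_paired_reads_face_inward(self):
        cfg = small_config(read_model=sd.ReadModel(error_rate=0.0),
                           organellar=sd.OrganellarSpec(clone_fraction=0.0))
        genome, truth = sd.simulate_genome(cfg)
        reads, clones = sd.simulate_bes(genome, cfg, truth=truth)
        ends = {r.end for r in reads}
        assert ends == {FORWARD, REVERSE}
        assert len(reads) == 2 * len(clones)

    def test_determinism(self):
        cfg = small_config()
        genome, truth = sd.simulate_genome(cfg)
        r1, _ = sd.simulate_bes(genome, cfg, truth=truth)
        r2, _ = sd.simulate_bes(genome, cfg, truth=truth)
        assert [(a.read_id, a.sequence) for a in r1] == [
            (b.read_id, b.sequence) for b in r2
        ]


class TestRelatedReference:
    def _genic_config(self):
        return sd.SimConfig(
            seed=9,
            genome_length=120_000,
            genes=sd.GeneSpec(count=60, peptide_min=100, peptide_max=140,
                              arrangement="tiled", gap_range=(200, 400)),
        )

    def test_zero_rearrangements_identity(self):
        cfg = self._genic_config()
        genome, truth = sd.simulate_genome(cfg)
        ref = sd.simulate_related_reference(
            genome, truth.genes, sd.RearrangementSpec(), seed=1
        )
        assert ref.chromosomes == {"chr1": genome}
        ortho = ref.orthology(truth.genes)
        assert [(p.pos_a, p.pos_b) for p in ortho] == [
            (i, i) for i in range(len(truth.genes))
        ]
        assert all(p.strand_a == p.strand_b for p in ortho)

    def test_inversion_flips_strands_and_order(self):
        cfg = self._genic_config()
        genome, truth = sd.simulate_genome(cfg)
        spec = sd.RearrangementSpec(n_inversions=1, inversion_len=(5_000, 9_000))
        ref = sd.simulate_related_reference(genome, truth.genes, spec, seed=3)
        (inv,) = ref.ledger
        inside = [g for g in truth.genes if inv.start <= g.interval.start and g.interval.end <= inv.end]
        assert len(inside) >= 3
        lifted = {g.gene_id: g for g in ref.genes}
        for g in inside:
            assert lifted[g.gene_id].strand != g.strand
        # order reversed among the inverted genes
        orig_order = [g.gene_id for g in sorted(inside, key=lambda g: g.interval.start)]
        new_order = [
            g.gene_id
            for g in sorted(
                (lifted[g.gene_id] for g in inside), key=lambda g: g.interval.start
            )
        ]
        assert new_order == list(reversed(orig_order))

    def test_lifted_gene_sequences_conserved(self):
        cfg = self._genic_config()
        genome, truth = sd.simulate_genome(cfg)
        spec = sd.RearrangementSpec(
            n_inversions=1, inversion_len=(5_000, 9_000),
            n_translocations=1, translocation_len=(10_000, 20_000),
        )
        ref = sd.simulate_related_reference(genome, truth.genes, spec, seed=4)
        originals = {g.gene_id: g for g in truth.genes}
        for g in ref.genes:
            new = ref.chromosomes[g.interval.seq_id][g.interval.start : g.interval.end]
            og = originals[g.gene_id]
            orig = genome[og.interval.start : og.interval.end]
            if og.strand != g.strand:
                orig = sd.revcomp(orig)
            assert new == orig

    def test_deleted_genes_disappear(self):
        cfg = self._genic_config()
        genome, truth = sd.simulate_genome(cfg)
        spec = sd.RearrangementSpec(n_deletions=1, deletion_len=(4_000, 8_000))
        ref = sd.simulate_related_reference(genome, truth.genes, spec, seed=5)
        (op,) = ref.ledger
        deleted = [
            g for g in truth.genes
            if op.start <= g.interval.start and g.interval.end <= op.end
        ]
        lifted_ids = {g.gene_id for g in ref.genes}
        assert deleted and all(g.gene_id not in lifted_ids for g in deleted)


def test_config_yaml_roundtrip(tmp_path):
    cfg = small_config()
    p = tmp_path / "sim.yaml"
    cfg.to_yaml(p)
    back = sd.SimConfig.from_yaml(p)
    assert back == cfg
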