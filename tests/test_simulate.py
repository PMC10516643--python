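"""Simulator: determinism, fusion/backsplice geometry, read sampling, aligner emulation."""

from __future__ import annotations

import itertools
from dataclasses import replace

import numpy as np
import pysam
import pytest

from fcircseeker import formats, simulate
from fcircseeker.model import GenomicInterval
from fcircseeker.simulate import (
    SimConfig,
    add_backsplices,
    build_synthetic_genome,
    circle_source_map,
    emit_aligner_emulation_sam,
    linear_source_map,
    make_fusion_set,
    simulate_reads,
)

from conftest import clean_config, plus_gene


SMALL = dict(n_chromosomes=2, chromosome_length=60_000, n_genes=10, n_fusions=2,
             fusion_class_mix={"inter": 1.0})


class TestGenome:
    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = SimConfig(**SMALL, seed=3)
        for run in ("a", "b"):
            genome, genes = build_synthetic_genome(cfg)
            formats.write_fasta(genome, tmp_path / f"{run}.fa")
            formats.write_gtf(genes, tmp_path / f"{run}.gtf")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
        assert (tmp_path / "a.gtf").read_bytes() == (tmp_path / "b.gtf").read_bytes()

    def test_zero_genes_warns(self, caplog):
        cfg = SimConfig(**{**SMALL, "n_genes": 0, "n_fusions": 1})
        with caplog.at_level("WARNING"):
            genome, genes = build_synthetic_genome(cfg)
        assert genes == [] and len(genome) == 2
        assert "n_genes=0" in caplog.text

    def test_capacity_exceeded_errors(self):
        cfg = SimConfig(n_chromosomes=1, chromosome_length=5000, n_genes=10, n_fusions=1)
        with pytest.raises(ValueError, match="budget"):
            build_synthetic_genome(cfg)

    def test_gene_layout_valid(self):
        genome, genes = build_synthetic_genome(SimConfig(seed=5))
        by_chrom: dict = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g.interval)
        for ivals in by_chrom.values():
            ivals.sort(key=lambda i: i.start)
            for a, b in zip(ivals, ivals[1:]):
                assert a.end <= b.start  # non-overlapping genes


class TestFusionSet:
    def test_inter_only_mix(self):
        cfg = SimConfig(**SMALL, seed=2)
        genome, genes = build_synthetic_genome(cfg)
        fusions = make_fusion_set(genes, cfg)
        assert len(fusions) == 2
        for fu in fusions:
            assert fu.gene5.chrom != fu.gene3.chrom

    def test_read_through_genomic_order(self):
        cfg = SimConfig(n_fusions=4, fusion_class_mix={"read_through": 1.0}, seed=4)
        genome, genes = build_synthetic_genome(cfg)
        fusions = make_fusion_set(genes, cfg)
        for fu in fusions:
            assert fu.class_label == "read_through"
            assert fu.gene5.chrom == fu.gene3.chrom
            assert fu.gene5.strand == fu.gene3.strand
            assert fu.gene5.interval.end < fu.gene3.interval.start

    def test_default_thirty_fusions_sixty_genes(self):
        cfg = SimConfig(seed=0)
        genome, genes = build_synthetic_genome(cfg)
        fusions = make_fusion_set(genes, cfg)
        assert len(fusions) == 30
        involved = {f.gene5.gene_id for f in fusions} | {f.gene3.gene_id for f in fusions}
        assert len(involved) == 60  # no gene reused

    def test_too_few_genes_errors(self):
        cfg = SimConfig(**SMALL)
        genome, genes = build_synthetic_genome(cfg)
        with pytest.raises(ValueError, match="genes"):
            make_fusion_set(genes[:3], cfg)


class TestBacksplices:
    @staticmethod
    def _two_by_two_fusion():
        g5 = plus_gene("A", "chr1", [(100, 200), (400, 500), (700, 800)])
        g3 = plus_gene("B", "chr2", [(100, 200), (400, 500), (700, 800)])
        return simulate.FusionDefinition(
            fusion_id="F1", gene5=g5, gene3=g3,
            exons5=g5.exons[:2], exons3=g3.exons[1:], class_label="inter",
        )

    def test_enumerated_circle_space(self):
        # Brute-force oracle: with 2 exons on each side, the possible
        # (acceptor exon, donor exon) pairs are exactly the 4 combinations.
        fu = self._two_by_two_fusion()
        expected = set()
        for acc_ex, don_ex in itertools.product(fu.exons5, fu.exons3):
            expected.add((acc_ex.start, don_ex.end - 1))
        observed = set()
        for seed in range(40):
            cfg = SimConfig(seed=seed)
            (rec,) = add_backsplices([fu], cfg)
            observed.add((rec.backsplice_acceptor.pos, rec.backsplice_donor.pos))
        assert observed == expected

    def test_truth_records_physically_possible_by_construction(self):
        cfg = SimConfig(seed=6)
        genome, genes = build_synthetic_genome(cfg)
        fusions = make_fusion_set(genes, cfg)
        truths = add_backsplices(fusions, cfg)
        by_id = {f.fusion_id: f for f in fusions}
        for t in truths:
            fu = by_id[t.fusion_id]
            g5, g3 = fu.gene5, fu.gene3
            assert g5.tkey(t.backsplice_acceptor.pos) <= g5.tkey(t.fusion_donor.pos)
            assert g3.tkey(t.backsplice_donor.pos) >= g3.tkey(t.fusion_acceptor.pos)
            assert t.same_chrom_same_strand == (
                g5.chrom == g3.chrom and g5.strand == g3.strand
            )

    def test_seed_determinism(self):
        fu = self._two_by_two_fusion()
        cfg = SimConfig(seed=11)
        assert add_backsplices([fu], cfg) == add_backsplices([fu], cfg)


class TestSimulateReads:
    def test_zero_coverage_empty_fastq(self):
        cfg = clean_config(seed=2, coverage=0.0, circle_junction_depth=0.0)
        genome, genes = build_synthetic_genome(cfg)
        fusions = make_fusion_set(genes, cfg)
        truths = add_backsplices(fusions, cfg)
        r1, r2, prov = simulate_reads(fusions, truths, genome, cfg)
        assert r1 == [] and r2 == [] and len(prov) == 0

    def test_zero_error_circle_fragments_match_doubled_sequence(self):
        cfg = clean_config(seed=3)
        genome, genes = build_synthetic_genome(cfg)
        fusions = make_fusion_set(genes, cfg)
        truths = add_backsplices(fusions, cfg)
        r1, r2, prov = simulate_reads(fusions, truths, genome, cfg)
        by_id = {f.fusion_id: f for f in fusions}
        truth_by = {t.fusion_id: t for t in truths}
        circ = prov[prov.source == "circle"]
        assert len(circ) > 0
        r1d, r2d = dict(r1), dict(r2)
        for row in circ.head(50).itertuples(index=False):
            fu = by_id[row.event]
            doubled = circle_source_map(fu, truth_by[row.event]).sequence(genome)
            assert r1d[row.read_id] == doubled[row.r1_start : row.r1_end]
            assert r2d[row.read_id] == simulate.revcomp(doubled[row.r2_start : row.r2_end])
            # every circle fragment crosses the backsplice wrap point
            L = circle_source_map(fu, truth_by[row.event]).length
            assert row.frag_start < L < row.frag_start + row.frag_len

    def test_expected_pair_count_matches_closed_form(self):
        # E[pairs] = coverage * L / (2 * read_length); average over 20 seeds.
        counts, expects = [], []
        for seed in range(20):
            cfg = clean_config(seed=seed, circle_junction_depth=0.0,
                               fusion_class_mix={"inter": 1.0})
            genome, genes = build_synthetic_genome(cfg)
            fusions = make_fusion_set(genes, cfg)
            truths = add_backsplices(fusions, cfg)
            _, _, prov = simulate_reads(fusions, truths, genome, cfg)
            for fu in fusions:
                L = linear_source_map(fu).length
                expects.append(cfg.coverage * L / (2 * cfg.read_length))
                counts.append((prov.event == fu.fusion_id).sum())
        ratio = np.sum(counts) / np.sum(expects)
        assert 0.95 < ratio < 1.05

    def test_coverage_calibration_within_15_percent(self):
        # Empirical per-base depth on linear transcripts vs configured coverage.
        depths = []
        for seed in range(20):
            cfg = clean_config(seed=seed, circle_junction_depth=0.0,
                               fusion_class_mix={"inter": 1.0})
            genome, genes = build_synthetic_genome(cfg)
            fusions = make_fusion_set(genes, cfg)
            truths = add_backsplices(fusions, cfg)
            _, _, prov = simulate_reads(fusions, truths, genome, cfg)
            fu = max(fusions, key=lambda f: linear_source_map(f).length)
            L = linear_source_map(fu).length
            sub = prov[prov.event == fu.fusion_id]
            covered = 2 * cfg.read_length * len(sub)
            depths.append(covered / L)
        mean_depth = float(np.mean(depths))
        assert abs(mean_depth - 50.0) / 50.0 < 0.15


def _tiny_world():
    """Two plus-strand genes with known sequences on one chromosome each."""
    rng = np.random.default_rng(99)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {
        "chr1": bases[rng.integers(0, 4, 3000)].tobytes().decode(),
        "chr2": bases[rng.integers(0, 4, 3000)].tobytes().decode(),
    }
    gA = plus_gene("A", "chr1", [(100, 300), (800, 1000)])
    gB = plus_gene("B", "chr2", [(200, 400), (900, 1100)])
    fu = simulate.FusionDefinition(
        fusion_id="F1", gene5=gA, gene3=gB,
        exons5=gA.exons, exons3=gB.exons, class_label="inter",
    )
    return genome, [gA, gB], fu


class TestAlignerEmulation:
    def _emit(self, tmp_path, prov_rows, reads1, reads2):
        import pandas as pd

        genome, genes, fu = _tiny_world()
        cfg = clean_config()
        truths = []
        prov = pd.DataFrame(prov_rows)
        sam = tmp_path / "t.sam"
        emit_aligner_emulation_sam(reads1, reads2, prov, [fu], truths, genome, cfg, sam)
        with pysam.AlignmentFile(str(sam), "r") as fh:
            return list(fh.fetch(until_eof=True))

    @staticmethod
    def _row(rid, r1, r2, **kw):
        base = dict(read_id=rid, event="F1", source="linear",
                    frag_start=r1[0], frag_len=r2[1] - r1[0],
                    r1_start=r1[0], r1_end=r1[1], r2_start=r2[0], r2_end=r2[1],
                    r1_spans_fusion=False, r2_spans_fusion=False,
                    r1_spans_backsplice=False, r2_spans_backsplice=False)
        base.update(kw)
        return base

    def test_read_inside_one_exon_all_match(self, tmp_path):
        genome, genes, fu = _tiny_world()
        seq = linear_source_map(fu).sequence(genome)
        reads1 = [("p1", seq[10:110])]
        reads2 = [("p1", simulate.revcomp(seq[150:250]))]
        recs = self._emit(tmp_path, [self._row("p1", (10, 110), (150, 250))], reads1, reads2)
        r1 = next(r for r in recs if r.is_read1)
        assert r1.cigarstring == "100M"
        assert r1.reference_name == "chr1" and r1.reference_start == 110
        assert genome["chr1"][r1.reference_start : r1.reference_start + 100] == r1.query_sequence

    def test_splice_gap_n_cigar(self, tmp_path):
        genome, genes, fu = _tiny_world()
        seq = linear_source_map(fu).sequence(genome)
        # read covering transcript offsets 150..250 crosses exon1|exon2 of A at 200
        reads1 = [("p1", seq[150:250])]
        reads2 = [("p1", simulate.revcomp(seq[250:350]))]
        recs = self._emit(tmp_path, [self._row("p1", (150, 250), (250, 350))], reads1, reads2)
        r1 = next(r for r in recs if r.is_read1)
        assert r1.cigarstring == "50M500N50M"

    def test_majority_rule_soft_clip(self, tmp_path):
        genome, genes, fu = _tiny_world()
        seq = linear_source_map(fu).sequence(genome)
        # fusion junction at transcript offset 400: read 340..440 = 60 in A | 40 in B
        reads1 = [("p1", seq[340:440])]
        reads2 = [("p1", simulate.revcomp(seq[500:600]))]
        row = self._row("p1", (340, 440), (500, 600), r1_spans_fusion=True)
        recs = self._emit(tmp_path, [row], reads1, reads2)
        r1 = next(r for r in recs if r.is_read1)
        assert r1.reference_name == "chr1"
        assert r1.cigarstring == "60M40S"

    def test_cross_gene_pair_is_discordant(self, tmp_path):
        genome, genes, fu = _tiny_world()
        seq = linear_source_map(fu).sequence(genome)
        reads1 = [("p1", seq[200:300])]
        reads2 = [("p1", simulate.revcomp(seq[450:550]))]
        sam_recs = self._emit(tmp_path, [self._row("p1", (200, 300), (450, 550))], reads1, reads2)
        assert {r.reference_name for r in sam_recs} == {"chr1", "chr2"}
        sam = tmp_path / "t.sam"
        (pair,) = formats.read_alignments(sam)
        assert pair.is_discordant


def test_truth_table_round_trip(tmp_path, clean_ds):
    from fcircseeker.simulate import read_truth_table, write_truth_table

    p = tmp_path / "truth.tsv"
    write_truth_table(clean_ds.truths, p)
    assert read_truth_table(p) == clean_ds.truths


def test_full_sam_is_consistent_with_reference(clean_ds):
    """Every mapped base of the emulated SAM matches the genome (zero-error run)."""
    n = 0
    with pysam.AlignmentFile(str(clean_ds.sam_path), "r") as fh:
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped or n > 300:
                continue
            ref = clean_ds.genome[rec.reference_name]
            for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
                assert rec.query_sequence[qpos] == ref[rpos]
            n += 1
    assert n > 100
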