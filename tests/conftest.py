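"""Shared fixtures: a small clean simulated dataset and object factories."""

from __future__ import annotations

import itertools

import pytest

from fcircseeker.classify import FilterConfig
from fcircseeker.detect import DetectParams
from fcircseeker.model import (
    Breakpoint,
    GeneModel,
    GenomicInterval,
    JunctionCluster,
    SplitAlignment,
    SplitSegment,
)
from fcircseeker.pipeline import run_detection, simulate_dataset
from fcircseeker.simulate import SimConfig

_counter = itertools.count()


def clean_config(seed: int = 1, **kw) -> SimConfig:
    """Noise-free simulator configuration: fixed coverage, zero error rate."""
    defaults = dict(
        n_genes=20,
        n_fusions=5,
        substitution_error_rate=0.0,
        linear_coverage_sigma=0.0,
        circle_depth_sigma=0.0,
        coverage=50.0,
        circle_junction_depth=25.0,
        seed=seed,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def clean_ds(tmp_path_factory):
    """One clean 5-fusion dataset shared across the suite."""
    return simulate_dataset(clean_config(seed=1), tmp_path_factory.mktemp("clean_ds"))


@pytest.fixture(scope="session")
def clean_result(clean_ds):
    return run_detection(clean_ds.sam_path, clean_ds.genes, clean_ds.genome)


def make_split(donor: Breakpoint, acceptor: Breakpoint, gene5: str, gene3: str,
               read_id: str | None = None) -> SplitAlignment:
    rid = read_id or f"r{next(_counter)}"
    return SplitAlignment(
        read_id=rid,
        segment5=SplitSegment(gene5, GenomicInterval(donor.chrom, max(0, donor.pos - 49), donor.pos + 1, donor.strand), 0, 50),
        segment3=SplitSegment(gene3, GenomicInterval(acceptor.chrom, acceptor.pos, acceptor.pos + 50, acceptor.strand), 50, 100),
        donor=donor,
        acceptor=acceptor,
        junction_offset_in_read=50,
    )


def make_cluster(donor: Breakpoint, acceptor: Breakpoint, gene5: str = "A", gene3: str = "B",
                 support: int = 1, wgs: int = 0, canonical: bool = True) -> JunctionCluster:
    members = [make_split(donor, acceptor, gene5, gene3) for _ in range(support)]
    return JunctionCluster(
        donor=donor,
        acceptor=acceptor,
        donor_gene=gene5,
        acceptor_gene=gene3,
        members=members,
        canonical_donor=canonical,
        canonical_acceptor=canonical,
        wgs_support=wgs,
    )


def plus_gene(gene_id: str, chrom: str, exon_spans: list[tuple[int, int]], strand: str = "+") -> GeneModel:
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_spans]
    if strand == "-":
        exons = exons[::-1]
    return GeneModel(
        gene_id=gene_id,
        gene_name=gene_id,
        interval=GenomicInterval(chrom, min(s for s, _ in exon_spans), max(e for _, e in exon_spans), strand),
        exons=exons,
    )
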