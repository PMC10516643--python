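"""Synthetic genomes, fusion transcripts, backsplices, reads and alignments.

The simulator states a small but complete world: random multi-exon genes on
both strands of several chromosomes, a configurable mix of inter-chromosomal,
intra-chromosomal and read-through fusion transcripts, one or more randomly
placed backsplices per fusion, paired-end reads drawn from the linear fusion
transcript and from a linearized (doubled) circle sequence, and an emulated
spliced aligner that produces a SAM file so the whole detection pipeline can
run hermetically.

Expression noise model: each event's linear transcript coverage and its
circle junction depth are drawn log-normally around their configured means,
so that lowly expressed circles occasionally drop below the novel-junction
read threshold, and occasionally a circle outnumbers its parent transcript
(which can mislead primary-junction designation downstream).  Both regimes
are observed in real total-RNA libraries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .model import (
    Breakpoint,
    GeneModel,
    GenomicInterval,
    SimTruthRecord,
    revcomp,
)

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

CLASS_INTER = "inter"
CLASS_INTRA = "intra"
CLASS_READ_THROUGH = "read_through"
FUSION_CLASSES = (CLASS_INTER, CLASS_INTRA, CLASS_READ_THROUGH)


@dataclass
class SimConfig:
    """Parameters of the simulated world.

    Coverage units: ``coverage`` is mean per-base depth over the linear
    fusion transcript; ``circle_junction_depth`` is the mean number of
    circle-derived fragments crossing the backsplice junction point.
    """

    n_chromosomes: int = 4
    chromosome_length: int = 300_000
    n_genes: int = 70
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_length: tuple[int, int] = (120, 220)
    intron_length: tuple[int, int] = (300, 800)
    intergenic_gap: tuple[int, int] = (500, 2000)
    n_fusions: int = 30
    fusion_class_mix: dict[str, float] = field(
        default_factory=lambda: {CLASS_INTER: 0.5, CLASS_INTRA: 0.3, CLASS_READ_THROUGH: 0.2}
    )
    backsplices_per_fusion: int = 1
    read_length: int = 100
    fragment_mean: float = 250.0
    fragment_sd: float = 25.0
    coverage: float = 50.0
    linear_coverage_sigma: float = 0.5
    circle_junction_depth: float = 16.0
    circle_depth_sigma: float = 0.9
    substitution_error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chromosome_length", "n_fusions",
                     "backsplices_per_fusion", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        total = sum(self.fusion_class_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("fusion_class_mix proportions must sum to 1")
        for cls in self.fusion_class_mix:
            if cls not in FUSION_CLASSES:
                raise ValueError(f"unknown fusion class {cls!r}")
        if self.read_length >= self.fragment_mean:
            raise ValueError("read_length must be smaller than fragment_mean")

    def rng(self, salt: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, salt])


@dataclass
class FusionDefinition:
    """A linear fusion transcript: exon prefix of gene5 + exon suffix of gene3."""

    fusion_id: str
    gene5: GeneModel
    gene3: GeneModel
    exons5: list[GenomicInterval]  # transcription order, prefix of gene5
    exons3: list[GenomicInterval]  # transcription order, suffix of gene3
    class_label: str

    @property
    def fusion_donor(self) -> Breakpoint:
        ex = self.exons5[-1]
        pos = ex.end - 1 if ex.strand == "+" else ex.start
        return Breakpoint(ex.chrom, pos, ex.strand)

    @property
    def fusion_acceptor(self) -> Breakpoint:
        ex = self.exons3[0]
        pos = ex.start if ex.strand == "+" else ex.end - 1
        return Breakpoint(ex.chrom, pos, ex.strand)


# ---------------------------------------------------------------------------
# Genome + annotation
# ---------------------------------------------------------------------------

def build_synthetic_genome(config: SimConfig) -> tuple[dict[str, str], list[GeneModel]]:
    """Generate a random genome and a non-overlapping multi-exon gene layout.

    Deterministic for a fixed ``config.seed``.  Raises if the requested gene
    count cannot be placed within the chromosome budget.
    """
    rng = config.rng(1)
    genome: dict[str, str] = {}
    for i in range(config.n_chromosomes):
        idx = rng.integers(0, 4, size=config.chromosome_length)
        genome[f"chr{i + 1}"] = _BASES[idx].tobytes().decode()

    genes: list[GeneModel] = []
    if config.n_genes == 0:
        log.warning("n_genes=0: returning genome with empty gene set")
        return genome, genes

    # Round-robin placement over chromosomes keeps inter-chromosomal gene
    # pairs available even for small gene counts.
    chroms = list(genome)
    cursors = {c: int(rng.integers(*config.intergenic_gap)) for c in chroms}
    full: set[str] = set()
    for gi in range(config.n_genes):
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        ex_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, size=n_ex)
        in_lens = rng.integers(config.intron_length[0], config.intron_length[1] + 1, size=n_ex - 1)
        span = int(ex_lens.sum() + in_lens.sum())
        chrom = None
        for probe in range(len(chroms)):
            cand = chroms[(gi + probe) % len(chroms)]
            if cand in full:
                continue
            if cursors[cand] + span <= config.chromosome_length:
                chrom = cand
                break
            full.add(cand)
        if chrom is None:
            raise ValueError(
                f"cannot place gene {gi + 1}/{config.n_genes}: exceeded "
                f"{config.n_chromosomes} x {config.chromosome_length} bp chromosome budget"
            )
        cursor = cursors[chrom]
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = cursor
        for k in range(n_ex):
            exons.append(GenomicInterval(chrom, pos, pos + int(ex_lens[k]), strand))
            pos += int(ex_lens[k])
            if k < n_ex - 1:
                pos += int(in_lens[k])
        if strand == "-":
            exons = exons[::-1]
        gid = f"G{gi + 1:03d}"
        genes.append(
            GeneModel(
                gene_id=gid,
                gene_name=gid,
                interval=GenomicInterval(chrom, cursor, cursor + span, strand),
                exons=exons,
            )
        )
        cursors[chrom] = cursor + span + int(rng.integers(*config.intergenic_gap))
    genes.sort(key=lambda g: (g.chrom, g.interval.start))
    return genome, genes


# ---------------------------------------------------------------------------
# Fusion + backsplice truth
# ---------------------------------------------------------------------------

def _class_counts(mix: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n fusions over the class mix."""
    raw = {c: mix.get(c, 0.0) * n for c in FUSION_CLASSES}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    rem = n - sum(counts.values())
    for c in sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)[:rem]:
        counts[c] += 1
    return counts


def make_fusion_set(genes: Sequence[GeneModel], config: SimConfig) -> list[FusionDefinition]:
    """Draw ``n_fusions`` fusion transcript definitions matching the class mix.

    Each fusion joins a 5' exon prefix of one gene to a 3' exon suffix of
    another at canonical exon boundaries; no gene is reused.  Read-through
    fusions join adjacent plus-strand genes in genomic (= transcription)
    order.
    """
    if len(genes) < 2 * config.n_fusions:
        raise ValueError(
            f"need >= {2 * config.n_fusions} genes for {config.n_fusions} fusions, have {len(genes)}"
        )
    rng = config.rng(2)
    counts = _class_counts(config.fusion_class_mix, config.n_fusions)
    used: set[str] = set()
    fusions: list[FusionDefinition] = []

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in sorted(genes, key=lambda g: (g.chrom, g.interval.start)):
        by_chrom.setdefault(g.chrom, []).append(g)

    def take_pair(g5: GeneModel, g3: GeneModel, label: str) -> None:
        k5 = int(rng.integers(1, len(g5.exons))) if len(g5.exons) > 1 else 1
        j3 = int(rng.integers(1, len(g3.exons))) if len(g3.exons) > 1 else 0
        fusions.append(
            FusionDefinition(
                fusion_id=f"F{len(fusions) + 1:03d}",
                gene5=g5,
                gene3=g3,
                exons5=list(g5.exons[:k5]),
                exons3=list(g3.exons[j3:]),
                class_label=label,
            )
        )
        used.add(g5.gene_id)
        used.add(g3.gene_id)

    # read-through: adjacent plus-strand gene pairs, genomic order
    rt_pairs = []
    for chrom_genes in by_chrom.values():
        for a, b in zip(chrom_genes, chrom_genes[1:]):
            if a.strand == b.strand == "+":
                rt_pairs.append((a, b))
    rng.shuffle(rt_pairs)
    n_rt = 0
    for a, b in rt_pairs:
        if n_rt == counts[CLASS_READ_THROUGH]:
            break
        if a.gene_id in used or b.gene_id in used:
            continue
        take_pair(a, b, CLASS_READ_THROUGH)
        n_rt += 1
    if n_rt < counts[CLASS_READ_THROUGH]:
        raise ValueError(
            f"read-through quota unsatisfiable: wanted {counts[CLASS_READ_THROUGH]}, "
            f"found {n_rt} disjoint adjacent plus-strand gene pairs"
        )

    def draw(label: str, predicate) -> None:
        free = [g for g in genes if g.gene_id not in used]
        order = list(rng.permutation(len(free)))
        for ii in order:
            g5 = free[ii]
            if g5.gene_id in used:
                continue
            partners = [g for g in free if g.gene_id not in used and g.gene_id != g5.gene_id and predicate(g5, g)]
            if not partners:
                continue
            g3 = partners[int(rng.integers(len(partners)))]
            take_pair(g5, g3, label)
            return
        raise ValueError(f"{label} fusion quota unsatisfiable with this annotation")

    for _ in range(counts[CLASS_INTER]):
        draw(CLASS_INTER, lambda a, b: a.chrom != b.chrom)
    for _ in range(counts[CLASS_INTRA]):
        draw(
            CLASS_INTRA,
            lambda a, b: a.chrom == b.chrom
            and (b.interval.start - a.interval.end > 5000 or a.interval.start - b.interval.end > 5000),
        )
    return fusions


def add_backsplices(fusions: Sequence[FusionDefinition], config: SimConfig) -> list[SimTruthRecord]:
    """Draw backsplice junctions for each fusion, uniform over exon pairs.

    The backsplice acceptor is the start of an exon in the gene5 portion and
    the donor the end of an exon in the gene3 portion, so every circle spans
    the fusion junction and is physically possible by construction.
    """
    rng = config.rng(3)
    truths: list[SimTruthRecord] = []
    for fu in fusions:
        if len(fu.exons5) + len(fu.exons3) < 2:
            log.warning("fusion %s has a single total exon; skipped", fu.fusion_id)
            continue
        for bi in range(config.backsplices_per_fusion):
            a = int(rng.integers(len(fu.exons5)))
            d = int(rng.integers(len(fu.exons3)))
            acc_ex = fu.exons5[a]
            don_ex = fu.exons3[d]
            acceptor = Breakpoint(
                acc_ex.chrom,
                acc_ex.start if acc_ex.strand == "+" else acc_ex.end - 1,
                acc_ex.strand,
            )
            donor = Breakpoint(
                don_ex.chrom,
                don_ex.end - 1 if don_ex.strand == "+" else don_ex.start,
                don_ex.strand,
            )
            truths.append(
                SimTruthRecord(
                    fusion_id=fu.fusion_id if config.backsplices_per_fusion == 1
                    else f"{fu.fusion_id}.b{bi + 1}",
                    gene5=fu.gene5.gene_id,
                    gene3=fu.gene3.gene_id,
                    fusion_donor=fu.fusion_donor,
                    fusion_acceptor=fu.fusion_acceptor,
                    backsplice_donor=donor,
                    backsplice_acceptor=acceptor,
                    exons_in_circle=list(fu.exons5[a:]) + list(fu.exons3[: d + 1]),
                    same_chrom_same_strand=(
                        fu.gene5.chrom == fu.gene3.chrom and fu.gene5.strand == fu.gene3.strand
                    ),
                )
            )
    return truths


# ---------------------------------------------------------------------------
# Transcript source maps
# ---------------------------------------------------------------------------

@dataclass
class SourceMap:
    """Exon chain of one read source with junction annotations.

    ``segments`` is a list of (exon, t_start, boundary_after) where
    boundary_after labels the junction following the exon: 'splice',
    'fusion', 'backsplice' or None (end of a linear source).  Circle
    sources are stored doubled (two copies of the exon chain) so fragment
    coordinates crossing the wrap point stay linear.
    """

    name: str
    segments: list[tuple[GenomicInterval, int, Optional[str]]]
    length: int  # length of ONE copy (circle) or the whole transcript (linear)
    circular: bool
    fusion_offsets: tuple[int, ...]  # t-offsets of the first base after the fusion junction
    backsplice_offset: Optional[int]  # t-offset of first base after the backsplice (circles)

    def sequence(self, genome: dict[str, str]) -> str:
        parts = []
        for ex, _, _ in self.segments:
            s = genome[ex.chrom][ex.start : ex.end]
            parts.append(s if ex.strand == "+" else revcomp(s))
        return "".join(parts)


def exon_chain_seq(exons: Sequence[GenomicInterval], genome: dict[str, str]) -> str:
    parts = []
    for ex in exons:
        s = genome[ex.chrom][ex.start : ex.end]
        parts.append(s if ex.strand == "+" else revcomp(s))
    return "".join(parts)


def linear_source_map(fu: FusionDefinition) -> SourceMap:
    segments = []
    t = 0
    all_ex = list(fu.exons5) + list(fu.exons3)
    n5 = len(fu.exons5)
    fus_off = sum(len(e) for e in fu.exons5)
    for i, ex in enumerate(all_ex):
        if i == n5 - 1:
            boundary = "fusion"
        elif i == len(all_ex) - 1:
            boundary = None
        else:
            boundary = "splice"
        segments.append((ex, t, boundary))
        t += len(ex)
    return SourceMap(
        name=f"{fu.fusion_id}:linear",
        segments=segments,
        length=t,
        circular=False,
        fusion_offsets=(fus_off,),
        backsplice_offset=None,
    )


def circle_source_map(fu: FusionDefinition, truth: SimTruthRecord) -> SourceMap:
    exons = truth.exons_in_circle
    n5 = sum(1 for ex in exons if ex.strand == fu.gene5.strand and ex.chrom == fu.gene5.chrom
             and fu.gene5.interval.start <= ex.start and ex.end <= fu.gene5.interval.end)
    length = sum(len(e) for e in exons)
    fus_off = sum(len(e) for e in exons[:n5])
    segments = []
    t = 0
    for copy in range(2):
        for i, ex in enumerate(exons):
            if i == n5 - 1:
                boundary = "fusion"
            elif i == len(exons) - 1:
                boundary = "backsplice" if copy == 0 else None
            else:
                boundary = "splice"
            segments.append((ex, t, boundary))
            t += len(ex)
    return SourceMap(
        name=f"{fu.fusion_id}:circle",
        segments=segments,
        length=length,
        circular=True,
        fusion_offsets=(fus_off, fus_off + length),
        backsplice_offset=length,
    )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    pos = rng.choice(len(seq), size=n_err, replace=False)
    for p in pos:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


def _crosses(a: int, b: int, junction: int) -> bool:
    """Does read interval [a, b) cross the junction located before offset ``junction``?"""
    return a < junction < b


def simulate_reads(
    fusions: Sequence[FusionDefinition],
    truths: Sequence[SimTruthRecord],
    genome: dict[str, str],
    config: SimConfig,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], pd.DataFrame]:
    """Simulate paired-end reads from linear fusion transcripts and circles.

    Returns (R1 reads, R2 reads, provenance table).  R1 is the fragment's
    transcript-sense prefix; R2 the reverse complement of its suffix.
    Circle fragments are drawn only across the backsplice junction of the
    doubled circle sequence.
    """
    rng = config.rng(4)
    truth_by_id = {t.fusion_id: t for t in truths}
    reads1: list[tuple[str, str]] = []
    reads2: list[tuple[str, str]] = []
    prov_rows = []
    rl = config.read_length

    def emit(source: SourceMap, seq: str, n_frags: int, junction_anchor: Optional[int]) -> None:
        L_avail = len(seq)
        for _ in range(n_frags):
            F = int(np.clip(rng.normal(config.fragment_mean, config.fragment_sd),
                            rl + 5, max(rl + 5, source.length)))
            if F > L_avail:
                continue
            if junction_anchor is None:
                s = int(rng.integers(0, L_avail - F + 1))
            else:
                lo = max(0, junction_anchor - F + 1)
                hi = junction_anchor - 1
                if hi < lo:
                    continue
                s = int(rng.integers(lo, hi + 1))
            frag = seq[s : s + F]
            r1 = _apply_errors(frag[:rl], config.substitution_error_rate, rng)
            r2 = _apply_errors(revcomp(frag[F - rl :]), config.substitution_error_rate, rng)
            rid = f"{source.name}:{len(prov_rows)}"
            a1, b1 = s, s + rl
            a2, b2 = s + F - rl, s + F
            row = dict(
                read_id=rid,
                event=source.name.split(":")[0],
                source="circle" if source.circular else "linear",
                frag_start=s,
                frag_len=F,
                r1_start=a1, r1_end=b1, r2_start=a2, r2_end=b2,
                r1_spans_fusion=any(_crosses(a1, b1, j) for j in source.fusion_offsets),
                r2_spans_fusion=any(_crosses(a2, b2, j) for j in source.fusion_offsets),
                r1_spans_backsplice=bool(source.backsplice_offset and _crosses(a1, b1, source.backsplice_offset)),
                r2_spans_backsplice=bool(source.backsplice_offset and _crosses(a2, b2, source.backsplice_offset)),
            )
            prov_rows.append(row)
            reads1.append((rid, r1))
            reads2.append((rid, r2))

    for fu in fusions:
        lin = linear_source_map(fu)
        lin_seq = lin.sequence(genome)
        mult = rng.lognormal(-config.linear_coverage_sigma**2 / 2, config.linear_coverage_sigma) \
            if config.linear_coverage_sigma > 0 else 1.0
        cov = config.coverage * mult
        if lin.length < rl + 10:
            log.warning("fragments longer than linear transcript %s; source skipped", fu.fusion_id)
        else:
            n_lin = rng.poisson(cov * lin.length / (2 * rl)) if cov > 0 else 0
            emit(lin, lin_seq, n_lin, None)

        for truth in truths:
            if truth.fusion_id.split(".")[0] != fu.fusion_id:
                continue
            circ = circle_source_map(fu, truth)
            if circ.length < rl + 10:
                log.warning("fragments longer than circle of %s; source skipped", truth.fusion_id)
                continue
            circ_seq = circ.sequence(genome)
            cmult = rng.lognormal(-config.circle_depth_sigma**2 / 2, config.circle_depth_sigma) \
                if config.circle_depth_sigma > 0 else 1.0
            n_circ = rng.poisson(config.circle_junction_depth * cmult) \
                if config.circle_junction_depth > 0 else 0
            emit(circ, circ_seq, n_circ, circ.backsplice_offset)

    prov = pd.DataFrame(
        prov_rows,
        columns=["read_id", "event", "source", "frag_start", "frag_len",
                 "r1_start", "r1_end", "r2_start", "r2_end",
                 "r1_spans_fusion", "r2_spans_fusion",
                 "r1_spans_backsplice", "r2_spans_backsplice"],
    )
    return reads1, reads2, prov


# ---------------------------------------------------------------------------
# Aligner emulation
# ---------------------------------------------------------------------------

def _pieces_for_interval(source: SourceMap, a: int, b: int):
    """Genomic pieces covered by source interval [a, b), with block splits.

    Returns a list of blocks; each block is a list of
    (chrom, gstart, gend, strand, sense_start) pieces joined by ordinary
    splice junctions.  Blocks are separated by fusion/backsplice junctions.
    """
    blocks: list[list[tuple[str, int, int, str, int]]] = [[]]
    for ex, t0, boundary in source.segments:
        t1 = t0 + len(ex)
        if t1 <= a or t0 >= b:
            continue
        p, q = max(a, t0), min(b, t1)
        o1, o2 = p - t0, q - t0
        if ex.strand == "+":
            piece = (ex.chrom, ex.start + o1, ex.start + o2, "+", p)
        else:
            piece = (ex.chrom, ex.end - o2, ex.end - o1, "-", p)
        blocks[-1].append(piece)
        if q == t1 and t1 < b and boundary in ("fusion", "backsplice"):
            blocks.append([])
    return [bl for bl in blocks if bl]


def _aligned_segment(
    header: pysam.AlignmentHeader,
    rid: str,
    mate: int,
    seq_sequenced: str,
    source: SourceMap,
    a: int,
    b: int,
    seed_min: int,
) -> pysam.AlignedSegment:
    rec = pysam.AlignedSegment(header)
    rec.query_name = rid
    rec.is_paired = True
    rec.is_read1 = mate == 1
    rec.is_read2 = mate == 2
    blocks = _pieces_for_interval(source, a, b)
    best = max(blocks, key=lambda bl: sum(g1 - g0 for _, g0, g1, _, _ in bl))
    blen = sum(g1 - g0 for _, g0, g1, _, _ in best)
    if blen < seed_min:
        rec.is_unmapped = True
        rec.query_sequence = seq_sequenced
        rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq_sequenced))
        return rec
    strand = best[0][3]
    chrom = best[0][0]
    sense_lo = min(p[4] for p in best)
    pre = sense_lo - a
    post = (b - a) - pre - blen
    rec.is_reverse = (mate == 2) != (strand == "-")
    rec.query_sequence = revcomp(seq_sequenced) if rec.is_reverse else seq_sequenced
    rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq_sequenced))
    pieces = sorted(best, key=lambda p: p[1])
    cig: list[tuple[int, int]] = []
    left_clip, right_clip = (pre, post) if strand == "+" else (post, pre)
    if left_clip:
        cig.append((4, left_clip))
    prev_end = None
    for _, g0, g1, _, _ in pieces:
        if prev_end is not None and g0 > prev_end:
            cig.append((3, g0 - prev_end))
        cig.append((0, g1 - g0))
        prev_end = g1
    if right_clip:
        cig.append((4, right_clip))
    rec.reference_name = chrom
    rec.reference_start = pieces[0][1]
    rec.cigartuples = cig
    return rec


def emit_aligner_emulation_sam(
    reads1: Sequence[tuple[str, str]],
    reads2: Sequence[tuple[str, str]],
    provenance: pd.DataFrame,
    fusions: Sequence[FusionDefinition],
    truths: Sequence[SimTruthRecord],
    genome: dict[str, str],
    config: SimConfig,
    path: str | Path,
    seed_min: int = 20,
) -> None:
    """Write a SAM file emulating a spliced linear aligner.

    Reads inside one gene map with match/N-gap CIGARs; reads crossing a
    fusion or backsplice junction map to the side holding the majority of
    their bases with the remainder soft-clipped (unmapped if no side holds
    at least ``seed_min`` bases).  Cross-gene fragments become discordant
    pairs.
    """
    maps: dict[tuple[str, str], SourceMap] = {}
    truth_by_id = {t.fusion_id.split(".")[0]: t for t in truths}
    for fu in fusions:
        maps[(fu.fusion_id, "linear")] = linear_source_map(fu)
        for t in truths:
            if t.fusion_id.split(".")[0] == fu.fusion_id:
                maps[(fu.fusion_id, "circle")] = circle_source_map(fu, t)

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": len(genome[c])} for c in genome],
        }
    )
    r1_by_id = dict(reads1)
    r2_by_id = dict(reads2)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in provenance.itertuples(index=False):
            source = maps[(row.event, row.source)]
            rec1 = _aligned_segment(header, row.read_id, 1, r1_by_id[row.read_id],
                                    source, row.r1_start, row.r1_end, seed_min)
            rec2 = _aligned_segment(header, row.read_id, 2, r2_by_id[row.read_id],
                                    source, row.r2_start, row.r2_end, seed_min)
            for rec, other in ((rec1, rec2), (rec2, rec1)):
                if other.is_unmapped:
                    rec.mate_is_unmapped = True
                    if not rec.is_unmapped:
                        other.reference_name = rec.reference_name
                        other.reference_start = rec.reference_start
                else:
                    rec.mate_is_unmapped = False
                    rec.next_reference_name = other.reference_name
                    rec.next_reference_start = other.reference_start
                    rec.mate_is_reverse = other.is_reverse
            if not rec1.is_unmapped and not rec2.is_unmapped:
                rec1.next_reference_name = rec2.reference_name
                rec1.next_reference_start = rec2.reference_start
                rec2.next_reference_name = rec1.reference_name
                rec2.next_reference_start = rec1.reference_start
                if rec1.reference_name == rec2.reference_name:
                    lo = min(rec1.reference_start, rec2.reference_start)
                    hi = max(rec1.reference_end, rec2.reference_end)
                    tlen = hi - lo
                    rec1.template_length = tlen if rec1.reference_start <= rec2.reference_start else -tlen
                    rec2.template_length = -rec1.template_length
                    if rec1.is_reverse != rec2.is_reverse and tlen <= 2 * config.fragment_mean:
                        rec1.is_proper_pair = True
                        rec2.is_proper_pair = True
            if rec1.is_unmapped and rec2.is_unmapped:
                continue  # fully unmappable pair: dropped, as a real aligner filter would
            out.write(rec1)
            out.write(rec2)


# ---------------------------------------------------------------------------
# Truth table I/O + WGS helper
# ---------------------------------------------------------------------------

_TRUTH_COLS = [
    "fusion_id", "gene5", "gene3",
    "fd_chrom", "fd_pos", "fd_strand", "fa_chrom", "fa_pos", "fa_strand",
    "bd_chrom", "bd_pos", "bd_strand", "ba_chrom", "ba_pos", "ba_strand",
    "same_chrom_same_strand", "circle_exons",
]


def write_truth_table(truths: Sequence[SimTruthRecord], path: str | Path) -> None:
    rows = []
    for t in truths:
        rows.append([
            t.fusion_id, t.gene5, t.gene3,
            *t.fusion_donor, *t.fusion_acceptor, *t.backsplice_donor, *t.backsplice_acceptor,
            int(t.same_chrom_same_strand),
            ";".join(f"{e.chrom}:{e.start}-{e.end}:{e.strand}" for e in t.exons_in_circle),
        ])
    pd.DataFrame(rows, columns=_TRUTH_COLS).to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> list[SimTruthRecord]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples(index=False):
        exons = []
        if isinstance(r.circle_exons, str) and r.circle_exons:
            for tok in r.circle_exons.split(";"):
                loc, strand = tok.rsplit(":", 1)
                chrom, rng_ = loc.split(":")
                s, e = rng_.split("-")
                exons.append(GenomicInterval(chrom, int(s), int(e), strand))
        out.append(SimTruthRecord(
            fusion_id=str(r.fusion_id), gene5=str(r.gene5), gene3=str(r.gene3),
            fusion_donor=Breakpoint(r.fd_chrom, int(r.fd_pos), r.fd_strand),
            fusion_acceptor=Breakpoint(r.fa_chrom, int(r.fa_pos), r.fa_strand),
            backsplice_donor=Breakpoint(r.bd_chrom, int(r.bd_pos), r.bd_strand),
            backsplice_acceptor=Breakpoint(r.ba_chrom, int(r.ba_pos), r.ba_strand),
            exons_in_circle=exons,
            same_chrom_same_strand=bool(r.same_chrom_same_strand),
        ))
    return out


def simulate_wgs_pairs(
    truth: SimTruthRecord,
    genome: dict[str, str],
    path: str | Path,
    n_pairs: int = 10,
    read_length: int = 100,
    max_offset: int = 500,
    seed: int = 0,
) -> None:
    """Write a small WGS SAM with discordant pairs flanking a genomic fusion breakpoint.

    Mate 1 sits on the gene5-body side of the fusion donor, mate 2 on the
    gene3-body side of the acceptor, both oriented toward the junction --
    the geometry expected of genomic fragments crossing a rearrangement.
    """
    rng = np.random.default_rng(seed)
    d, a = truth.fusion_donor, truth.fusion_acceptor
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": c, "LN": len(genome[c])} for c in genome]}
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i in range(n_pairs):
            off1 = int(rng.integers(10, max_offset - read_length))
            off2 = int(rng.integers(10, max_offset - read_length))
            if d.strand == "+":
                s1 = d.pos - off1 - read_length + 1
                rev1 = False
            else:
                s1 = d.pos + off1
                rev1 = True
            if a.strand == "+":
                s2 = a.pos + off2
                rev2 = True
            else:
                s2 = a.pos - off2 - read_length + 1
                rev2 = False
            recs = []
            for mate, (chrom, s, rev) in enumerate(((d.chrom, s1, rev1), (a.chrom, s2, rev2)), 1):
                rec = pysam.AlignedSegment(header)
                rec.query_name = f"wgs{i}"
                rec.is_paired = True
                rec.is_read1 = mate == 1
                rec.is_read2 = mate == 2
                rec.reference_name = chrom
                rec.reference_start = max(0, s)
                rec.is_reverse = rev
                seq = genome[chrom][rec.reference_start : rec.reference_start + read_length]
                rec.query_sequence = seq
                rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                rec.cigartuples = [(0, len(seq))]
                recs.append(rec)
            recs[0].next_reference_name = recs[1].reference_name
            recs[0].next_reference_start = recs[1].reference_start
            recs[1].next_reference_name = recs[0].reference_name
            recs[1].next_reference_start = recs[0].reference_start
            recs[0].mate_is_reverse = recs[1].is_reverse
            recs[1].mate_is_reverse = recs[0].is_reverse
            out.write(recs[0])
            out.write(recs[1])
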