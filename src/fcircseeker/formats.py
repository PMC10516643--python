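"""Readers and writers for the standard formats used by the toolkit.

Owns every coordinate-convention conversion: GTF and VCF are 1-based
(closed / position-of-base respectively), everything internal and BED-like
is 0-based half-open.  The modified-BEDPE fcircRNA schema written here is
the interchange contract with the visualization module; its columns are
documented in the file header emitted by :func:`write_fcirc_bedpe`.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Iterator, Optional

import gffutils
import pandas as pd
import pysam
from pyfaidx import Fasta

from .model import (
    Breakpoint,
    Cytoband,
    FcircBedpeRecord,
    GeneModel,
    GenomicInterval,
    JunctionCluster,
    MateAlignment,
    ReadPairRecord,
)

log = logging.getLogger(__name__)

DEFAULT_MAX_INSERT = 1000


# ---------------------------------------------------------------------------
# GTF / FASTA
# ---------------------------------------------------------------------------

def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of possibly-overlapping intervals (0-based half-open)."""
    merged: list[list[int]] = []
    for s, e in sorted(ivals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Parse a GTF into per-gene exon-union :class:`GeneModel` objects.

    GTF coordinates (1-based closed) are converted to 0-based half-open.
    Exons of all transcripts of a gene are merged into a single union set
    and returned in transcription order.
    """
    path = str(path)
    # Pre-validate line shape so parse failures carry a line number.
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) < 9:
                raise ValueError(f"{path}: unparseable GTF line {lineno}")
    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except gffutils.exceptions.EmptyInputError:
        log.warning("no exon records found in %s", path)
        return []
    exons_by_gene: dict[str, list[gffutils.Feature]] = defaultdict(list)
    for feat in db.features_of_type("exon"):
        gid = feat.attributes.get("gene_id", [None])[0]
        if gid is None:
            raise ValueError(f"{path}: exon without gene_id at {feat.seqid}:{feat.start}")
        exons_by_gene[gid].append(feat)
    declared_genes = {
        f.attributes.get("gene_id", [f.id])[0]: f for f in db.features_of_type("gene")
    }
    for gid in set(declared_genes) - set(exons_by_gene):
        log.warning("gene %s has zero exons; skipped", gid)

    genes: list[GeneModel] = []
    for gid, feats in exons_by_gene.items():
        chrom = feats[0].seqid
        strand = feats[0].strand
        name = feats[0].attributes.get("gene_name", [gid])[0]
        merged = _merge_intervals([(f.start - 1, f.end) for f in feats])
        ivals = [GenomicInterval(chrom, s, e, strand) for s, e in merged]
        if strand == "-":
            ivals = ivals[::-1]
        hull = GenomicInterval(chrom, merged[0][0], merged[-1][1], strand)
        genes.append(GeneModel(gene_id=gid, gene_name=name, interval=hull, exons=ivals))
    if not genes:
        log.warning("no exon records found in %s", path)
    genes.sort(key=lambda g: (g.chrom, g.interval.start))
    return genes


def write_gtf(genes: Iterable[GeneModel], path: str | Path, source: str = "fcircseeker") -> None:
    """Write gene models as GTF (1-based closed coordinates), one transcript per gene."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}"; transcript_id "{g.gene_id}.t1";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.interval.start + 1}\t{g.interval.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for ex in sorted(g.exons, key=lambda e: e.start):
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


def load_genome(path: str | Path) -> dict[str, str]:
    """Load a FASTA reference into an in-memory chromosome->sequence dict."""
    fa = Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, qual_char: str = "I") -> None:
    """Write (read_id, sequence) pairs as FASTQ with a constant quality string."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual_char * len(seq)}\n")


# ---------------------------------------------------------------------------
# Ideogram
# ---------------------------------------------------------------------------

def read_ideogram(path: str | Path) -> dict[str, list[Cytoband]]:
    """Read a UCSC cytoBand.txt file into per-chromosome sorted band lists."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "gieStain"],
        dtype={"chrom": str, "name": str, "gieStain": str},
    )
    if df["gieStain"].isna().any() or df["name"].isna().any():
        raise ValueError(f"{path}: cytoBand file requires 5 columns (missing stain?)")
    bands: dict[str, list[Cytoband]] = defaultdict(list)
    for row in df.itertuples(index=False):
        bands[row.chrom].append(
            Cytoband(
                chrom=row.chrom,
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                band_name=row.name,
                stain=row.gieStain,
            )
        )
    for chrom, blist in bands.items():
        blist.sort(key=lambda b: b.interval.start)
        for a, b in zip(blist, blist[1:]):
            if a.interval.end > b.interval.start:
                raise ValueError(
                    f"{path}: overlapping cytobands {a.band_name}/{b.band_name} on {chrom}"
                )
    return dict(bands)


def lookup_cytoband(bands: dict[str, list[Cytoband]], chrom: str, pos: int) -> Optional[Cytoband]:
    for band in bands.get(chrom, ()):
        if band.interval.start <= pos < band.interval.end:
            return band
    return None


# ---------------------------------------------------------------------------
# SAM/BAM
# ---------------------------------------------------------------------------

def _mate_alignment(rec: pysam.AlignedSegment) -> MateAlignment:
    if rec.is_unmapped:
        return MateAlignment(mapped=False)
    cig = rec.cigartuples or []
    clip_left = cig[0][1] if cig and cig[0][0] in (4, 5) else 0
    clip_right = cig[-1][1] if cig and cig[-1][0] in (4, 5) else 0
    return MateAlignment(
        mapped=True,
        chrom=rec.reference_name,
        start=rec.reference_start,
        end=rec.reference_end,
        is_reverse=rec.is_reverse,
        clip_left=clip_left,
        clip_right=clip_right,
    )


def _sequenced(rec: pysam.AlignedSegment) -> str:
    seq = rec.query_sequence or ""
    if rec.is_reverse:
        from .model import revcomp

        return revcomp(seq)
    return seq


def _discordant(m1: MateAlignment, m2: MateAlignment, max_insert: int) -> bool:
    if not (m1.mapped and m2.mapped):
        return False
    if m1.chrom != m2.chrom:
        return True
    if m1.is_reverse == m2.is_reverse:
        return True
    span = max(m1.end, m2.end) - min(m1.start, m2.start)
    return span > max_insert


def read_alignments(
    path: str | Path,
    region: Optional[str] = None,
    max_insert: int = DEFAULT_MAX_INSERT,
) -> Iterator[ReadPairRecord]:
    """Stream mate-paired records from a SAM/BAM file (primary alignments only).

    ``is_discordant`` is recomputed from reference, orientation and genomic
    span rather than trusted from the proper-pair flag.  Unpaired read ids
    at end of stream are emitted with one empty mate and a warning.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    pending: dict[str, pysam.AlignedSegment] = {}
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        it = fh.fetch(region=region) if region else fh.fetch(until_eof=True)
        for rec in it:
            if rec.is_secondary or rec.is_supplementary:
                continue
            qn = rec.query_name
            if qn in pending:
                other = pending.pop(qn)
                first, second = (other, rec) if other.is_read1 else (rec, other)
                m1, m2 = _mate_alignment(first), _mate_alignment(second)
                yield ReadPairRecord(
                    read_id=qn,
                    mate1=m1,
                    mate2=m2,
                    sequence1=_sequenced(first),
                    sequence2=_sequenced(second),
                    is_discordant=_discordant(m1, m2, max_insert),
                )
            else:
                pending[qn] = rec
    for qn, rec in pending.items():
        log.warning("unpaired read id %s at end of stream", qn)
        m = _mate_alignment(rec)
        if rec.is_read2:
            yield ReadPairRecord(qn, MateAlignment(mapped=False), m, "", _sequenced(rec))
        else:
            yield ReadPairRecord(qn, m, MateAlignment(mapped=False), _sequenced(rec), "")


# ---------------------------------------------------------------------------
# Modified BEDPE (fcircRNA interchange format)
# ---------------------------------------------------------------------------

_BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score",
    "strand1", "strand2", "bs_chrom5", "bs_pos5", "bs_strand5", "bs_chrom3",
    "bs_pos3", "bs_strand3", "gene5", "gene3", "fusion_reads",
    "backsplice_reads", "read_ids", "canonical5", "canonical3",
]


def write_fcirc_bedpe(records: Iterable[FcircBedpeRecord], path: str | Path) -> None:
    """Write fcircRNA calls in the modified-BEDPE schema.

    Columns 1-10 are standard BEDPE describing the fusion junction (each
    breakpoint a 1-bp block, 0-based half-open); columns 11+ carry the
    backsplice junction, gene names, read support, supporting read ids and
    canonical-boundary flags.
    """
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_BEDPE_COLUMNS) + "\n")
        for r in records:
            fields = [
                r.chrom1, r.start1, r.end1, r.chrom2, r.start2, r.end2,
                r.name, r.score, r.strand1, r.strand2,
                r.bs_chrom5, r.bs_pos5, r.bs_strand5,
                r.bs_chrom3, r.bs_pos3, r.bs_strand3,
                r.gene5, r.gene3, r.fusion_reads, r.backsplice_reads,
                ";".join(r.read_ids) if r.read_ids else ".",
                int(r.canonical5), int(r.canonical3),
            ]
            fh.write("\t".join(str(f) for f in fields) + "\n")


def read_fcirc_bedpe(path: str | Path) -> list[FcircBedpeRecord]:
    """Read the modified-BEDPE schema back; extra trailing columns are ignored."""
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < len(_BEDPE_COLUMNS):
                raise ValueError(f"{path}: expected >={len(_BEDPE_COLUMNS)} columns, got {len(f)}")
            records.append(
                FcircBedpeRecord(
                    chrom1=f[0], start1=int(f[1]), end1=int(f[2]),
                    chrom2=f[3], start2=int(f[4]), end2=int(f[5]),
                    name=f[6], score=int(f[7]), strand1=f[8], strand2=f[9],
                    bs_chrom5=f[10], bs_pos5=int(f[11]), bs_strand5=f[12],
                    bs_chrom3=f[13], bs_pos3=int(f[14]), bs_strand3=f[15],
                    gene5=f[16], gene3=f[17],
                    fusion_reads=int(f[18]), backsplice_reads=int(f[19]),
                    read_ids=[] if f[20] == "." else f[20].split(";"),
                    canonical5=bool(int(f[21])), canonical3=bool(int(f[22])),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Junction TSV and VCF breakends
# ---------------------------------------------------------------------------

def _gene_or_dot(name: Optional[str]) -> str:
    if not name:
        log.warning("junction with missing gene annotation written with '.'")
        return "."
    return name


def write_junction_tsv(
    junctions: Iterable[JunctionCluster],
    path: str | Path,
    categories: Optional[dict[int, str]] = None,
) -> None:
    """Write one junction per row with the full annotation set.

    ``categories`` optionally maps ``id(junction)`` to a secondary-junction
    category label.
    """
    cols = [
        "gene5", "gene3", "donor_chrom", "donor_pos", "donor_strand",
        "acceptor_chrom", "acceptor_pos", "acceptor_strand", "spanning_reads",
        "encompassing_reads", "wgs_reads", "canonical_donor",
        "canonical_acceptor", "category", "read_ids",
    ]
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        for j in junctions:
            cat = (categories or {}).get(id(j), ".")
            fields = [
                _gene_or_dot(j.donor_gene), _gene_or_dot(j.acceptor_gene),
                j.donor.chrom, j.donor.pos, j.donor.strand,
                j.acceptor.chrom, j.acceptor.pos, j.acceptor.strand,
                j.support, j.encompassing_support, j.wgs_support,
                int(j.canonical_donor), int(j.canonical_acceptor), cat,
                ";".join(j.read_ids) if j.members else ".",
            ]
            fh.write("\t".join(str(f) for f in fields) + "\n")


def _bnd_alt(ref: str, mate_chrom: str, mate_pos1: int, here_strand: str,
             mate_strand: str, donor_side: bool) -> str:
    """VCF breakend ALT string for one side of an oriented junction."""
    p = f"{mate_chrom}:{mate_pos1}"
    if donor_side:
        if here_strand == "+":
            return f"{ref}[{p}[" if mate_strand == "+" else f"{ref}]{p}]"
        return f"]{p}]{ref}" if mate_strand == "-" else f"[{p}[{ref}"
    # acceptor side: the donor-side piece attaches upstream of this base
    if here_strand == "+":
        return f"]{p}]{ref}" if mate_strand == "+" else f"[{p}[{ref}"
    return f"{ref}[{p}[" if mate_strand == "-" else f"{ref}]{p}]"


def write_vcf(
    junctions: Iterable[JunctionCluster],
    path: str | Path,
    genome: Optional[dict[str, str]] = None,
) -> None:
    """Write fusion junctions as VCF 4.2 breakend (BND) pairs with MATEID links."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend id">',
        '##INFO=<ID=GENE5,Number=1,Type=String,Description="5-prime gene">',
        '##INFO=<ID=GENE3,Number=1,Type=String,Description="3-prime gene">',
        '##INFO=<ID=SPAN,Number=1,Type=Integer,Description="Spanning read support">',
        '##INFO=<ID=ENC,Number=1,Type=Integer,Description="Encompassing pair support">',
        '##INFO=<ID=WGS,Number=1,Type=Integer,Description="WGS read support">',
        '##INFO=<ID=CANON,Number=1,Type=String,Description="Canonical donor,acceptor flags">',
    ]
    if genome:
        for chrom in genome:
            lines.append(f"##contig=<ID={chrom},length={len(genome[chrom])}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for i, j in enumerate(junctions):
        name = f"bnd_{i}"
        ref_d = genome[j.donor.chrom][j.donor.pos] if genome else "N"
        ref_a = genome[j.acceptor.chrom][j.acceptor.pos] if genome else "N"
        info = (
            f"SVTYPE=BND;GENE5={_gene_or_dot(j.donor_gene)};GENE3={_gene_or_dot(j.acceptor_gene)};"
            f"SPAN={j.support};ENC={j.encompassing_support};WGS={j.wgs_support};"
            f"CANON={int(j.canonical_donor)},{int(j.canonical_acceptor)}"
        )
        alt_d = _bnd_alt(ref_d, j.acceptor.chrom, j.acceptor.pos + 1,
                         j.donor.strand, j.acceptor.strand, donor_side=True)
        alt_a = _bnd_alt(ref_a, j.donor.chrom, j.donor.pos + 1,
                         j.acceptor.strand, j.donor.strand, donor_side=False)
        lines.append(
            f"{j.donor.chrom}\t{j.donor.pos + 1}\t{name}_1\t{ref_d}\t{alt_d}\t.\t.\t"
            f"{info};MATEID={name}_2"
        )
        lines.append(
            f"{j.acceptor.chrom}\t{j.acceptor.pos + 1}\t{name}_2\t{ref_a}\t{alt_a}\t.\t.\t"
            f"{info};MATEID={name}_1"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
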