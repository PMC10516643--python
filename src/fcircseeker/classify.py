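"""Primary-junction designation, secondary-junction orientation annotation,
physical-possibility review and fcircRNA call assembly.

All upstream/downstream reasoning happens in transcription-direction
coordinates per gene (:meth:`GeneModel.tkey`), which makes plus-strand,
minus-strand and mixed-strand fusions uniform; genomic positions are only
used for output.  The four-way secondary-junction rule:

* ``backsplice`` -- donor in the 3' gene at/downstream of the primary
  acceptor AND acceptor in the 5' gene at/upstream of the primary donor
  (the junction points back across the fusion, closing a circle);
* ``alternative_splice`` -- donor in the 5' gene, acceptor in the 3' gene
  (forward orientation) at coordinates differing from the primary;
* ``reciprocal_fusion`` -- donor in the 3' gene upstream of the primary
  acceptor, acceptor in the 5' gene downstream of the primary donor, both
  at canonical exon boundaries (the complementary product of a balanced
  rearrangement);
* ``unclassified`` -- anything else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import (
    Breakpoint,
    FcircBedpeRecord,
    FcircRNACall,
    FusionCandidate,
    GeneModel,
    GenomicInterval,
    JunctionCluster,
    SecondaryAnnotation,
)

log = logging.getLogger(__name__)

BACKSPLICE = "backsplice"
ALTERNATIVE_SPLICE = "alternative_splice"
RECIPROCAL_FUSION = "reciprocal_fusion"
UNCLASSIFIED = "unclassified"


@dataclass
class FilterConfig:
    """Read-support thresholds: lenient for published junctions, stricter for novel."""

    min_reads_known: int = 1
    min_reads_novel: int = 2
    known_junctions: Optional[set[tuple[str, int, str, int]]] = None
    # entries: (donor_chrom, donor_pos, acceptor_chrom, acceptor_pos)
    match_window: int = 5

    def __post_init__(self) -> None:
        if self.min_reads_known < 0 or self.min_reads_novel < 0:
            raise ValueError("read thresholds must be >= 0")

    def is_known(self, junction: JunctionCluster) -> bool:
        if not self.known_junctions:
            return False
        for dc, dp, ac, ap in self.known_junctions:
            if (
                dc == junction.donor.chrom
                and ac == junction.acceptor.chrom
                and abs(dp - junction.donor.pos) <= self.match_window
                and abs(ap - junction.acceptor.pos) <= self.match_window
            ):
                return True
        return False


def select_primary(
    junctions: Sequence[JunctionCluster],
) -> tuple[JunctionCluster, list[JunctionCluster]]:
    """Designate the junction with greatest distinct spanning-read support.

    Ties break by (1) greater WGS support, (2) both-ends-canonical,
    (3) leftmost genomic donor coordinate.
    """
    if not junctions:
        raise ValueError("select_primary requires at least one junction")
    ranked = sorted(
        junctions,
        key=lambda j: (
            -j.support,
            -j.wgs_support,
            -(j.canonical_donor and j.canonical_acceptor),
            j.donor.chrom,
            j.donor.pos,
        ),
    )
    return ranked[0], ranked[1:]


def _in_gene(bp: Breakpoint, gene: GeneModel) -> bool:
    return gene.contains(bp.chrom, bp.pos) and bp.strand == gene.strand


def classify_secondary(
    secondary: JunctionCluster,
    primary: JunctionCluster,
    gene5: GeneModel,
    gene3: GeneModel,
) -> SecondaryAnnotation:
    """Annotate a secondary junction by its orientation relative to the primary."""
    if gene5.strand not in "+-" or gene3.strand not in "+-":
        return SecondaryAnnotation(secondary, UNCLASSIFIED)
    d, a = secondary.donor, secondary.acceptor
    category = UNCLASSIFIED
    if _in_gene(d, gene5) and _in_gene(a, gene3):
        if (d.pos, a.pos) != (primary.donor.pos, primary.acceptor.pos):
            category = ALTERNATIVE_SPLICE
    elif _in_gene(d, gene3) and _in_gene(a, gene5):
        points_back = (
            gene3.tkey(d.pos) >= gene3.tkey(primary.acceptor.pos)
            and gene5.tkey(a.pos) <= gene5.tkey(primary.donor.pos)
        )
        forward_reciprocal = (
            gene3.tkey(d.pos) < gene3.tkey(primary.acceptor.pos)
            and gene5.tkey(a.pos) > gene5.tkey(primary.donor.pos)
        )
        if points_back:
            category = BACKSPLICE
        elif forward_reciprocal and secondary.canonical_donor and secondary.canonical_acceptor:
            category = RECIPROCAL_FUSION
    possible = category == BACKSPLICE and physically_possible(secondary, primary, gene5, gene3)
    return SecondaryAnnotation(secondary, category, physically_possible=possible)


def physically_possible(
    backsplice: JunctionCluster,
    primary: JunctionCluster,
    gene5: GeneModel,
    gene3: GeneModel,
) -> bool:
    """Can this circle be a subsequence of the fusion transcript?

    True iff the backsplice acceptor lies at/upstream of the primary donor
    within the 5' gene AND the backsplice donor lies at/downstream of the
    primary acceptor within the 3' gene.  Calls failing this review are
    physically impossible and excluded.
    """
    a, d = backsplice.acceptor, backsplice.donor
    if not (_in_gene(a, gene5) and _in_gene(d, gene3)):
        return False
    return (
        gene5.tkey(a.pos) <= gene5.tkey(primary.donor.pos)
        and gene3.tkey(d.pos) >= gene3.tkey(primary.acceptor.pos)
    )


def apply_support_filters(
    junctions: Sequence[JunctionCluster],
    config: FilterConfig,
) -> list[JunctionCluster]:
    """Keep junctions meeting the distinct-read threshold for their class.

    Junctions matching the known list (within ``match_window``) need
    ``min_reads_known`` independent reads; novel junctions need
    ``min_reads_novel``.
    """
    kept = []
    for j in junctions:
        threshold = config.min_reads_known if config.is_known(j) else config.min_reads_novel
        if j.support >= threshold:
            kept.append(j)
    return kept


def build_candidates(
    clusters: Sequence[JunctionCluster],
    genes: dict[str, GeneModel] | Sequence[GeneModel],
) -> list[FusionCandidate]:
    """Group junction clusters per gene pair and designate each pair's primary.

    The 5' and 3' roles follow the primary junction's orientation: the
    primary's donor gene is the fusion's 5' partner.
    """
    if not isinstance(genes, dict):
        genes = {g.gene_id: g for g in genes}
    grouped: dict[frozenset, list[JunctionCluster]] = {}
    for cl in clusters:
        grouped.setdefault(frozenset((cl.donor_gene, cl.acceptor_gene)), []).append(cl)
    candidates = []
    for pair, juncs in sorted(grouped.items(), key=lambda kv: sorted(kv[0])):
        primary, _ = select_primary(juncs)
        candidates.append(
            FusionCandidate(
                gene5=genes[primary.donor_gene],
                gene3=genes[primary.acceptor_gene],
                junctions=juncs,
                primary=primary,
            )
        )
    return candidates


def _exons_between(gene: GeneModel, from_key: int, to_key: int) -> list[GenomicInterval]:
    """Exons whose transcribed span lies within [from_key, to_key] (tkey units)."""
    out = []
    for ex in gene.exons:
        first = ex.start if gene.strand == "+" else ex.end - 1
        last = ex.end - 1 if gene.strand == "+" else ex.start
        if gene.tkey(first) >= from_key and gene.tkey(last) <= to_key:
            out.append(ex)
    return out


def circle_exons(
    call_backsplice: JunctionCluster,
    primary: JunctionCluster,
    gene5: GeneModel,
    gene3: GeneModel,
) -> list[GenomicInterval]:
    """Canonical exon content of the circle, in transcription order."""
    part5 = _exons_between(
        gene5,
        gene5.tkey(call_backsplice.acceptor.pos),
        gene5.tkey(primary.donor.pos),
    )
    part3 = _exons_between(
        gene3,
        gene3.tkey(primary.acceptor.pos),
        gene3.tkey(call_backsplice.donor.pos),
    )
    return part5 + part3


def assemble_fcirc_calls(
    candidates: Sequence[FusionCandidate],
    config: Optional[FilterConfig] = None,
) -> list[FcircRNACall]:
    """Emit one fcircRNA call per surviving backsplice junction.

    A backsplice survives when it is classified as such, passes the
    physical-possibility review, and meets the read-support filter (as does
    the primary fusion junction itself).
    """
    config = config or FilterConfig()
    calls: list[FcircRNACall] = []
    for cand in candidates:
        if not apply_support_filters([cand.primary], config):
            continue
        secondaries = [j for j in cand.junctions if j is not cand.primary]
        for sec in secondaries:
            ann = classify_secondary(sec, cand.primary, cand.gene5, cand.gene3)
            if ann.category != BACKSPLICE or not ann.physically_possible:
                continue
            if not apply_support_filters([sec], config):
                continue
            calls.append(
                FcircRNACall(
                    fusion=cand.primary,
                    backsplice=sec,
                    gene5=cand.gene5.gene_id,
                    gene3=cand.gene3.gene_id,
                    exons_in_circle=circle_exons(sec, cand.primary, cand.gene5, cand.gene3),
                    fusion_reads=cand.primary.support,
                    backsplice_reads=sec.support,
                )
            )
    return calls


def calls_to_bedpe(calls: Sequence[FcircRNACall]) -> list[FcircBedpeRecord]:
    """Serialize calls into the modified-BEDPE schema.

    The fusion junction occupies the standard BEDPE block (each breakpoint a
    1-bp block); bs_*5 columns carry the backsplice acceptor (the circle's
    5'-gene endpoint) and bs_*3 the backsplice donor.
    """
    records = []
    for call in calls:
        f = call.fusion
        b = call.backsplice
        records.append(
            FcircBedpeRecord(
                chrom1=f.donor.chrom, start1=f.donor.pos, end1=f.donor.pos + 1,
                chrom2=f.acceptor.chrom, start2=f.acceptor.pos, end2=f.acceptor.pos + 1,
                name=f"{call.gene5}::{call.gene3}",
                score=call.fusion_reads,
                strand1=f.donor.strand, strand2=f.acceptor.strand,
                bs_chrom5=b.acceptor.chrom, bs_pos5=b.acceptor.pos, bs_strand5=b.acceptor.strand,
                bs_chrom3=b.donor.chrom, bs_pos3=b.donor.pos, bs_strand3=b.donor.strand,
                gene5=call.gene5, gene3=call.gene3,
                fusion_reads=call.fusion_reads,
                backsplice_reads=call.backsplice_reads,
                read_ids=b.read_ids,
                canonical5=b.canonical_acceptor,
                canonical3=b.canonical_donor,
            )
        )
    return records
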