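"""Core genomic domain types shared across the toolkit.

All internal coordinates are 0-based half-open intervals; single-base
breakpoints are stored as the 0-based position of the transcribed base
itself.  Conversions to 1-based conventions (GTF, VCF) happen only at
format boundaries in :mod:`fcircseeker.formats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STRANDS = ("+", "-")


def revcomp(seq: str) -> str:
    """Reverse-complement a nucleotide string (N-safe)."""
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_pos(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


class Breakpoint(NamedTuple):
    """A single oriented breakpoint: the 0-based position of a transcribed base."""

    chrom: str
    pos: int
    strand: str


@dataclass
class GeneModel:
    """A gene with its strand and the union of its transcripts' exons.

    Exons are stored in *transcription order*: ascending genomic position on
    the plus strand, descending on the minus strand.  The exon set is the
    per-gene union across transcripts, so exons never overlap.
    """

    gene_id: str
    gene_name: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ex in self.exons:
            if ex.strand != self.strand or ex.chrom != self.chrom:
                raise ValueError(f"exon {ex} inconsistent with gene {self.gene_id}")
            if not (self.interval.start <= ex.start and ex.end <= self.interval.end):
                raise ValueError(f"exon {ex} outside gene interval of {self.gene_id}")
        gstarts = [ex.start for ex in self.exons]
        expected = sorted(gstarts, reverse=self.strand == "-")
        if gstarts != expected:
            raise ValueError(f"exons of {self.gene_id} not in transcription order")
        for a, b in zip(sorted(gstarts), sorted(ex.end for ex in self.exons)):
            pass  # overlap check below
        ordered = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(ordered, ordered[1:]):
            if a.end > b.start:
                raise ValueError(f"overlapping exons in {self.gene_id}")

    # -- convenience -------------------------------------------------------
    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def spliced_length(self) -> int:
        return sum(len(ex) for ex in self.exons)

    def contains(self, chrom: str, pos: int) -> bool:
        return self.interval.contains_pos(chrom, pos)

    def tkey(self, pos: int) -> int:
        """Transcription-direction ordering key for a genomic position.

        Smaller key = further upstream (5') in this gene's transcription
        direction, regardless of strand.
        """
        return pos if self.strand == "+" else -pos

    def transcript_to_genomic(self, toff: int) -> int:
        """Genomic position of the base at spliced-transcript offset ``toff``."""
        if toff < 0:
            raise IndexError(toff)
        for ex in self.exons:
            if toff < len(ex):
                if self.strand == "+":
                    return ex.start + toff
                return ex.end - 1 - toff
            toff -= len(ex)
        raise IndexError("offset beyond spliced transcript")

    def genomic_to_transcript(self, pos: int) -> Optional[int]:
        """Spliced-transcript offset of a genomic base, or None if intronic."""
        off = 0
        for ex in self.exons:
            if ex.start <= pos < ex.end:
                if self.strand == "+":
                    return off + (pos - ex.start)
                return off + (ex.end - 1 - pos)
            off += len(ex)
        return None

    def donor_boundaries(self) -> list[int]:
        """Genomic positions of each exon's last transcribed base (splice-donor side)."""
        if self.strand == "+":
            return [ex.end - 1 for ex in self.exons]
        return [ex.start for ex in self.exons]

    def acceptor_boundaries(self) -> list[int]:
        """Genomic positions of each exon's first transcribed base (splice-acceptor side)."""
        if self.strand == "+":
            return [ex.start for ex in self.exons]
        return [ex.end - 1 for ex in self.exons]

    def spliced_sequence(self, genome: dict[str, str]) -> str:
        chrom_seq = genome[self.chrom]
        parts = [chrom_seq[ex.start : ex.end] for ex in sorted(self.exons, key=lambda e: e.start)]
        seq = "".join(parts)
        return seq if self.strand == "+" else revcomp(seq)


@dataclass(frozen=True)
class Cytoband:
    chrom: str
    interval: GenomicInterval
    band_name: str
    stain: str


@dataclass
class MateAlignment:
    """One mate's alignment footprint as reported by the aligner."""

    mapped: bool
    chrom: Optional[str] = None
    start: int = 0
    end: int = 0
    is_reverse: bool = False
    clip_left: int = 0
    clip_right: int = 0

    @property
    def max_clip(self) -> int:
        return max(self.clip_left, self.clip_right)


@dataclass
class ReadPairRecord:
    """A mate-paired sequencing record with discordance already computed."""

    read_id: str
    mate1: MateAlignment
    mate2: MateAlignment
    sequence1: str
    sequence2: str
    is_discordant: bool = False

    def __post_init__(self) -> None:
        if not (self.sequence1 or self.sequence2):
            raise ValueError(f"read pair {self.read_id} has no sequence")


class SplitSegment(NamedTuple):
    gene_id: str
    interval: GenomicInterval
    read_start: int
    read_end: int


@dataclass
class SplitAlignment:
    """A spanning read split across a junction between two genes."""

    read_id: str
    segment5: SplitSegment
    segment3: SplitSegment
    donor: Breakpoint
    acceptor: Breakpoint
    junction_offset_in_read: int
    mismatches: int = 0


@dataclass
class JunctionCluster:
    """A cluster of spanning reads agreeing on one donor->acceptor junction."""

    donor: Breakpoint
    acceptor: Breakpoint
    donor_gene: str
    acceptor_gene: str
    members: list[SplitAlignment] = field(default_factory=list)
    encompassing_support: int = 0
    canonical_donor: bool = False
    canonical_acceptor: bool = False
    wgs_support: int = 0

    @property
    def support(self) -> int:
        """Number of distinct (independent) spanning reads."""
        return len({m.read_id for m in self.members})

    @property
    def read_ids(self) -> list[str]:
        return sorted({m.read_id for m in self.members})


@dataclass
class FusionCandidate:
    """A gene pair with all of its junction clusters and the designated primary."""

    gene5: GeneModel
    gene3: GeneModel
    junctions: list[JunctionCluster]
    primary: JunctionCluster


@dataclass
class SecondaryAnnotation:
    junction: JunctionCluster
    category: str  # backsplice | alternative_splice | reciprocal_fusion | unclassified
    physically_possible: bool = False


@dataclass
class FcircRNACall:
    """A called fusion-derived circular RNA: primary fusion + backsplice junction."""

    fusion: JunctionCluster
    backsplice: JunctionCluster
    gene5: str
    gene3: str
    exons_in_circle: list[GenomicInterval] = field(default_factory=list)
    fusion_reads: int = 0
    backsplice_reads: int = 0


@dataclass
class FcircBedpeRecord:
    """One line of the modified-BEDPE fcircRNA interchange format."""

    # Standard BEDPE block: the fusion junction, each breakpoint a 1-bp block.
    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int
    name: str
    score: int
    strand1: str
    strand2: str
    # Extended columns: the backsplice junction + annotation.
    bs_chrom5: str
    bs_pos5: int
    bs_strand5: str
    bs_chrom3: str
    bs_pos3: int
    bs_strand3: str
    gene5: str
    gene3: str
    fusion_reads: int
    backsplice_reads: int
    read_ids: list[str] = field(default_factory=list)
    canonical5: bool = False
    canonical3: bool = False

    def __post_init__(self) -> None:
        if self.fusion_reads < 0 or self.backsplice_reads < 0:
            raise ValueError("read support counts must be >= 0")


@dataclass
class SimTruthRecord:
    """Ground truth for one simulated fcircRNA event."""

    fusion_id: str
    gene5: str
    gene3: str
    fusion_donor: Breakpoint
    fusion_acceptor: Breakpoint
    backsplice_donor: Breakpoint
    backsplice_acceptor: Breakpoint
    exons_in_circle: list[GenomicInterval] = field(default_factory=list)
    same_chrom_same_strand: bool = False
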