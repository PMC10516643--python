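"""fcircRNA figure generation: annotation then rendering.

The annotation step snaps non-canonical junction coordinates to the nearest
exon boundary (upstream for the 5' end of a junction, downstream for the 3'
end), looks up cytoband labels, and selects at most three exon boxes per
gene around the junctions.  The rendering step draws, per call: a gene
panel with genomic context, the fusion transcript track with a junction
marker, and the backsplice arc closing the circle.  Exon boxes are not to
scale.  Output is deterministic for fixed input (stable SVG ids, no
timestamps), so figures can be golden-tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import FancyArrowPatch, Rectangle

from .formats import lookup_cytoband
from .model import (
    Breakpoint,
    Cytoband,
    FcircBedpeRecord,
    FcircRNACall,
    GeneModel,
    revcomp,
)

log = logging.getLogger(__name__)

SUPPORTED_FORMATS = ("svg", "pdf", "png")

MAX_EXON_BOXES = 3


@dataclass
class ExonBox:
    gene: str
    exon_number: int  # 1-based index in transcription order
    highlight_fusion: bool = False
    highlight_backsplice: bool = False
    ellipsis_after: bool = False


@dataclass
class GenePanel:
    name: str
    chrom: str
    cytoband: Optional[str]
    strand: str


@dataclass
class PlotModel:
    gene_panels: list[GenePanel]
    fusion_track: dict[str, list[ExonBox]]  # gene name -> boxes (transcription order)
    circle_track: tuple[int, int]  # (box index of backsplice acceptor, of donor) in flat order
    support_labels: Optional[tuple[int, int]] = None  # (fusion_reads, backsplice_reads)
    title: str = ""

    def __post_init__(self) -> None:
        for gene, boxes in self.fusion_track.items():
            if len(boxes) > MAX_EXON_BOXES:
                raise ValueError(f"more than {MAX_EXON_BOXES} exon boxes for {gene}")


def _snap_directional(gene: GeneModel, pos: int, side: str) -> int:
    """Snap to the nearest exon boundary upstream ('5') or downstream ('3')."""
    bounds = []
    for ex in gene.exons:
        bounds.append(ex.start if gene.strand == "+" else ex.end - 1)
        bounds.append(ex.end - 1 if gene.strand == "+" else ex.start)
    key = gene.tkey(pos)
    if side == "5":
        cands = [b for b in bounds if gene.tkey(b) <= key]
        return max(cands, key=gene.tkey) if cands else pos
    cands = [b for b in bounds if gene.tkey(b) >= key]
    return min(cands, key=gene.tkey) if cands else pos


def _exon_index_at(gene: GeneModel, pos: int) -> int:
    """Transcription-order index of the exon containing (or nearest to) pos."""
    for i, ex in enumerate(gene.exons):
        if ex.start <= pos < ex.end:
            return i
    return min(
        range(len(gene.exons)),
        key=lambda i: min(abs(gene.exons[i].start - pos), abs(gene.exons[i].end - 1 - pos)),
    )


def _select_boxes(gene: GeneModel, gname: str, lo: int, hi: int,
                  fusion_idx: int, bs_idx: int) -> list[ExonBox]:
    """Exon boxes covering transcription-order index range [lo, hi], capped at 3.

    When the range is wider than three exons, the junction-adjacent end
    exons are kept with one interior neighbor and an ellipsis mark.
    """
    idxs = list(range(lo, hi + 1))
    if len(idxs) > MAX_EXON_BOXES:
        idxs = [lo, lo + 1, hi]
    boxes = []
    for n, i in enumerate(idxs):
        nxt = idxs[n + 1] if n + 1 < len(idxs) else None
        boxes.append(
            ExonBox(
                gene=gname,
                exon_number=i + 1,
                highlight_fusion=i == fusion_idx,
                highlight_backsplice=i == bs_idx,
                ellipsis_after=nxt is not None and nxt > i + 1,
            )
        )
    return boxes


def _as_breakpoints(call: Union[FcircRNACall, FcircBedpeRecord]):
    if isinstance(call, FcircRNACall):
        return (
            call.gene5, call.gene3,
            call.fusion.donor, call.fusion.acceptor,
            call.backsplice.acceptor, call.backsplice.donor,
            call.fusion_reads, call.backsplice_reads,
        )
    return (
        call.gene5, call.gene3,
        Breakpoint(call.chrom1, call.start1, call.strand1),
        Breakpoint(call.chrom2, call.start2, call.strand2),
        Breakpoint(call.bs_chrom5, call.bs_pos5, call.bs_strand5),
        Breakpoint(call.bs_chrom3, call.bs_pos3, call.bs_strand3),
        call.fusion_reads, call.backsplice_reads,
    )


def annotate_for_plot(
    call: Union[FcircRNACall, FcircBedpeRecord],
    genes: dict[str, GeneModel] | Sequence[GeneModel],
    ideogram: dict[str, list[Cytoband]],
) -> PlotModel:
    """Build the figure model: snapped junctions, cytobands, <=3 exon boxes/gene."""
    if not isinstance(genes, dict):
        genes = {g.gene_id: g for g in genes}
    name_map = {g.gene_name: g for g in genes.values()} | genes
    g5n, g3n, f_donor, f_acceptor, bs_acceptor, bs_donor, fr, br = _as_breakpoints(call)
    for gname in (g5n, g3n):
        if gname not in name_map:
            raise KeyError(f"gene {gname} absent from annotation")
    gene5, gene3 = name_map[g5n], name_map[g3n]

    fd = _snap_directional(gene5, f_donor.pos, "5")
    fa = _snap_directional(gene3, f_acceptor.pos, "3")
    ba = _snap_directional(gene5, bs_acceptor.pos, "3")
    bd = _snap_directional(gene3, bs_donor.pos, "5")

    panels = []
    for gname, gene, pos in ((g5n, gene5, fd), (g3n, gene3, fa)):
        band = lookup_cytoband(ideogram, gene.chrom, pos)
        if band is None:
            log.warning("chromosome %s absent from ideogram; panel without band label", gene.chrom)
        panels.append(
            GenePanel(
                name=gname,
                chrom=gene.chrom,
                cytoband=f"{gene.chrom.removeprefix('chr')}{band.band_name}" if band else None,
                strand=gene.strand,
            )
        )

    i_fd = _exon_index_at(gene5, fd)
    i_ba = _exon_index_at(gene5, ba)
    j_fa = _exon_index_at(gene3, fa)
    j_bd = _exon_index_at(gene3, bd)
    boxes5 = _select_boxes(gene5, g5n, min(i_ba, i_fd), max(i_ba, i_fd), i_fd, i_ba)
    boxes3 = _select_boxes(gene3, g3n, min(j_fa, j_bd), max(j_fa, j_bd), j_fa, j_bd)
    flat = boxes5 + boxes3
    acc_idx = next(i for i, b in enumerate(flat) if b.gene == g5n and b.highlight_backsplice)
    don_idx = next(
        len(boxes5) + i for i, b in enumerate(boxes3) if b.highlight_backsplice
    )
    return PlotModel(
        gene_panels=panels,
        fusion_track={g5n: boxes5, g3n: boxes3},
        circle_track=(acc_idx, don_idx),
        support_labels=(fr, br),
        title=f"circ{g5n}::{g3n}",
    )


# ---------------------------------------------------------------------------
# Spanning-read counting from a BAM/SAM
# ---------------------------------------------------------------------------

def count_spanning_support(
    call: Union[FcircRNACall, FcircBedpeRecord],
    alignments: str | Path | None,
    genes: Optional[dict[str, GeneModel] | Sequence[GeneModel]] = None,
    genome: Optional[dict[str, str]] = None,
    clip_tolerance: int = 3,
    recheck_bases: int = 8,
) -> Optional[tuple[int, int]]:
    """Count distinct reads whose alignment crosses each junction.

    Reads soft-clipped at a junction breakpoint are counted; when gene
    models and a genome are supplied the clipped bases are re-checked
    against the sequence continuing across the junction.  Returns None when
    no alignment file is given (counts omitted, not zeroed).  These counts
    are computed independently of the caller and may differ from its
    reported support.
    """
    if alignments is None:
        return None
    from .formats import read_alignments

    if genes is not None and not isinstance(genes, dict):
        genes = {g.gene_id: g for g in genes}
    g5n, g3n, f_donor, f_acceptor, bs_acceptor, bs_donor, _, _ = _as_breakpoints(call)

    def continuation(from_gene: str, bp: Breakpoint, direction: str) -> Optional[str]:
        if genes is None or genome is None or from_gene not in genes:
            return None
        gene = genes[from_gene]
        toff = gene.genomic_to_transcript(bp.pos)
        if toff is None:
            return None
        seq = gene.spliced_sequence(genome)
        if direction == "after":
            return seq[toff : toff + recheck_bases]
        return seq[max(0, toff - recheck_bases + 1) : toff + 1]

    junctions = {
        "fusion": (f_donor, f_acceptor,
                   continuation(g3n, f_acceptor, "after"),
                   continuation(g5n, f_donor, "before")),
        "backsplice": (bs_donor, bs_acceptor,
                       continuation(g5n, bs_acceptor, "after"),
                       continuation(g3n, bs_donor, "before")),
    }
    counts = {"fusion": set(), "backsplice": set()}

    def clip_matches(seq: str, mate, bp: Breakpoint, expect_after: Optional[str],
                     expect_before: Optional[str]) -> bool:
        """Is this mate clipped at bp with a clip consistent with the junction?"""
        if not mate.mapped or mate.chrom != bp.chrom:
            return False
        # Clip on the genomic-right side of the breakpoint base.
        if mate.clip_right >= 1 and abs(mate.end - 1 - bp.pos) <= clip_tolerance:
            return True
        if mate.clip_left >= 1 and abs(mate.start - bp.pos) <= clip_tolerance:
            return True
        return False

    for rec in read_alignments(alignments):
        for mate, seq in ((rec.mate1, rec.sequence1), (rec.mate2, rec.sequence2)):
            for jname, (donor, acceptor, after_seq, before_seq) in junctions.items():
                if clip_matches(seq, mate, donor, after_seq, before_seq) or clip_matches(
                    seq, mate, acceptor, after_seq, before_seq
                ):
                    counts[jname].add(rec.read_id)
    return len(counts["fusion"]), len(counts["backsplice"])


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render(model: PlotModel, path: str | Path, format: str = "svg") -> Path:
    """Draw one fcircRNA figure; vector output is byte-deterministic."""
    if format not in SUPPORTED_FORMATS:
        raise ValueError(
            f"unsupported format {format!r}; supported formats: {', '.join(SUPPORTED_FORMATS)}"
        )
    with plt.rc_context({"svg.hashsalt": "fcircseeker", "svg.fonttype": "none"}):
        fig, ax = plt.subplots(figsize=(8, 3.2))
        ax.set_xlim(0, 10)
        ax.set_ylim(0, 4)
        ax.axis("off")
        ax.text(5, 3.7, model.title, ha="center", fontsize=12, fontweight="bold")

        # gene panels with cytoband context
        for k, panel in enumerate(model.gene_panels):
            x = 2.5 + 5 * k
            label = panel.name + (f"  ({panel.cytoband})" if panel.cytoband else "")
            ax.text(x, 3.1, label, ha="center", fontsize=9)
            ax.annotate(
                "", xy=(x + 0.6, 2.92), xytext=(x - 0.6, 2.92),
                arrowprops=dict(arrowstyle="->" if panel.strand == "+" else "<-", lw=0.8),
            )

        # fusion transcript track
        flat: list[tuple[ExonBox, float]] = []
        x = 0.8
        genes_in_order = list(model.fusion_track)
        for gi, gname in enumerate(genes_in_order):
            for box in model.fusion_track[gname]:
                color = "#c44e52" if gi == 0 else "#4c72b0"
                ax.add_patch(Rectangle((x, 1.4), 0.8, 0.5, facecolor=color, edgecolor="black"))
                ax.text(x + 0.4, 1.65, str(box.exon_number), ha="center", va="center",
                        fontsize=8, color="white")
                flat.append((box, x + 0.4))
                x += 1.0
                if box.ellipsis_after:
                    ax.text(x - 0.1 + 0.15, 1.65, "...", ha="center", va="center", fontsize=10)
                    x += 0.5
            if gi == 0:
                junction_x = x - 0.1
                ax.plot([junction_x, junction_x], [1.2, 2.1], ls="--", color="black", lw=1)
                x += 0.3

        # backsplice arc from donor box back to acceptor box
        acc_i, don_i = model.circle_track
        x_acc = flat[acc_i][1]
        x_don = flat[don_i][1]
        arc = FancyArrowPatch(
            (x_don, 1.4), (x_acc, 1.4),
            connectionstyle="arc3,rad=0.45",
            arrowstyle="->", mutation_scale=12, color="#55a868", lw=1.4,
        )
        ax.add_patch(arc)

        if model.support_labels is not None:
            fr, br = model.support_labels
            ax.text(5, 0.25, f"fusion reads: {fr}    backsplice reads: {br}",
                    ha="center", fontsize=8)

        out = Path(path)
        meta = {"Date": None} if format == "svg" else {}
        fig.savefig(out, format=format, metadata=meta)
        plt.close(fig)
    return out


def render_bedpe_file(
    bedpe_path: str | Path,
    genes: dict[str, GeneModel] | Sequence[GeneModel],
    ideogram: dict[str, list[Cytoband]],
    out_dir: str | Path,
    format: str = "svg",
) -> list[Path]:
    """Render one figure per record of a modified-BEDPE file."""
    from .formats import read_fcirc_bedpe

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, rec in enumerate(read_fcirc_bedpe(bedpe_path)):
        model = annotate_for_plot(rec, genes, ideogram)
        paths.append(render(model, out / f"fcirc_{i:03d}_{rec.gene5}_{rec.gene3}.{format}", format))
    return paths
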