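"""Fusion junction detection from discordant pairs and split reads.

The pipeline mirrors the classic encompassing/spanning two-stage design:

1. a gene graph is built whose edges are gene pairs connected by discordant
   (encompassing) read pairs overlapping annotated exons;
2. edges are pruned by re-aligning each supporting mate against both partner
   genes' spliced exonic sequence and discarding pairs of ambiguous origin;
3. unmapped and soft-clipped reads are split-aligned (exact k-mer seed +
   gapless extension) across each surviving gene pair in both transcript
   orientations to recover junction-spanning reads;
4. spanning reads are clustered by junction coordinates and snapped to
   annotated exon boundaries when within the clustering window;
5. optional WGS alignments contribute breakpoint-level support counts.

Split alignment is gapless per segment (no indels across junctions); all
thresholds live in :class:`DetectParams`.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import (
    Breakpoint,
    GeneModel,
    GenomicInterval,
    JunctionCluster,
    ReadPairRecord,
    SplitAlignment,
    SplitSegment,
    revcomp,
)

log = logging.getLogger(__name__)


@dataclass
class DetectParams:
    cluster_window: int = 5
    min_segment_length: int = 15
    max_mismatches: int = 2
    min_encompassing_pairs: int = 1
    wgs_window: int = 1000
    kmer: int = 12
    max_insert: int = 1000

    def __post_init__(self) -> None:
        if self.min_segment_length < self.kmer:
            raise ValueError("min_segment_length must be >= kmer size")


@dataclass
class EdgeSupport:
    """Evidence attached to one gene-graph edge."""

    pairs: list[tuple[str, str, str, str, str]] = field(default_factory=list)
    # (read_id, gene_of_mate1, gene_of_mate2, seq1, seq2)

    @property
    def read_ids(self) -> set[str]:
        return {p[0] for p in self.pairs}

    @property
    def count(self) -> int:
        return len(self.read_ids)


@dataclass
class GeneGraph:
    nodes: dict[str, GeneModel]
    edges: dict[frozenset, EdgeSupport]


class ExonIndex:
    """Per-chromosome sorted exon lookup (genes assumed non-overlapping)."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.by_chrom: dict[str, list[tuple[int, int, str]]] = defaultdict(list)
        for g in genes:
            for ex in g.exons:
                self.by_chrom[ex.chrom].append((ex.start, ex.end, g.gene_id))
        for lst in self.by_chrom.values():
            lst.sort()
        self.starts = {c: [t[0] for t in lst] for c, lst in self.by_chrom.items()}

    def gene_at(self, chrom: str, start: int, end: int) -> Optional[str]:
        """Gene whose exon overlaps [start, end), or None."""
        lst = self.by_chrom.get(chrom)
        if not lst:
            return None
        i = bisect_right(self.starts[chrom], end - 1)
        for s, e, gid in reversed(lst[:i]):
            if e > start:
                return gid
            if e <= start and s < start - 10_000:
                break
        return None


def build_gene_graph(
    alignments: Iterable[ReadPairRecord],
    genes: Sequence[GeneModel],
) -> GeneGraph:
    """Connect gene pairs bridged by discordant read pairs over annotated exons."""
    index = ExonIndex(genes)
    by_id = {g.gene_id: g for g in genes}
    edges: dict[frozenset, EdgeSupport] = defaultdict(EdgeSupport)
    for rec in alignments:
        if not rec.is_discordant:
            continue
        m1, m2 = rec.mate1, rec.mate2
        g1 = index.gene_at(m1.chrom, m1.start, m1.end) if m1.mapped else None
        g2 = index.gene_at(m2.chrom, m2.start, m2.end) if m2.mapped else None
        if g1 is None or g2 is None or g1 == g2:
            continue
        key = frozenset((g1, g2))
        edges[key].pairs.append((rec.read_id, g1, g2, rec.sequence1, rec.sequence2))
    return GeneGraph(nodes=by_id, edges=dict(edges))


# ---------------------------------------------------------------------------
# Gapless k-mer alignment machinery
# ---------------------------------------------------------------------------

def _to_arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


class _GeneSeqCache:
    """Lazily built spliced sequences and k-mer indexes per gene."""

    def __init__(self, genes: dict[str, GeneModel], genome: dict[str, str], k: int):
        self.genes = genes
        self.genome = genome
        self.k = k
        self._seq: dict[str, str] = {}
        self._arr: dict[str, np.ndarray] = {}
        self._idx: dict[str, dict[str, list[int]]] = {}

    def seq(self, gid: str) -> str:
        if gid not in self._seq:
            self._seq[gid] = self.genes[gid].spliced_sequence(self.genome)
        return self._seq[gid]

    def arr(self, gid: str) -> np.ndarray:
        if gid not in self._arr:
            self._arr[gid] = _to_arr(self.seq(gid))
        return self._arr[gid]

    def index(self, gid: str) -> dict[str, list[int]]:
        if gid not in self._idx:
            s = self.seq(gid)
            idx: dict[str, list[int]] = defaultdict(list)
            for i in range(len(s) - self.k + 1):
                idx[s[i : i + self.k]].append(i)
            self._idx[gid] = dict(idx)
        return self._idx[gid]


def _diagonals(read: str, idx: dict[str, list[int]], k: int, cap: int = 8) -> list[int]:
    """Candidate target-minus-read diagonals ranked by seed hit count."""
    hits: Counter = Counter()
    for roff in range(len(read) - k + 1):
        for toff in idx.get(read[roff : roff + k], ()):
            hits[toff - roff] += 1
    return [d for d, _ in hits.most_common(cap)]


def _match_array(tarr: np.ndarray, d: int, rarr: np.ndarray) -> np.ndarray:
    R = len(rarr)
    m = np.zeros(R, dtype=bool)
    lo = max(0, -d)
    hi = min(R, len(tarr) - d)
    if hi > lo:
        m[lo:hi] = tarr[d + lo : d + hi] == rarr[lo:hi]
    return m


def _best_score(read: str, cache: _GeneSeqCache, gid: str) -> int:
    """Best gapless full-length match count of read (either orientation) in a gene."""
    best = 0
    tarr = cache.arr(gid)
    idx = cache.index(gid)
    for oriented in (read, revcomp(read)):
        rarr = _to_arr(oriented)
        for d in _diagonals(oriented, idx, cache.k):
            best = max(best, int(_match_array(tarr, d, rarr).sum()))
    return best


def prune_graph(
    graph: GeneGraph,
    genome: dict[str, str],
    params: DetectParams,
) -> GeneGraph:
    """Drop ambiguous encompassing pairs and weakly supported edges.

    Each supporting mate is re-aligned against both partner genes' spliced
    sequence; a pair is discarded when either mate matches the partner gene
    at least as well as its own (ambiguous origin, e.g. homologous genes).
    """
    cache = _GeneSeqCache(graph.nodes, genome, params.kmer)
    kept: dict[frozenset, EdgeSupport] = {}
    for key, support in graph.edges.items():
        a, b = tuple(key)
        if graph.nodes[a].chrom not in genome or graph.nodes[b].chrom not in genome:
            log.warning("gene sequence unavailable for edge %s-%s; edge dropped", a, b)
            continue
        surviving = EdgeSupport()
        for read_id, g1, g2, seq1, seq2 in support.pairs:
            ambiguous = False
            for gown, seq in ((g1, seq1), (g2, seq2)):
                if not seq:
                    continue
                gother = b if gown == a else a
                if _best_score(seq, cache, gother) >= _best_score(seq, cache, gown):
                    ambiguous = True
                    break
            if not ambiguous:
                surviving.pairs.append((read_id, g1, g2, seq1, seq2))
        if surviving.count >= params.min_encompassing_pairs:
            kept[key] = surviving
    return GeneGraph(nodes=graph.nodes, edges=kept)


# ---------------------------------------------------------------------------
# Spanning-read recovery
# ---------------------------------------------------------------------------

def _candidate_mates(records: Iterable[ReadPairRecord], min_clip: int):
    for rec in records:
        for mate_no, (mate, seq) in enumerate(
            ((rec.mate1, rec.sequence1), (rec.mate2, rec.sequence2)), 1
        ):
            if not seq:
                continue
            if (not mate.mapped) or mate.max_clip >= min_clip:
                yield f"{rec.read_id}/{mate_no}", seq


def map_spanning_reads(
    graph: GeneGraph,
    records: Iterable[ReadPairRecord],
    genome: dict[str, str],
    params: DetectParams,
) -> list[SplitAlignment]:
    """Split-align unmapped/soft-clipped reads across candidate gene pairs.

    A read is accepted for the junction that yields its unique best split:
    both segments at least ``min_segment_length``, total mismatches at most
    ``max_mismatches``.  Reads scoring equally well at two distinct
    junctions are rejected as ambiguous.
    """
    cache = _GeneSeqCache(graph.nodes, genome, params.kmer)
    edge_genes: set[str] = set()
    for key in graph.edges:
        edge_genes.update(key)
    ms = params.min_segment_length
    splits: list[SplitAlignment] = []

    for cand_id, seq in _candidate_mates(records, ms):
        R = len(seq)
        if R < 2 * ms:
            continue
        best_score = -1
        best_junctions: set[tuple] = set()
        best_detail = None
        for oriented in (seq, revcomp(seq)):
            rarr = _to_arr(oriented)
            hits: dict[str, list[int]] = {}
            for gid in edge_genes:
                diags = _diagonals(oriented, cache.index(gid), params.kmer)
                if diags:
                    hits[gid] = diags
            if len(hits) < 2:
                continue
            match_cache: dict[tuple[str, int], np.ndarray] = {}

            def prefix(gid: str, d: int) -> np.ndarray:
                key = (gid, d)
                if key not in match_cache:
                    m = _match_array(cache.arr(gid), d, rarr)
                    match_cache[key] = np.concatenate(([0], np.cumsum(m)))
                return match_cache[key]

            gene_list = sorted(hits)
            for gx in gene_list:
                for gy in gene_list:
                    if gx == gy or frozenset((gx, gy)) not in graph.edges:
                        continue
                    gene_x = graph.nodes[gx]
                    gene_y = graph.nodes[gy]
                    donor_bounds = set(gene_x.donor_boundaries())
                    acceptor_bounds = set(gene_y.acceptor_boundaries())
                    for dx in hits[gx]:
                        px = prefix(gx, dx)
                        for dy in hits[gy]:
                            py = prefix(gy, dy)
                            total_y = py[R]
                            scores = px[ms : R - ms + 1] + (total_y - py[ms : R - ms + 1])
                            score = int(scores.max())
                            if score < R - params.max_mismatches:
                                continue
                            # Sequence identity straddling the junction makes a
                            # plateau of equally scoring split points; prefer the
                            # one landing on annotated exon boundaries.
                            plateau = [ms + int(r) for r in np.flatnonzero(scores == score)]
                            best_i = None
                            best_bonus = -1
                            chosen = None
                            for i in plateau:
                                t_donor = dx + i - 1
                                t_acceptor = dy + i
                                if not (0 <= t_donor < gene_x.spliced_length):
                                    continue
                                if not (0 <= t_acceptor < gene_y.spliced_length):
                                    continue
                                dpos = gene_x.transcript_to_genomic(t_donor)
                                apos = gene_y.transcript_to_genomic(t_acceptor)
                                bonus = (dpos in donor_bounds) + (apos in acceptor_bounds)
                                if bonus > best_bonus:
                                    best_bonus = bonus
                                    best_i = i
                                    chosen = (dpos, apos)
                            if best_i is None:
                                continue
                            i = best_i
                            donor = Breakpoint(gene_x.chrom, chosen[0], gene_x.strand)
                            acceptor = Breakpoint(gene_y.chrom, chosen[1], gene_y.strand)
                            jkey = (gx, gy, donor.pos, acceptor.pos)
                            if score > best_score:
                                best_score = score
                                best_junctions = {jkey}
                                best_detail = (gx, gy, dx, dy, i, donor, acceptor, R - score)
                            elif score == best_score:
                                best_junctions.add(jkey)
        if best_detail is None or len(best_junctions) != 1:
            continue
        gx, gy, dx, dy, i, donor, acceptor, mism = best_detail
        gene_x, gene_y = graph.nodes[gx], graph.nodes[gy]
        g5a = gene_x.transcript_to_genomic(max(dx, 0))
        g5b = donor.pos
        g3a = acceptor.pos
        g3b = gene_y.transcript_to_genomic(min(dy + R, gene_y.spliced_length) - 1)
        splits.append(
            SplitAlignment(
                read_id=cand_id.rsplit("/", 1)[0],
                segment5=SplitSegment(
                    gx,
                    GenomicInterval(gene_x.chrom, min(g5a, g5b), max(g5a, g5b) + 1, gene_x.strand),
                    0,
                    i,
                ),
                segment3=SplitSegment(
                    gy,
                    GenomicInterval(gene_y.chrom, min(g3a, g3b), max(g3a, g3b) + 1, gene_y.strand),
                    i,
                    R,
                ),
                donor=donor,
                acceptor=acceptor,
                junction_offset_in_read=i,
                mismatches=mism,
            )
        )
    return splits


# ---------------------------------------------------------------------------
# Junction clustering
# ---------------------------------------------------------------------------

def _single_linkage(points: list[tuple[int, int]], window: int) -> list[int]:
    """Union-find single-linkage clustering under Chebyshev distance <= window."""
    n = len(points)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if (
                abs(points[i][0] - points[j][0]) <= window
                and abs(points[i][1] - points[j][1]) <= window
            ):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    return [find(i) for i in range(n)]


def _snap(pos: int, boundaries: list[int], window: int) -> tuple[int, bool]:
    if not boundaries:
        return pos, False
    nearest = min(boundaries, key=lambda b: (abs(b - pos), b))
    if abs(nearest - pos) <= window:
        return nearest, True
    return pos, False


def cluster_junctions(
    splits: Sequence[SplitAlignment],
    genes: dict[str, GeneModel] | Sequence[GeneModel],
    params: DetectParams,
    encompassing: Optional[dict[frozenset, int]] = None,
) -> list[JunctionCluster]:
    """Merge spanning reads agreeing within ``cluster_window`` into junction clusters.

    The representative coordinates are the modal (donor, acceptor) pair of
    the cluster, snapped to an annotated exon boundary when within the
    window (setting the canonical flags).
    """
    if not isinstance(genes, dict):
        genes = {g.gene_id: g for g in genes}
    grouped: dict[tuple[str, str], list[SplitAlignment]] = defaultdict(list)
    for sp in splits:
        grouped[(sp.segment5.gene_id, sp.segment3.gene_id)].append(sp)

    clusters: list[JunctionCluster] = []
    for (g5, g3), members in grouped.items():
        pts = [(sp.donor.pos, sp.acceptor.pos) for sp in members]
        labels = _single_linkage(pts, params.cluster_window)
        by_label: dict[int, list[SplitAlignment]] = defaultdict(list)
        for lab, sp in zip(labels, members):
            by_label[lab].append(sp)
        gene5, gene3 = genes[g5], genes[g3]
        for group in by_label.values():
            modal = Counter((sp.donor.pos, sp.acceptor.pos) for sp in group)
            top = max(modal.values())
            dpos, apos = min(p for p, c in modal.items() if c == top)
            dpos, canon_d = _snap(dpos, gene5.donor_boundaries(), params.cluster_window)
            apos, canon_a = _snap(apos, gene3.acceptor_boundaries(), params.cluster_window)
            enc = (encompassing or {}).get(frozenset((g5, g3)), 0)
            clusters.append(
                JunctionCluster(
                    donor=Breakpoint(gene5.chrom, dpos, gene5.strand),
                    acceptor=Breakpoint(gene3.chrom, apos, gene3.strand),
                    donor_gene=g5,
                    acceptor_gene=g3,
                    members=list(group),
                    encompassing_support=enc,
                    canonical_donor=canon_d,
                    canonical_acceptor=canon_a,
                )
            )
    clusters.sort(key=lambda c: (c.donor.chrom, c.donor.pos, c.acceptor.chrom, c.acceptor.pos))
    return clusters


# ---------------------------------------------------------------------------
# WGS corroboration
# ---------------------------------------------------------------------------

def _near_donor(m, bp: Breakpoint, window: int, slop: int = 10) -> bool:
    if not m.mapped or m.chrom != bp.chrom:
        return False
    if bp.strand == "+":
        return (not m.is_reverse) and bp.pos - window <= m.end <= bp.pos + slop
    return m.is_reverse and bp.pos - slop <= m.start <= bp.pos + window


def _near_acceptor(m, bp: Breakpoint, window: int, slop: int = 10) -> bool:
    if not m.mapped or m.chrom != bp.chrom:
        return False
    if bp.strand == "+":
        return m.is_reverse and bp.pos - slop <= m.start <= bp.pos + window
    return (not m.is_reverse) and bp.pos - window <= m.end <= bp.pos + slop


def _clip_near(m, pos: int, tol: int = 5, min_clip: int = 10) -> bool:
    if not m.mapped:
        return False
    if m.clip_left >= min_clip and abs(m.start - pos) <= tol:
        return True
    if m.clip_right >= min_clip and abs(m.end - 1 - pos) <= tol:
        return True
    return False


def resolve_wgs_support(
    clusters: Sequence[JunctionCluster],
    wgs_records: Optional[Iterable[ReadPairRecord]],
    params: DetectParams,
) -> list[JunctionCluster]:
    """Fill ``wgs_support`` from WGS discordant pairs and split reads.

    A no-op (all counts 0) when no WGS data is provided.  Support comes from
    discordant pairs whose mates flank the donor and acceptor breakpoints in
    junction-compatible orientation within ``wgs_window``, plus reads
    soft-clipped at the breakpoint itself.
    """
    clusters = list(clusters)
    if wgs_records is None:
        return clusters
    wgs = list(wgs_records)
    for cl in clusters:
        supporters: set[str] = set()
        for rec in wgs:
            pair_ok = False
            if rec.is_discordant:
                for md, ma in ((rec.mate1, rec.mate2), (rec.mate2, rec.mate1)):
                    if _near_donor(md, cl.donor, params.wgs_window) and _near_acceptor(
                        ma, cl.acceptor, params.wgs_window
                    ):
                        pair_ok = True
            split_ok = any(
                _clip_near(m, p)
                for m, p in (
                    (rec.mate1, cl.donor.pos), (rec.mate1, cl.acceptor.pos),
                    (rec.mate2, cl.donor.pos), (rec.mate2, cl.acceptor.pos),
                )
            )
            if pair_ok or split_ok:
                supporters.add(rec.read_id)
        cl.wgs_support = len(supporters)
    return clusters
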