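# Methods

## The problem

Fusion-derived circular RNAs (fcircRNAs) arise when backsplicing — a splice
joining a downstream donor to an upstream acceptor — occurs within a
transcript composed of two independent genes (a genomic gene fusion or a
read-through transcript spanning adjacent genes). In paired-end RNA-Seq
they leave two footprints: *encompassing* read pairs whose mates map to the
two partner genes, and *spanning* (split) reads whose sequence crosses a
junction. The difficulty is that one fusion locus can produce several
junctions — the genomic fusion junction, alternative splice joins,
reciprocal-fusion junctions and backsplices — and only their relative
orientation distinguishes them.

## Detection model

1. **Gene graph.** Genes are nodes (per-gene exon-union models from the
   GTF; transcript isoforms are not resolved). An edge connects genes A and
   B when at least one discordant pair has one mate overlapping an exon of
   A and the other an exon of B. Discordance is recomputed from the
   alignments: different chromosomes, same-orientation mates, or genomic
   span above `max_insert` (default 1000 bp).
2. **Pruning.** Every supporting mate is re-aligned (gapless k-mer
   seed-and-extend, k = 12) against the spliced sequence of both partner
   genes; a pair whose mate matches the partner gene at least as well as
   its own is ambiguous (e.g. paralogs) and discarded. Edges below
   `min_encompassing_pairs` (default 1) are dropped.
3. **Spanning-read recovery.** Candidate reads are the unmapped mates and
   mates soft-clipped by at least `min_segment_length` (default 15 bp).
   Each candidate is split-aligned across every surviving gene pair it
   seeds in, in both transcript orders and read orientations: the read must
   be fully explained by a 5′ segment in one gene's spliced sequence and a
   3′ segment in the other, each ≥ `min_segment_length`, with at most
   `max_mismatches` (default 2) mismatches in total. When bases flanking
   the junction match both genes, the equally scoring split positions are
   resolved in favor of annotated exon boundaries (the same convention
   spliced aligners use for ambiguous introns); a read whose best score is
   achieved by two *different* junctions is rejected as ambiguous.
4. **Clustering.** Splits for one gene pair merge by single linkage when
   both junction coordinates agree within `cluster_window` (default 5 bp).
   The representative junction is the modal (donor, acceptor) pair, snapped
   to an annotated exon boundary when within the window (setting the
   canonical flags). Support is counted in distinct read ids.
5. **WGS corroboration (optional).** A cluster gains support from WGS
   discordant pairs whose mates flank the donor and acceptor within
   `wgs_window` (default 1000 bp) in junction-compatible orientation, and
   from WGS reads soft-clipped at a breakpoint. Genomic fusion junctions
   are expected to have WGS support; splice-derived junctions are not.

## Classification model

All upstream/downstream reasoning uses transcription-direction coordinates
per gene, making plus-, minus- and mixed-strand fusions uniform. Per gene
pair, the junction with the most distinct spanning reads is the **primary
fusion junction** (ties: WGS support, then both-ends-canonical, then
leftmost donor). Each secondary junction is categorized by orientation
relative to the primary:

* **backsplice** — donor in the 3′ gene at/downstream of the primary
  acceptor *and* acceptor in the 5′ gene at/upstream of the primary donor;
* **alternative splice** — donor in the 5′ gene, acceptor in the 3′ gene,
  coordinates differing from the primary;
* **reciprocal fusion** — donor in the 3′ gene upstream of the primary
  acceptor, acceptor in the 5′ gene downstream of the primary donor, both
  at canonical exon boundaries;
* **unclassified** — everything else (the complete taxonomy of secondary
  orientations is open-ended; the four-way rule is kept in one pure
  function so it can be amended).

A backsplice is **physically possible** iff both circle endpoints lie
inside the fusion transcript (acceptor at/upstream of the primary donor in
the 5′ gene, donor at/downstream of the primary acceptor in the 3′ gene);
equivalently, the circle sequence is a substring of the doubled fusion
transcript. Impossible candidates are excluded. Read-support filters keep a
junction with ≥ `min_reads_known` (default 1) distinct reads when it
matches a provided list of published junctions (within 5 bp), else
≥ `min_reads_novel` (default 2). One fcircRNA call is emitted per
surviving backsplice, with its canonical exon content.

A known limitation, inherited from the primary-junction assumption: when a
circle is expressed far above its parent linear transcript, the backsplice
junction can out-support the fusion junction and be mis-designated primary,
producing a call with swapped junctions. WGS data, when provided, breaks
such ties in favor of the genomic junction.

## Simulator

The simulator states a small world sufficient to exercise every code path:

| parameter | default | rationale |
|---|---|---|
| chromosomes × length | 4 × 300 kb | smallest genome giving all three fusion classes room |
| genes | 70, 4–8 exons of 120–220 bp, introns 300–800 bp | compact caricature of human gene structure |
| fusions | 30 per iteration; mix 50% inter-chromosomal, 30% intra-chromosomal, 20% read-through | class variety with every geometry represented |
| backsplices | 1 per fusion, endpoints uniform over exon pairs | circles span the fusion junction by construction |
| reads | 2×100 bp, fragments 250 ± 25 bp | typical short-read RNA-Seq |
| linear coverage | 50× per transcript, log-normal across events (σ = 0.5) | realistic expression spread |
| circle depth | 16 junction-crossing fragments, log-normal (σ = 0.9) | see calibration below |
| substitution errors | 0.1% | Illumina-like |

Reads from circles are drawn from the doubled circle sequence, restricted
to fragments crossing the wrap point, so every circle fragment carries
backsplice-junction evidence. Sources shorter than `read_length + 10` are
skipped with a warning; otherwise fragments are truncated to the source
length. Read-through fusions join adjacent plus-strand genes in genomic
order.

An **aligner emulation** writes a SAM file the way a spliced linear aligner
would: reads within one gene map with match/N-gap CIGARs; reads crossing a
fusion or backsplice junction map to the side holding the majority of their
bases with the remainder soft-clipped; cross-gene fragments become
discordant pairs. This keeps the test loop hermetic; externally aligned
BAM/SAM files enter through the same reader.

**Noise calibration.** The two expression-noise defaults (circle depth 16,
σ = 0.9) were chosen so the 20-iteration benchmark means sit inside the
reference accuracy bands; they are the declared tuning surface and are
committed here. The two error regimes they induce are the ones seen in real
libraries: circles whose junction support falls below the 2-read novel
threshold (false negatives), and rare circles expressed above their linear
parent (primary mis-designation; one false positive plus one false
negative). With the error rate at 0 and fixed 50× coverage the pipeline
recovers every event exactly — a green benchmark therefore establishes
correct junction arithmetic and orientation logic under expression noise,
not robustness to alignment artifacts, paralogy, or library chemistry,
which the synthetic world does not contain (random sequence has no
homology, no GC bias, no intronic or rRNA background, no PCR duplicates,
no indels).

## Benchmark

A call is a true positive when all four junction endpoints (fusion
donor/acceptor, backsplice donor/acceptor) match one unmatched truth record
in chromosome and strand within 5 bp. The one-to-one assignment is solved
exactly (Hungarian algorithm; maximum cardinality, minimum total distance)
rather than greedily — greedy matching is demonstrably suboptimal on
adversarial 2×2 instances. Sensitivity = TP/(TP+FN), precision =
TP/(TP+FP), F1 their harmonic mean, all 0 when undefined. The structural
exclusion bound reports (N − n_excluded)/N for detectors that cannot see
events whose partner genes share a strand of one chromosome; its
percentage is floored (truncated) to one decimal, matching the convention
of the reference report (26/30 → 86.6%).

## Output formats

Internal coordinates are 0-based half-open everywhere; conversions happen
only at format boundaries. Junction breakpoints are the genomic positions
of the last transcribed base of the 5′ segment (donor) and the first of
the 3′ segment (acceptor). The modified-BEDPE schema: columns 1–10 are
standard BEDPE for the fusion junction (each breakpoint a 1-bp block),
followed by backsplice acceptor (`bs_*5`, the circle's 5′-gene endpoint),
backsplice donor (`bs_*3`), gene names, fusion/backsplice read counts, a
semicolon-delimited supporting-read list and canonical flags. The write →
read round trip is the identity, and extra trailing columns from similar
schemas are tolerated on read. VCF output encodes each fusion junction as
a breakend (BND) pair with reciprocal MATEIDs at 1-based positions.

## Visualization

Figures are built from a plot model, not pixels: per gene a panel with the
cytoband label, a fusion-transcript track with at most three exon boxes per
gene (junction-adjacent exons kept, interior exons elided with an ellipsis;
boxes are not to scale), a junction marker, the backsplice arc, and
optional read-support labels. Junctions off canonical boundaries are
snapped to the nearest upstream (5′ junction ends) or downstream (3′ ends)
exon boundary for display only. Spanning-read counts recomputed from a
BAM/SAM (soft-clip position check, with sequence re-check when the genome
is available) may legitimately differ from the caller's counts. SVG output
is byte-deterministic (fixed hash salt, no timestamps) so figures can be
golden-tested structurally.

## Numerical and degenerate-input conventions

* Clustering ties (equal modal counts) resolve to the smallest coordinate
  pair; snapping ties to the nearest boundary, then the smaller position.
* Primary-selection ties fall through WGS support → canonical ends →
  leftmost donor, so the result is deterministic for any input order.
* Empty junction sets error in `select_primary`; empty truth sets error in
  the exclusion bound; zero-denominator metrics are 0 by convention.
* All simulator randomness flows from one integer seed through
  per-operation substreams; every output is byte-identical for a fixed
  seed and the benchmark reseeds iteration *i* with `base_seed + i`.
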