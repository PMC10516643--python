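"""Detect fusions and fcircRNAs from a SAM file + GTF + FASTA.

Runs the detection stages explicitly -- gene graph from discordant pairs,
pruning by re-alignment, spanning-read split alignment, junction clustering,
primary-junction selection and backsplice classification -- on a freshly
simulated dataset, then prints every junction cluster with its annotation.
"""

import sys

from fcircseeker.formats import load_genome, read_gtf
from fcircseeker.pipeline import run_detection, simulate_dataset, write_outputs
from fcircseeker.simulate import SimConfig

out_dir = sys.argv[1] if len(sys.argv) > 1 else "detect_out"
ds = simulate_dataset(SimConfig(n_genes=20, n_fusions=5, seed=11), out_dir)

# read the annotation and genome back from disk, as an external caller would
genes = read_gtf(ds.gtf_path)
genome = load_genome(ds.fasta_path)
result = run_detection(ds.sam_path, genes, genome)
paths = write_outputs(result, out_dir, genome)

print(f"{len(result.candidates)} fusion candidates, {len(result.clusters)} junction clusters")
for cand in result.candidates:
    p = cand.primary
    print(f"  {cand.gene5.gene_id}::{cand.gene3.gene_id}  primary junction "
          f"{p.donor.chrom}:{p.donor.pos}({p.donor.strand}) -> "
          f"{p.acceptor.chrom}:{p.acceptor.pos}({p.acceptor.strand})  "
          f"spanning={p.support} encompassing={p.encompassing_support}")
print(f"{len(result.calls)} fcircRNA calls (backsplice with >=2 independent reads, "
      "physically possible within the fusion transcript)")
for c in result.calls:
    print(f"  circ{c.gene5}::{c.gene3}  backsplice {c.backsplice.donor.pos} -> "
          f"{c.backsplice.acceptor.pos}  reads={c.backsplice_reads}  "
          f"exons_in_circle={len(c.exons_in_circle)}")
print(f"outputs: {paths['bedpe']}, {paths['tsv']}, {paths['vcf']}")
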