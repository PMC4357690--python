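"""Design ranked knock-in scenarios for every projection of one gene.

A scenario pairs an exon-spanning arm (>=20 b margins beyond both borders)
with a flanking arm within 700 b on one side: left-arm:span-arm (LS) or
span-arm:right-arm (SR).  Ranking prefers small gaps between the arms, a
split point close to the exon border, and long cumulative homology; at most
five scenarios per category are kept after near-duplicates are collapsed.
"""

import armkit as ak
from armkit.pipeline import design_gene

cfg = ak.SimConfig(seed=42, chrom_length=120_000, n_genes=5, repeat_density=0.2)
sim = ak.simulate(cfg, "example_out/sim")
gms = ak.parse_ccds(sim.table_path)
seqs = ak.SequenceStore(sim.fasta_path)

gene_id = gms.gene_ids()[0]
design = design_gene(gms, seqs, gene_id, ak.DesignParams(npp=10))
print(f"gene {gene_id}: {len(design.knockin)} knock-in scenarios")
for s in design.knockin:
    print(
        f"  exon {s.exon_start}-{s.exon_end} {s.category} rank {s.rank}: "
        f"gap {s.gap} b, split {s.split_distance} b from the exon border, "
        f"arms {s.flank_arm.length}+{s.span_arm.length} b"
    )
ak.export(design.knockin, "tsv", "example_out/knockin.tsv")
print("wrote example_out/knockin.tsv")
# gap = bases replaced by the selection cassette between the two arms;
# split = distance from the integration junction to the target exon border.
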