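"""Design knock-out scenarios and link complementary stop-codon knock-ins.

Only exons present in every transcript variant with length not divisible by
3 are eligible.  Partial deletions put both split points inside the exon;
whole-exon excision (exons <= 700 b) removes the exon with >20 b margins.
Exons without a deletion design may still be knocked out by introducing a
premature stop codon through one of their knock-in scenarios.
"""

import armkit as ak
from armkit.pipeline import design_gene

cfg = ak.SimConfig(seed=42, chrom_length=120_000, n_genes=5, repeat_density=0.2)
sim = ak.simulate(cfg, "example_out/sim")
gms = ak.parse_ccds(sim.table_path)
seqs = ak.SequenceStore(sim.fasta_path)

for gene_id in gms.gene_ids()[:2]:
    design = design_gene(gms, seqs, gene_id, ak.DesignParams(npp=10))
    eligible = ak.knockout_eligible_exons(gms, gene_id)
    print(f"gene {gene_id}: {len(eligible)} eligible exons, "
          f"{len(design.knockout)} deletion scenarios")
    for s in design.knockout:
        print(
            f"  exon {s.exon_start}-{s.exon_end} {s.mode} rank {s.rank}: "
            f"gap {s.gap} b (gap mod 3 = {s.gap_mod3}), arms "
            f"{s.left_arm.length}+{s.right_arm.length} b"
        )
    for exon_iv, comp in design.complementary.items():
        print(
            f"  exon {exon_iv[0]}-{exon_iv[1]}: "
            f"{len(comp)} complementary stop-codon knock-in option(s)"
        )
# gap mod 3 != 0 marks deletions that shift the reading frame by themselves.
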