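"""Generate a synthetic genome + annotation and build the exon databases.

Creates a 120 kb soft-masked chromosome with 5 multi-transcript genes, parses
the CCDS-style table, and prints the per-gene unique-exon and projection
counts.  Unique exons collapse coordinate-identical exons across transcript
variants; projections merge overlapping unique exons to their outermost
boundaries and are the unit of knock-in design.
"""

import armkit as ak

cfg = ak.SimConfig(seed=42, chrom_length=120_000, n_genes=5, repeat_density=0.2)
sim = ak.simulate(cfg, "example_out/sim")
gms = ak.parse_ccds(sim.table_path)

print(
    f"parsed {gms.n_transcripts} Public transcripts, {gms.n_genes} genes, "
    f"{gms.n_exons} exon records"
)
print(f"masked fraction of the chromosome: {sim.truth['realized_repeat_fraction']:.3f}")
for gid in gms.gene_ids():
    unique = ak.compress_exons(gms, gid)
    projections = ak.project_exons(gms, gid)
    eligible = ak.knockout_eligible_exons(gms, gid)
    print(
        f"gene {gid}: {gms.transcript_count(gid)} transcripts, "
        f"{len(unique)} unique exons -> {len(projections)} projections, "
        f"{len(eligible)} knock-out-eligible exons"
    )
# A projection count below the unique-exon count means transcript variants
# with overlapping (but not identical) exon coordinates were merged.
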