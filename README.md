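# armkit

Design of rAAV (recombinant adeno-associated virus) homology-arm gene-targeting
constructs for protein-coding exons.

rAAV-mediated homologous recombination edits human somatic-cell genomes with
single-base precision, but every targeting construct needs two *homology arms* —
PCR products of 700–1200 bp flanking the intended edit — chosen under a stack of
empirical design rules: arms must amplify cleanly, contain ≤25% repeat-derived
sequence, sit close together (the gap between them is replaced by the selection
cassette), and for knock-ins the integration junction must stay clear of splice
sites of *every* transcript variant of the gene. armkit automates this end to
end for users planning knock-in (point mutation) or knock-out (deletion /
premature stop) experiments:

1. **Gene models** — a CCDS-style annotation table is parsed (status-`Public`
   records with a GeneID); coordinate-identical exons of a gene are compressed
   into *unique exons*, and overlapping unique exons are merged to their
   outermost boundaries into *exon projections*, the unit of knock-in design.
2. **Arm database** — each projection ± 3 kb of soft-masked genomic sequence is
   tiled with sliding windows (size `SW`=1300, step `SS`=50); a primer engine
   proposes up to `NPP`=50 pairs per window in each 50 bp product-size bin from
   700 to 1200 bp. Pairs survive three filters: no primer base in a repeat
   (lowercase) or `N`, no mononucleotide run >3 in a primer, and ≤25% repeat
   content in the product. The shipped engine scores primers by SantaLucia
   nearest-neighbor melting temperature, GC and length deviations; any engine
   honoring the same contract (e.g. a Primer3 wrapper) can be plugged in.
3. **Scenario design** — knock-in: an exon-*spanning* arm (≥20 b margins) plus
   a flanking arm within 700 b on either side (categories LS and SR); knock-out
   (only for exons present in all transcript variants with length ∤ 3): partial
   deletion with both split points inside the exon, or whole-exon excision for
   exons ≤700 b. Arms are clustered by DBSCAN (Chebyshev metric on product
   endpoints), matched cluster-against-cluster, screened (gap < 700 b, no exon
   in the gap, no arm terminus inside another exon), ranked — smaller gap,
   split point closer to the exon border, longer cumulative homology — and
   deduplicated through a similarity graph (arms within 5 b at both ends), with
   at most 5 scenarios per category (10 per exon).
4. **Export** — TSV/JSON/BED scenario reports and attB-tailed amplification
   primers for Gateway BP/LR cloning of the arms into entry and destination
   vectors.

A deterministic synthetic-data generator (`armkit.fixtures`) emits soft-masked
genomes and multi-transcript CCDS-dialect annotation with a ground-truth
record, so the whole pipeline runs and is tested without any download.

## Worked example

```python
import armkit as ak
from armkit.pipeline import design_gene

cfg = ak.SimConfig(seed=42, chrom_length=120_000, n_genes=5, repeat_density=0.2)
sim = ak.simulate(cfg, "example_out/sim")
gms = ak.parse_ccds(sim.table_path)
seqs = ak.SequenceStore(sim.fasta_path)
design = design_gene(gms, seqs, 1000, ak.DesignParams(npp=10))
for s in design.knockin[:3]:
    print(f"exon {s.exon_start}-{s.exon_end} {s.category} rank {s.rank}: "
          f"gap {s.gap} b, split {s.split_distance} b, "
          f"arms {s.flank_arm.length}+{s.span_arm.length} b")
```

prints

```
exon 6067-6257 LS rank 1: gap 0 b, split 508 b from the exon border, arms 901+1160 b
exon 6067-6257 LS rank 2: gap 0 b, split 548 b from the exon border, arms 1177+1188 b
exon 6067-6257 LS rank 3: gap 1 b, split 821 b from the exon border, arms 1053+1127 b
```

— the best left-arm:span-arm design for this exon has its two arms directly
adjacent (gap 0, nothing deleted on integration), its cassette junction 508 b
from the exon border, and 2061 b of total homology. `ak.tail_primers(s)`
yields the four attB-tailed primers that amplify the two arms for Gateway
cloning. The scripts in `examples/` walk through each stage the same way; the
same pipeline is available from the shell via the `armkit` CLI
(`simulate`, `build-db`, `design-arms`, `coverage-stats`, `design-knockin`,
`design-knockout`, `export`).

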