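# Methods

## Problem and model

armkit designs homologous-recombination targeting constructs for rAAV
(recombinant adeno-associated virus) editing of protein-coding exons. A
construct carries two homology arms (HAs) of 700–1200 bp amplified from the
target locus; the selection cassette integrates at the junction between the
arms (the *split point*), and whatever genomic sequence lies between the arms
(the *gap*) is replaced by the cassette. The design problem is combinatorial:
enumerate arm candidates that will PCR cleanly and recombine efficiently, then
choose arm *pairs* whose geometry respects splicing and maximizes targeting
efficiency.

The empirical rules encoded throughout the package are: arms must avoid
genomic repeats in their primers and carry at most 25% repeat sequence overall
(repeats both impair PCR specificity and reduce recombination fidelity); the
gap between arms should be small (integration efficiency falls with cassette
distance from homology); for knock-ins the probability of retaining the edit
decays with distance between the split point and the edited base, so the
junction should sit close to the target exon; and cumulative homology length
helps, so longer arm pairs are preferred at equal gap/split geometry.

## Gene models

The annotation input is the CCDS tab-separated dialect. Only records with
status exactly `Public` and an integer GeneID are used; records whose
`cds_locations` is `-` or whose GeneID is missing are skipped with a warning
(matching the real file's withdrawn-style rows), while syntactically broken
interval lists in kept records raise with the line number. `cds_locations`
intervals are read as 0-based with inclusive ends (length = to − from + 1) and
held internally as 0-based half-open — the convention of every coordinate in
the package and of the BED exports.

Two derived stores drive the designers:

* **unique exons** — per gene, exons with identical (chrom, start, end) across
  transcript variants are compressed into one record holding the union of
  contributing CCDS accessions. Single-transcript genes trivially have every
  exon "present in all transcript forms".
* **exon projections** — transitively overlapping unique exons merged to their
  outermost coordinates. Editing within a projection (with the span-arm
  margins below) cannot disturb a splice boundary of any variant. The
  projection's *commonality* is recorded as the count of transcripts
  containing at least one member exon (a count, not a fraction).

Knock-out *eligibility* = present in all transcript variants AND length not
divisible by 3 (exon skipping cannot restore the frame). It is decided from
the annotation alone; the genome is never consulted.

## Sequence access and repeats

The genome is a soft-masked FASTA read through pyfaidx; lowercase marks
repeat-derived bases. Hard-masked `N` runs are treated as repeat *and* as
forbidden primer positions. Repeat fraction = (lowercase + `N`) / length, and
is invariant under reverse complement. Target regions are the focus feature
± 3000 bp, clipped (not erroring) at chromosome ends so terminal exons with
truncated flanks remain designable.

## Arm generation

Each target region is tiled with sliding windows of `SW` = 1300 bp at step
`SS` = 50 bp; window offsets run 0, SS, 2·SS, … while a full window fits, plus
one final window anchored at the region end when a remainder exists (so region
tails are never systematically uncovered); a region shorter than SW is a
single whole-region window. SW exceeds the largest product (1200 bp) yet stays
below twice the smallest (1400 bp), limiting redundant re-design of small
products while leaving primer placement freedom.

Per window, the primer engine is asked for up to `NPP` = 50 pairs in each of
ten product-size bins tiling 700–1200 bp in 50 bp steps ([700,750), …,
[1150,1200] — bin boundaries are a package choice; the range and increment are
the design constraint). Candidate pairs then pass three filters:

1. no primer nucleotide on a masked (lowercase) or `N` base;
2. no mononucleotide run longer than 3 in either primer, checked on the primer
   as synthesized (run lengths are invariant under reverse complement);
3. product repeat fraction ≤ 0.25, boundary inclusive (25.0% passes).

Arms identical in the genomic coordinate quadruple of their two primers are
deduplicated globally (across windows, bins and regions), keeping the lowest
penalty; coordinates rather than sequences are compared so engine case
differences cannot split duplicates. Per-gene stores are written as sorted
TSV with fixed float formatting, making byte-level reproducibility directly
checkable.

### The built-in primer engine

Primer design is a plug-in contract (window sequence, size range, pair budget
→ scored pairs). The shipped `ThermoEngine` is deterministic and
dependency-free: every (start, length) candidate with length 18–30 nt is
scored vectorized via dinucleotide enthalpy/entropy prefix sums using the
SantaLucia (1998) unified nearest-neighbor parameters, with terminal
initiation corrections, entropic salt correction (0.368·(N−1)·ln[Na⁺],
Na⁺ = 50 mM) and total strand concentration 50 nM. The single-primer penalty
is |Tm − 60 °C| + 0.3·|len − 20| + 0.05·|GC% − 50|; a pair adds
0.5·|ΔTm|. Per position the best forward (by start) and reverse (by end)
candidate is kept, and per size bin the exact top-NPP pairs under the total
order (penalty, forward start, reverse end) are returned — computed by
partitioning on penalty and lexicographically sorting the candidates at or
below the cutoff, so results are identical across runs and platforms and the
top-k lists are nested in k. The engine's agreement with an independent
nearest-neighbor implementation is part of the test suite. An external engine
such as Primer3 can be substituted behind the same contract; the design
constraints (size bins, primer length bounds, no `N` accepted) are the same
ones such engines take natively.

Two exact monotonicity properties follow from this construction and are
exercised as tests: window sets at nested step sizes are nested (aligned
offsets plus the anchored tail window), so sequence coverage is non-decreasing
as SS shrinks; and top-k nesting makes coverage depth non-decreasing in NPP.

## Clustering and matching

Candidate arms are embedded as points (product start, product end) and
clustered with DBSCAN under the Chebyshev metric (two arms are eps-neighbors
iff both endpoints differ by ≤ eps), harmonizing with the 5 bp end-tolerance
similarity rule used later. Defaults eps = 50 (one step size) and
min_pts = 1 — with min_pts = 1 there are no noise points, and the partition
equals the connected components of the eps-neighbor graph, hence is
independent of input order. Both knobs are configuration-exposed and logged.
scikit-learn's DBSCAN provides the implementation; tests compare it against a
brute-force density-reachability oracle.

Knock-in matching, per projection: span arms must cover the exon with ≥20 b
beyond each border (boundary inclusive: exactly 20 qualifies); flank arms sit
within 700 b of the span arm's end on one side, gap strictly < 700 and never
negative (overlapping arm pairs are rejected). A candidate scenario is
screened out if any other exon of the gene overlaps the gap interval, or if
any arm terminus falls strictly inside another exon of the gene (the target
exon is legitimately covered by the span arm; exons of *other* genes are not
consulted). For every (span cluster × flank cluster) pair, all member
combinations are screened (vectorized as broadcast comparisons over member
coordinate arrays) and exactly the best survivor per cluster pair is kept.

Ranking is the lexicographic order (gap ascending, split distance ascending,
cumulative arm length descending, genomic start ascending as a deterministic
tie-break). The split point is defined as the junction between the gap and
the span arm — the cassette inserts between the arms, and this junction is
the point whose distance to the target exon border bounds how far the edit
can sit from the integration site. Split distance is therefore ≥ 20 by the
span-margin construction.

Scenarios sharing an identical arm, or whose corresponding arms (flank↔flank,
span↔span) both differ by ≤ 5 b at each end, are connected in an undirected
graph (networkx); only the best scenario per connected component survives,
and at most 5 per category (LS, SR) — 10 per exon — are emitted with ranks.

Knock-out designs reuse the same machinery with mode-specific screens:
*partial deletion* requires the left arm's end and the right arm's start
strictly inside the exon (split points inside the exon) with 0 ≤ gap < 700;
*whole-exon excision* is attempted only for exons ≤ 700 b, with margins
strictly greater than 20 b on each side (so the deletion exceeds the exon by
> 20 b both ways; the ≥-vs-> reading differs by one base and is configurable
via the margin parameter) and inner arm ends within 700 b of the exon
borders. Per cluster pair the smallest-gap design survives; ranking drops the
split-distance term (gap ascending, cumulative length descending). The
deleted segment's length mod 3 is reported in the exports but *not* filtered
on — a frame-preserving internal deletion may still be the user's intent.
Exons of genes with one transcript use the plain exon store directly. First
or last exon status is not down-weighted; the exon ordinal is left to user
judgment. Knock-in scenarios overlapping an eligible exon are additionally
flagged as complementary stop-codon knock-out options.

## attB tailing and exports

Amplification primers for each arm are the stored genomic primers with an
attB tail prepended — pure concatenation, so stripping the configured tail
recovers the stored primer byte-identically. The shipped defaults are the
canonical Gateway attB1/attB2 (arm 1 → pDONR P1-P2) and attB3/attB4 (arm 2)
sequences and are explicitly user-replaceable configuration, since donor
vector families differ. Scenario exports: TSV (lossless round-trip, floats
serialized with `repr`), JSON, and BED (0-based half-open; one record per arm
plus one for the gap/deletion interval; names encode gene, exon, category and
rank).

## Synthetic data

The generator emulates the statistical structure of the real inputs: genes
laid sequentially on one chromosome with log-normal exon lengths (median
~120 b, the scale of real coding exons, clipped to 30–800 b), uniform introns
of 0.3–2.5 kb, 1–3 transcripts per gene whose variant exons are kept (p=0.7),
boundary-shifted by up to 30 b (p=0.2) or dropped (p=0.1) relative to the
canonical chain; non-Public decoy records at 15%; base composition at GC 0.41;
and independent geometric repeat tracts (mean 300 b) placed until the
requested masked density (default 0.2) is reached, overlaps merging
naturally. All randomness flows from a single seed; identical seeds yield
byte-identical FASTA, table and truth JSON.

What the generator does *not* model: real repeat families and their sequence
composition, splice-site motifs, GC isochores, strand asymmetries, assembly
gaps, and genes overlapping other genes. Tests passing on synthetic data
therefore demonstrate algorithmic correctness (counts, screens, ranking,
reproducibility) — not that arm yields or coverage percentages match any
particular genome and masking library, which depend on the engine version and
the repeat annotation used.

Three hand-built micro fixtures (≤ 20 kb) pin down oracle comparisons:
`one-gene-knockin` (unmasked, one two-transcript gene, a 100 b shared target
exon with the only other exon far outside the design window),
`ko-eligible` (exon lengths 100 shared / 99 shared / 100 private, so exactly
one exon is eligible), and `all-masked` (fully lowercase chromosome, zero
arms by construction).

## Verification strategy and problem sizes

* Brute-force oracles: textbook DBSCAN with density reachability; exhaustive
  enumeration of all valid arm pairs with independent scoring, union-find
  similarity grouping and ranking. When hand-placed arms are pairwise farther
  than eps apart, every cluster is a singleton and the heuristic must equal
  the oracle exactly; on engine-generated stores the heuristic's rank-1
  scenario must equal the global brute-force optimum and every emitted
  scenario must be a valid pair (the cluster pre-selection may legitimately
  replace lower ranks with near-equivalents — it prunes within clusters of
  near-identical arms before global ranking).
* The melting-temperature model is cross-checked against an independent
  nearest-neighbor implementation (Biopython's, same parameter set) to
  0.01 °C.
* Parameter-trend checks run on a simulated 200 kb chromosome (3 genes,
  15% repeat density): SS ∈ {100, 50, 25} at NPP = 5 for coverage, and
  NPP ∈ {5, 10, 25, 50} at SS = 100 for depth. Because the properties are
  exact (nested window sets, nested top-k), small NPP/SS crosses do not
  weaken them; the sizes keep the default suite fast.
* `scripts/acceptance.py` re-runs everything at the standard parameters
  (SW = 1300, SS = 50, NPP = 50) on a 200 kb / 8-gene / 20%-repeat instance
  and reports annotation totals, arm counts, coverage and scenario
  statistics; all quantities are computed at run time from the seeded
  simulation.

## Known limitations

* The cluster–cluster pre-selection can, by design, drop a globally top-5
  scenario that exhaustive search would keep; the emitted alternatives come
  from distinct arm clusters and rank-1 is provably preserved.
* No thermodynamic dimer/hairpin screening beyond the engine's scoring; no
  mutagenesis-primer design for introducing the point mutation itself.
* Overlapping genes are not considered in the exclusion screens (only the
  target gene's own exons are).
* Masking is an input property; no on-the-fly repeat annotation. Coverage and
  yield figures are therefore only comparable between runs sharing a masking
  source.
* Scenario counts at genome scale depend on the primer engine's candidate
  ordering; different engines honoring the same contract will produce
  differently sized (though similarly structured) databases.
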