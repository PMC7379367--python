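# drjkit

Direct-repeat-junction (DRJ) discovery and excision-breakpoint analysis
for endogenous polydnavirus loci.

Parasitoid wasps that carry ichnoviruses keep the viral genome integrated
in their own chromosomes as *proviral segments*: stretches of viral
sequence delimited by a **direct repeated sequence (DRJ)** present at both
ends (and sometimes in extra internal copies, or as a second, unrelated
repeat family). In the wasp ovary each segment is excised and circularized
by homologous recombination between two DRJ copies; the circle carries a
single *recombined* DRJ — a hybrid that matches the right parental copy
(DRJR) up to the crossover and the left copy (DRJL) after it. Because the
two parental copies differ at many positions (~85% identity is typical),
reads sequenced from the circles reveal *where* the crossover happened.

`drjkit` implements that analysis end to end, for people studying segment
excision or any analogous direct-repeat-mediated circularization:

- **discovery** — find the repeat copies delimiting an annotated locus,
  group them into families (DRJ1, DRJ2, ... by position), measure copy-pair
  identity, and enumerate the circles each family can generate (a family
  with *c* copies yields *c*(*c*−1)/2 nested/overlapping products);
- **mapping** — a self-contained seed-and-extend mapper that aligns
  circularized-molecule reads to the genome and extracts
  read–DRJL–DRJR *triplets*: reads whose alignments cover a full
  recombined DRJ plus unique flanking sequence on both sides;
- **segmentation** — the breakpoint caller. Each informative alignment
  column (where the parents differ) votes +1 (read matches the DRJR
  allele) or −1 (DRJL allele); a piecewise-constant function with two
  changepoints is fitted to this punctual-difference signal, partitioning
  the window into DRJR-homology / breakpoint region / DRJL-homology.
  Formally it minimizes over 0 ≤ k₁ ≤ k₂ ≤ m

      SSE(k₁,k₂) = Σ_seg Σ_{i∈seg} (sᵢ − μ_seg)² ,

  with ties broken by narrowest middle segment, then leftmost. The
  breakpoint region is the interval between the last DRJR-supporting site
  and the first DRJL-supporting site;
- **aggregation** — per-DRJ-pair, per-position read support of excision
  sites in the left-copy frame (each read supports every position its
  region spans);
- **motif statistics** — overlapping k-mer window counts and a Pearson
  chi-square (1 df, no continuity correction) for motif enrichment in
  DRJs versus genome background;
- **simulator** — a truth-tracked generator of scaffolds with embedded
  proviral loci (diverged DRJ copies, optional internal copies and second
  families), excised circles with known crossovers, and error-bearing
  reads, so the whole stack is testable without any external data.

## Worked example

`examples/` holds one short script per capability. For instance,
`python examples/aggregate_breakpoint_distribution.py` simulates one locus
with a 300 bp DRJ pair whose crossovers are drawn from a peak mid-repeat,
calls a breakpoint per read and aggregates:

```
reads: 120, ok calls: 120, no_informative: 0
left copy frame: 2544-2844
modal support 30 at 2692-2701 (true crossover peak near 2694)
total support mass 1104 = sum of ok-region widths
```

The modal window (scaffold positions 2692–2701, supported by 30 reads)
brackets the true crossover peak at 2694, and total coverage mass equals
the summed widths of all called regions exactly — the aggregation
conserves evidence. `examples/call_excision_breakpoints.py` shows the
per-read view (every error-free call contains the true crossover), and
`examples/discover_repeat_families.py` the repeat-architecture census.

## Command line

The same pipeline is scriptable from a shell, one subcommand per stage,
each consuming the previous stage's TSV:

```
drjkit simulate    --seed 42 --out-dir sim/
drjkit find-drjs   --genome sim/genome.fasta --loci sim/loci.bed --out drjs.tsv
drjkit find-triplets --genome sim/genome.fasta --drjs drjs.tsv \
                     --reads sim/reads.fasta --out triplets.tsv
drjkit breakpoints --triplets triplets.tsv --genome sim/genome.fasta \
                   --drjs drjs.tsv --out calls.tsv
drjkit aggregate   --calls calls.tsv --genome sim/genome.fasta \
                   --drjs drjs.tsv --out summary.tsv --profiles-dir profiles/
drjkit motif-test  --drj-fasta drjs.fasta --genome sim/genome.fasta \
                   --motif NNGCTN --k 6 --out motif_report.tsv
```

Every run writes a JSON provenance record (version, parameters, input
checksums) next to its outputs.

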