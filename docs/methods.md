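# Methods

## Coordinate and alignment conventions

All intervals are 0-based half-open on the forward strand; BED is the
native interchange format and any 1-based table dialect is converted at
parse time. One affine-gap scoring scheme is used everywhere (match +2,
mismatch −3, gap open −5, gap extend −2, so a length-*g* gap costs
5 + 2*g*), via `Bio.Align.PairwiseAligner`. `N` never scores as a match,
not even against another `N`, so masked sequence cannot anchor an
alignment. Percent identity is always *matching columns / all alignment
columns*, counting terminal and internal gap columns against identity —
a conservative, end-to-end definition suited to comparing full repeat
copies.

## Repeat (DRJ) discovery

A proviral locus is searched for a direct repeat shared by its two ends:
the first and last `window_bp` (default 1500) are locally aligned, and a
hit is accepted if both copies are at least `min_repeat_len` (50 bp) at
`min_identity_pct` (75%) or better. Three refinements make this robust
on realistic architectures:

1. **Composite splitting.** When two distinct repeat families sit a
   short spacer apart, one local alignment can bridge
   repeat–spacer–repeat against repeat–spacer–repeat. The bridged spacer
   aligns unrelated sequence, which the affine aligner can only make
   look similar by spending gaps; a sustained (≥20-column), gap-bearing
   stretch of low smoothed column score therefore splits the alignment,
   and each side is considered separately.
2. **Iterative re-anchoring.** The chosen repeat is re-aligned inside
   padded regions around itself (padding 300 bp per round, up to 8
   rounds, chunks matched across rounds by overlap), so a copy truncated
   by the end window grows to its full extent.
3. **Boundary re-estimation.** Copy ends are finally placed by an
   explicit changepoint decision on the positional match series of the
   two copies: inside the repeat, columns match with probability ≈ 0.86
   (at the default 15% divergence), outside ≈ 0.25, giving per-column
   log-likelihood ratios of +1.232 (match) and −1.657 (mismatch). Under
   a flat prior, the boundary posterior is proportional to the
   exponentiated cumulative LLR; the boundary is placed to maximize the
   posterior mass within ±5 bp (the Bayes decision for a "within 5 bp"
   loss), scanning ±80 bp around the alignment end, with edge-padding so
   a boundary at the scan limit is not repelled. This is noticeably more
   robust to chance mutation clusters at a genuine repeat end than the
   raw maximum-likelihood changepoint.

Additional families are found by masking every accepted copy with `N`
and repeating the terminal search anchored on the unmasked extent (the
first/last clean 20-mer). A new repeat joins an existing family when a
local alignment of the two consensi reaches `family_link_identity_pct`
(80%) over at least 60% of the shorter one (containment linkage, so a
partially recovered copy still merges). Families are labelled DRJ1,
DRJ2, ... by leftmost copy. Internal copies are found by iterative
best-local-alignment of the family consensus against the locus interior
with masking between rounds. Loci whose ends carry no acceptable repeat
are reported as "no-DRJ", not as errors.

Circle enumeration is purely combinatorial: one prediction per ordered
same-family copy pair, sequence = the scaffold interval between the two
copy starts rotated body-first (beginning at the base after the left
copy), so a family with *c* copies yields *c*(*c*−1)/2 nested products
and two interleaved families yield overlapping circles.

## Read mapping and triplet extraction

The mapper is a deterministic exact-seed (k = 15) / affine-extend local
aligner over both strands; a read's orientation is fixed once (the
strand with more seed hits; reverse reads are reverse-complemented and
processed on plus, which suffices because DRJs are direct repeats).
Chimeric junction reads produce two alignments, one on each side of the
locus.

A read is junction evidence for a DRJ pair only if one alignment covers
`flank_bp` (20 bp) of unique sequence *preceding the right copy* and
runs into it, another runs out of the left copy through the `flank_bp`
*following it*, and the union of read intervals covers the whole window
between those projections. This excludes reads lying inside a single
copy, which carry no recombination signal. The covered window
(recombined DRJ ± flank) is then re-aligned globally to each parental
context (copy ± flank on the scaffold), producing the triplet. A read
satisfying the test for several pairs (possible with nested families)
is emitted for each, flagged ambiguous.

## Breakpoint segmentation

The two context alignments are merged on window coordinates. A column
is *informative* when both parents carry (different) bases and the read
matches exactly one of them: +1 for the DRJR allele, −1 for DRJL.
Columns with a gap, an `N`, or a read base matching neither parent are
excluded; columns where the parents agree carry no signal. Restricting
the fit to informative sites makes the clean-signal optimum coincide
with the interval between the two flanking mismatches.

`fit_two_changepoints` minimizes the residual sum of squares of a
3-segment piecewise-constant fit over all 0 ≤ k₁ ≤ k₂ ≤ m. Ties are
broken by smallest middle width, then smallest k₁. Internally a
vectorised float screen shortlists near-optimal candidates and the
winner is decided in exact integer rational arithmetic, so the result
equals exhaustive search bit-for-bit, independent of float rounding.
A call is `ok` only with ≥2 informative sites, at least one site in each
outer segment, and valid orientation (mean of segment 1 strictly above
segment 3, compared exactly: the circle's hybrid runs DRJR → DRJL);
otherwise the status records the failure mode (`no_informative`,
`no_switch`, `inconsistent_orientation`). The region is the half-open
window interval (last segment-1 site, first segment-3 site], projected
into both parental copies and clipped to their spans.

## Aggregation

Per DRJ pair, each `ok` call adds 1 to every left-copy position its
region spans (interval evidence; a midpoint-only mode exists behind a
flag). Total support mass therefore equals the summed region widths
exactly, and aggregation is invariant to call order. Summaries report
the modal position(s) — ties as an interval — plus per-status read
tallies; profiles are two-column TSVs (position, support) per pair, with
optional cosmetic PNGs.

## Motif statistics

Window counts are overlapping k-windows (default k = 6) on the forward
strand (both-strand mode behind a flag); windows containing `N` are
excluded. Query motifs may carry IUPAC degeneracy (sequence `N` matches
nothing). Enrichment uses the Pearson chi-square on the 2×2 table
[motif, other] × [DRJ, genome], 1 df, no continuity correction (counts
in the intended use are in the 10⁴–10⁸ range); the odds ratio gets a
Haldane +0.5 correction, flagged, when a cell is zero. When several
motifs are tested the CLI prints the Bonferroni factor but does not
adjust.

## Simulator

`simulate_genome` draws i.i.d. uniform background sequence and embeds
non-overlapping loci of the form DRJL–body–DRJR. Both copies derive from
one ancestral repeat by independent per-base substitution at rate
`drj_divergence/2` each, so expected pairwise identity ≈ 1 − divergence;
the default 0.15 reproduces the ~85% copy identity typical of these
repeats. Defaults: bodies 2–18 kb and repeats 69–1132 bp (the observed
segment and repeat size ranges), a second unrelated family in 40% of
loci (arranged F1L–F2L–body–F1R–F2R with 100–400 bp spacers, yielding
two overlapping circles) and an internal copy in 10% — frequencies
matching the published census of such loci. `simulate_circles` samples
a crossover *x* per circle (uniform over the gapless homologous
coordinate system by default, or truncated normal) and emits
body + DRJR[0..x) + DRJL[x..). `simulate_reads` samples start positions
uniformly around the circle (wrap-around), lengths 200–900 bp
(454/Sanger-like), substitution errors at 0.005/bp by default, and a
random strand; `junction_only` mode instead guarantees every read spans
the hybrid DRJ plus a 30 bp unique margin. Everything is reproducible
from one seed, and the truth tables (copy coordinates, crossovers,
per-read geometry) let every downstream stage be scored exactly.

What the simulator does *not* emulate: indel divergence between copies
(substitution-only by design — the breakpoint signal is defined on
punctual differences; indels are exercised only through alignment
machinery), homopolymer-type sequencing error profiles, quality scores,
paired ends, repeat families outside the planted DRJs, and circle
reintegration. Passing tests therefore demonstrate correctness of the
method's logic and its calibration under substitution divergence, not
robustness to structurally messy assemblies.

## Problem sizes and numerical choices

The validation suite uses desk-scale problem sizes chosen to exercise
every regime: 1000 random ±1 signals of up to 300 sites for the
segmentation-vs-brute-force equivalence; 20 loci × 50 junction reads per
circle (at error 0 and 0.005) for breakpoint truth containment; 100
loci for repeat-architecture recovery; 50 replicate loci for the
identity calibration. Determinism: all randomness flows from explicit
seeds; alignment, fitting and tie-breaking are deterministic by
construction.

## Known limitations

- **Boundary localization at 85% identity is partly irreducible.** The
  first/last bases of a repeat copy pair are ambiguous whenever a chance
  mutation cluster sits at the end: an oracle experiment that starts
  from the *true* boundary and applies the optimal changepoint decision
  still misplaces at least one terminal boundary by >5 bp in ~10–15% of
  simulated loci at 15% divergence. The discovery pipeline performs at
  that statistical limit (~90% of loci within ±5 bp); claims of finer
  accuracy at this divergence would be overfitting to luck.
- Reads mapping equally well to two nested DRJ pairs are emitted for
  both and flagged ambiguous rather than resolved; downstream users
  should filter on the flag when nested families are present.
- The mapper targets hundreds-of-bp reads on desk-scale references; it
  is not engineered for long reads or gigabase genomes.
- `pair_identity` reports one optimal global alignment; among co-optimal
  alignments the reported identity is the aligner's deterministic first
  choice.
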