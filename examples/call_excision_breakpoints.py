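"""Localize excision breakpoints from reads of circularized molecules.

Simulates circles excised from proviral segments (each with a known
crossover position inside the homologous repeat tract), samples
junction-spanning reads, maps them back to the genome, extracts
read-DRJL-DRJR triplets, and fits the two-changepoint segmentation to
call a breakpoint region per read.  The printed check shows that with
error-free reads every called region brackets the true crossover.
"""

from drjkit import MapParams, SimConfig, call_breakpoint, find_triplets
from drjkit.discovery import RepeatCopy, pair_from_copies
from drjkit.simulate import simulate_dataset

cfg = SimConfig(seed=11, n_loci=3, n_scaffolds=1, scaffold_len_bp=60_000,
                body_len_range=(2_500, 4_000), drj_len_range=(150, 400),
                drj_divergence=0.15, p_second_family=0.0, p_internal_copy=0.0,
                circles_per_pair=2, reads_per_circle=5, junction_only=True,
                read_error_rate=0.0, p_reverse_read=0.5)
scaffolds, loci, circles, reads, truth = simulate_dataset(cfg)
by_id = {s.id: s for s in scaffolds}

# terminal DRJ pairs (here taken from simulator truth; see
# discover_repeat_families.py for finding them de novo)
pairs, locus_scaffold = [], {}
for lt in truth.loci:
    seq = by_id[lt.scaffold_id].sequence
    left, right = lt.copies[0], lt.copies[-1]
    pairs.append(pair_from_copies(
        RepeatCopy(lt.name, "DRJ1", left.start, left.end, "left",
                   seq[left.start:left.end]),
        RepeatCopy(lt.name, "DRJ1", right.start, right.end, "right",
                   seq[right.start:right.end])))
    locus_scaffold[lt.name] = lt.scaffold_id

triplets = find_triplets(reads, scaffolds, pairs, MapParams(), locus_scaffold)
read_truth = {r.read_id: r for r in truth.reads}

n_ok = n_contain = 0
for t in triplets[:8]:
    call = call_breakpoint(t)
    x = read_truth[t.read_id].crossover_read_pos - t.window_start
    lo, hi = call.region_window
    hit = call.status == "ok" and lo < x <= hi
    print(f"{t.read_id:28s} status={call.status:4s} "
          f"region=({lo},{hi}] true_crossover={x} "
          f"support R/L={call.n_support_R}/{call.n_support_L} "
          f"{'contains truth' if hit else ''}")
for t in triplets:
    call = call_breakpoint(t)
    if call.status == "ok":
        n_ok += 1
        x = read_truth[t.read_id].crossover_read_pos - t.window_start
        n_contain += call.region_window[0] < x <= call.region_window[1]
print(f"\n{n_ok} breakpoint calls, {n_contain} contain the true crossover "
      f"({100 * n_contain / n_ok:.1f}%)")

# The region (lo, hi] is the interval between the last read position
# supporting the right parental copy and the first supporting the left
# one: the crossover of the recombined DRJ must lie inside it.
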