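import numpy as np
import pytest

from drjkit._align import revcomp
from drjkit.simulate import SimConfig, simulate_circles, simulate_dataset, simulate_genome


def small_cfg(**kw):
    base = dict(seed=5, n_loci=2, n_scaffolds=1, scaffold_len_bp=40000,
                body_len_range=(2000, 3000), drj_len_range=(100, 200),
                circles_per_pair=1, reads_per_circle=4, p_second_family=0.0,
                p_internal_copy=0.0, read_error_rate=0.0, p_reverse_read=0.0)
    base.update(kw)
    return SimConfig(**base)


class TestSimulateGenome:
    def test_zero_divergence_identical_copies(self):
        scafs, loci, truth = simulate_genome(small_cfg(drj_divergence=0.0))
        seq = scafs[0].sequence
        for lt in truth.loci:
            l, r = lt.copies[0], lt.copies[-1]
            assert seq[l.start : l.end] == seq[r.start : r.end]

    def test_truth_consistent_with_fasta(self):
        scafs, loci, truth = simulate_genome(small_cfg())
        by_id = {s.id: s for s in scafs}
        for locus, lt in zip(loci, truth.loci):
            assert (locus.start, locus.end) == (lt.start, lt.end)
            seq = by_id[lt.scaffold_id].sequence
            # every copy has the ancestral length (substitution-only)
            for c in lt.copies:
                assert c.end - c.start == len(lt.ancestors[c.family])
                assert set(seq[c.start : c.end]) <= set("ACGT")

    def test_deterministic_under_seed(self):
        a = simulate_genome(small_cfg())
        b = simulate_genome(small_cfg())
        assert [s.sequence for s in a[0]] == [s.sequence for s in b[0]]
        assert a[2].loci == b[2].loci

    def test_seeds_differ(self):
        a = simulate_genome(small_cfg())
        b = simulate_genome(small_cfg(seed=6))
        assert a[0][0].sequence != b[0][0].sequence

    def test_divergence_calibration(self):
        # emitted pair identity ~ 100*(1 - divergence) within binomial noise
        idents = []
        for seed in range(10):
            cfg = small_cfg(seed=seed, drj_divergence=0.15,
                            drj_len_range=(800, 1000))
            scafs, loci, truth = simulate_genome(cfg)
            seq = scafs[0].sequence
            for lt in truth.loci:
                l, r = lt.copies[0], lt.copies[-1]
                a, b = seq[l.start : l.end], seq[r.start : r.end]
                idents.append(100 * sum(x == y for x, y in zip(a, b)) / len(a))
        assert abs(np.mean(idents) - 85.0) < 3.0

    def test_impossible_placement_raises(self):
        with pytest.raises(ValueError, match="scaffold_len_bp"):
            simulate_genome(small_cfg(scaffold_len_bp=3000))


class TestSimulateCircles:
    def test_boundary_crossovers(self):
        scafs, loci, truth = simulate_genome(small_cfg(drj_divergence=0.2))
        seq = scafs[0].sequence
        lt = truth.loci[0]
        left, right = lt.copies[0], lt.copies[-1]
        lseq, rseq = seq[left.start : left.end], seq[right.start : right.end]
        body = seq[left.end : right.start]
        cfg = small_cfg(drj_divergence=0.2)
        circles, truth2 = simulate_circles(scafs, truth, cfg)
        for circ, ct in zip(circles, truth2.circles):
            if ct.locus != lt.name:
                continue
            hybrid = circ.sequence[ct.body_len :]
            # hybrid = DRJR[:x] + DRJL[x:], checked site by site
            assert hybrid == rseq[: ct.crossover] + lseq[ct.crossover :]
            assert circ.sequence[: ct.body_len] == body

    def test_uniform_crossover_distribution_ks(self):
        cfg = small_cfg(seed=13, n_loci=1, circles_per_pair=1000,
                        body_len_range=(2000, 2000), drj_len_range=(200, 200))
        scafs, loci, truth = simulate_genome(cfg)
        circles, truth = simulate_circles(scafs, truth, cfg)
        xs = np.array([c.crossover for c in truth.circles], dtype=float)
        # randomized PIT: x uniform on {0..200} + U(0,1) jitter is U(0, 201)
        jit = np.random.default_rng(0).uniform(0, 1, xs.size)
        from scipy import stats

        p = stats.kstest((xs + jit) / 201.0, "uniform").pvalue
        assert p > 0.01

    def test_normal_crossover_clipped_and_centered(self):
        cfg = small_cfg(seed=14, n_loci=1, circles_per_pair=300,
                        drj_len_range=(200, 200),
                        crossover_dist=("normal", 0.5, 10.0))
        scafs, loci, truth = simulate_genome(cfg)
        circles, truth = simulate_circles(scafs, truth, cfg)
        xs = np.array([c.crossover for c in truth.circles])
        assert xs.min() >= 0 and xs.max() <= 200
        assert abs(xs.mean() - 100) < 3
        assert 7 < xs.std() < 13

    def test_circle_length_equals_copy_start_distance(self):
        scafs, loci, truth = simulate_genome(small_cfg())
        cfg = small_cfg()
        circles, truth2 = simulate_circles(scafs, truth, cfg)
        for ct in truth2.circles:
            assert ct.length == ct.right_start - ct.left_start


class TestSimulateReads:
    def test_reads_derive_from_circles(self):
        scafs, loci, circles, reads, truth = simulate_dataset(small_cfg())
        by_id = {c.circle_id: c for c in truth.circles}
        circ_by_id = {c.id: c for c in circles}
        for read, rt in zip(reads, truth.reads):
            circ = circ_by_id[rt.circle_id].sequence
            doubled = circ + circ
            expect = doubled[rt.start : rt.start + rt.length]
            got = revcomp(read.sequence) if rt.is_reverse else read.sequence
            assert got == expect  # error rate 0: byte-exact

    def test_junction_only_reads_span_hybrid(self):
        cfg = small_cfg(junction_only=True, reads_per_circle=10)
        scafs, loci, circles, reads, truth = simulate_dataset(cfg)
        assert truth.reads
        assert all(rt.spans_junction for rt in truth.reads)
        assert all(rt.crossover_read_pos is not None for rt in truth.reads)

    def test_junction_fraction_matches_geometry(self):
        # P(random read spans DRJ +/- margin) ~ (len - drj - 2*margin)/circle
        cfg = small_cfg(seed=11, n_loci=1, reads_per_circle=1000,
                        read_len_range=(500, 500), drj_len_range=(150, 150),
                        body_len_range=(2500, 2500), junction_margin=30)
        scafs, loci, circles, reads, truth = simulate_dataset(cfg)
        ct = truth.circles[0]
        expected = (500 - ct.drj_len - 2 * 30 + 1) / ct.length
        observed = np.mean([rt.spans_junction for rt in truth.reads])
        assert observed == pytest.approx(expected, abs=0.03)

    def test_error_rate_applied(self):
        cfg = small_cfg(read_error_rate=0.02, reads_per_circle=50)
        *_, truth = simulate_dataset(cfg)
        total = sum(rt.n_errors for rt in truth.reads)
        bases = sum(rt.length for rt in truth.reads)
        assert 0.01 < total / bases < 0.03

    def test_dataset_deterministic(self):
        a = simulate_dataset(small_cfg(p_reverse_read=0.5, read_error_rate=0.01))
        b = simulate_dataset(small_cfg(p_reverse_read=0.5, read_error_rate=0.01))
        assert [r.sequence for r in a[3]] == [r.sequence for r in b[3]]
        assert a[4].reads == b[4].reads
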