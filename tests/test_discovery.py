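import numpy as np
import pytest

from drjkit.discovery import (
    DiscoveryParams,
    discover_all_families,
    enumerate_circles,
    find_family_copies,
    find_terminal_repeats,
    pair_identity,
)
from drjkit.io import ProviralLocus, Scaffold

BASES = np.array(list("ACGT"))


def rand_seq(rng, n):
    return "".join(rng.choice(BASES, n))


def mutate(rng, seq, n_subs):
    """Plant exactly n_subs substitutions at distinct interior positions."""
    pos = rng.choice(np.arange(2, len(seq) - 2), size=n_subs, replace=False)
    out = list(seq)
    for i in pos:
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def nw_identity(a, b, match=2, mismatch=-3, gap_open=-5, gap_extend=-2):
    """Tiny independent global-alignment oracle: affine-gap DP, returns
    percent identity over all alignment columns."""
    na, nb = len(a), len(b)
    NEG = -10**9
    M = [[NEG] * (nb + 1) for _ in range(na + 1)]  # end in match/mismatch
    X = [[NEG] * (nb + 1) for _ in range(na + 1)]  # gap in b
    Y = [[NEG] * (nb + 1) for _ in range(na + 1)]  # gap in a
    M[0][0] = 0
    for i in range(1, na + 1):
        X[i][0] = gap_open + gap_extend * i
    for j in range(1, nb + 1):
        Y[0][j] = gap_open + gap_extend * j
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open + gap_extend,
                          X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open + gap_extend,
                          Y[i][j - 1] + gap_extend)
    # traceback counting matches and columns
    i, j = na, nb
    state = max(("M", M[i][j]), ("X", X[i][j]), ("Y", Y[i][j]),
                key=lambda t: t[1])[0]
    matches = cols = 0
    while i > 0 or j > 0:
        cols += 1
        if state == "M":
            s = match if a[i - 1] == b[j - 1] else mismatch
            matches += a[i - 1] == b[j - 1]
            prev = max(("M", M[i - 1][j - 1]), ("X", X[i - 1][j - 1]),
                       ("Y", Y[i - 1][j - 1]), key=lambda t: t[1])[0]
            i, j, state = i - 1, j - 1, prev
        elif state == "X":
            state = "M" if M[i - 1][j] + gap_open + gap_extend >= \
                X[i - 1][j] + gap_extend else "X"
            i -= 1
        else:
            state = "M" if M[i][j - 1] + gap_open + gap_extend >= \
                Y[i][j - 1] + gap_extend else "Y"
            j -= 1
        if i == 0 and j == 0:
            break
    return 100.0 * matches / cols


class TestPairIdentity:
    def test_identical(self, rng):
        s = rand_seq(rng, 100)
        assert pair_identity(s, s) == 100.0

    def test_single_mismatch_by_hand(self):
        assert pair_identity("ACGTACGT", "ACGAACGT") == 87.5  # 7/8

    def test_terminal_gaps_count(self, rng):
        a = rand_seq(rng, 80)
        assert pair_identity(a, a + rand_seq(rng, 10)) == round(
            100 * 80 / 90, 1
        )

    def test_matches_independent_nw_oracle(self, rng):
        for _ in range(5):
            a = rand_seq(rng, 60)
            b = mutate(rng, a, 8)
            assert pair_identity(a, b) == round(nw_identity(a, b), 1)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(5):
            a, b = rand_seq(rng, 50), rand_seq(rng, 55)
            ab = pair_identity(a, b)
            assert ab == pair_identity(b, a)
            assert 0 <= ab < 100

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pair_identity("", "ACGT")


def locus_with(rng, parts, pad=0):
    """Assemble a scaffold holding one locus made of the given parts."""
    lead = rand_seq(rng, 500 + pad)
    locus_seq = "".join(parts)
    tail = rand_seq(rng, 500)
    scaffold = Scaffold("s1", lead + locus_seq + tail)
    locus = ProviralLocus("LocT", "s1", len(lead), len(lead) + len(locus_seq))
    return scaffold, locus


class TestFindTerminalRepeats:
    def test_exact_copies_found_at_ends(self, rng):
        r = rand_seq(rng, 120)
        scaffold, locus = locus_with(rng, [r, rand_seq(rng, 5000), r])
        pair = find_terminal_repeats(locus, scaffold)
        assert pair is not None
        assert pair.identity_pct == 100.0
        assert (pair.left.start - locus.start, pair.left.end - locus.start) == (0, 120)
        assert (pair.right.start - locus.start, pair.right.end - locus.start) == (
            len(locus) - 120, len(locus))

    def test_diverged_copy_identity_equals_nw_oracle(self, rng):
        r = rand_seq(rng, 120)
        r2 = mutate(rng, r, 18)
        scaffold, locus = locus_with(rng, [r, rand_seq(rng, 5000), r2])
        pair = find_terminal_repeats(locus, scaffold)
        assert pair is not None
        # substitution-only divergence: the optimal global alignment is
        # gapless, identity = 102/120
        assert pair.identity_pct == 85.0
        assert pair.identity_pct == round(nw_identity(r, r2), 1)

    def test_unrelated_ends_give_none(self, rng):
        scaffold, locus = locus_with(rng, [rand_seq(rng, 5000)])
        assert find_terminal_repeats(locus, scaffold) is None

    def test_short_locus_rejected(self, rng):
        scaffold = Scaffold("s1", rand_seq(rng, 500))
        locus = ProviralLocus("L", "s1", 10, 90)
        with pytest.raises(ValueError):
            find_terminal_repeats(locus, scaffold,
                                  DiscoveryParams(min_repeat_len=50))


class TestFamilyCopies:
    def test_planted_internal_copy_recovered(self, rng):
        r = rand_seq(rng, 150)
        internal = mutate(rng, r, 12)
        scaffold, locus = locus_with(
            rng, [r, rand_seq(rng, 2000), internal, rand_seq(rng, 2000), r]
        )
        pair = find_terminal_repeats(locus, scaffold)
        copies = find_family_copies(locus, scaffold, pair)
        assert [c.role for c in copies] == ["left", "internal", "right"]
        mid = copies[1]
        true_start = locus.start + 150 + 2000
        assert abs(mid.start - true_start) <= 5
        assert abs(mid.end - (true_start + 150)) <= 5

    def test_no_internal_copy(self, rng):
        r = rand_seq(rng, 150)
        scaffold, locus = locus_with(rng, [r, rand_seq(rng, 3000), r])
        pair = find_terminal_repeats(locus, scaffold)
        assert [c.role for c in find_family_copies(locus, scaffold, pair)] == [
            "left", "right"]

    def test_low_identity_internal_not_reported(self, rng):
        r = rand_seq(rng, 150)
        decoy = mutate(rng, r, 60)  # ~60% identity, below the 75% default
        scaffold, locus = locus_with(
            rng, [r, rand_seq(rng, 2000), decoy, rand_seq(rng, 2000), r]
        )
        pair = find_terminal_repeats(locus, scaffold)
        copies = find_family_copies(locus, scaffold, pair)
        assert len(copies) == 2


class TestFamiliesAndCircles:
    def _two_family_locus(self, rng):
        f1 = rand_seq(rng, 300)
        f2 = rand_seq(rng, 250)
        parts = [f1, rand_seq(rng, 200), f2, rand_seq(rng, 4000),
                 mutate(rng, f1, 30), rand_seq(rng, 200), mutate(rng, f2, 25)]
        return locus_with(rng, parts)

    def test_two_interleaved_families_found(self, rng):
        scaffold, locus = self._two_family_locus(rng)
        families = discover_all_families(locus, scaffold)
        assert [f.label for f in families] == ["DRJ1", "DRJ2"]
        assert [len(f.copies) for f in families] == [2, 2]
        # families never merge: cross-family identity is far below the
        # link threshold
        assert pair_identity(families[0].copies[0].sequence,
                             families[1].copies[0].sequence) < 80.0

    def test_two_families_give_two_overlapping_circles(self, rng):
        scaffold, locus = self._two_family_locus(rng)
        families = discover_all_families(locus, scaffold)
        circles = enumerate_circles(locus, scaffold, families)
        assert len(circles) == 2
        spans = sorted((c.left_copy.start, c.right_copy.start) for c in circles)
        assert spans[0][1] > spans[1][0]  # overlapping products

    def test_single_family(self, rng):
        r = rand_seq(rng, 200)
        scaffold, locus = locus_with(rng, [r, rand_seq(rng, 3000), r])
        families = discover_all_families(locus, scaffold)
        assert len(families) == 1

    def test_three_copies_three_circles(self, rng):
        r = rand_seq(rng, 150)
        scaffold, locus = locus_with(
            rng, [r, rand_seq(rng, 2000), mutate(rng, r, 10),
                  rand_seq(rng, 2000), r]
        )
        families = discover_all_families(locus, scaffold)
        assert [len(f.copies) for f in families] == [3]
        circles = enumerate_circles(locus, scaffold, families)
        assert len(circles) == 3  # C(3,2)

    def test_circle_geometry(self, rng):
        r = rand_seq(rng, 120)
        body = rand_seq(rng, 3000)
        scaffold, locus = locus_with(rng, [r, body, r])
        families = discover_all_families(locus, scaffold)
        (circle,) = enumerate_circles(locus, scaffold, families)
        left, right = circle.left_copy, circle.right_copy
        assert circle.predicted_length == right.start - left.start
        # body-first rotation: sequence begins right after the left copy
        assert circle.predicted_sequence == (
            scaffold.sequence[left.end : right.start]
            + scaffold.sequence[left.start : left.end]
        )
        assert len(circle.predicted_sequence) == circle.predicted_length
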