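"""Synthetic provirus genomes, excised circles, and circle-sequencing reads.

The generator emulates the architecture of endogenous ichnovirus loci: a
proviral segment is a body flanked by two copies of a direct repeat (DRJ),
both derived from one ancestral repeat by independent per-base substitution
(rate drj_divergence/2 each, so the expected pairwise copy identity is
about 1 - drj_divergence; 0.15 reproduces the ~85% identity typical of
these repeats).  Loci may carry an extra internal copy and/or a second,
unrelated repeat family arranged so that the two families generate
overlapping circles.  A circle excised between two copies is the
inter-copy sequence (body-first) followed by a hybrid DRJ: the right copy
up to the crossover x, the left copy after it.  Reads are sampled around
the circle (wrap-around) with substitution errors.

Everything is reproducible from a single seed, and a full truth table
(locus placements, copy coordinates, crossovers, per-read geometry) is
returned so downstream modules can be validated without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._align import revcomp
from .io import CircleRead, ProviralLocus, Scaffold

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    seed: int
    n_scaffolds: int = 2
    scaffold_len_bp: int = 150_000
    n_loci: int = 4
    body_len_range: tuple[int, int] = (2_000, 18_000)
    drj_len_range: tuple[int, int] = (69, 1_132)
    drj_divergence: float = 0.15
    p_internal_copy: float = 0.10
    p_second_family: float = 0.40
    crossover_dist: tuple = ("uniform",)  # or ("normal", center_frac, sd_bp)
    circles_per_pair: int = 3
    reads_per_circle: int = 20
    read_len_range: tuple[int, int] = (200, 900)
    read_error_rate: float = 0.005
    p_reverse_read: float = 0.5
    junction_only: bool = False
    junction_margin: int = 30  # guaranteed unique flank on junction reads

    def __post_init__(self):
        for lo, hi in (self.body_len_range, self.drj_len_range, self.read_len_range):
            if lo > hi or lo < 1:
                raise ValueError("invalid range")
        for p in (self.drj_divergence, self.p_internal_copy,
                  self.p_second_family, self.read_error_rate,
                  self.p_reverse_read):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass(frozen=True)
class CopyTruth:
    family: str
    start: int  # scaffold coordinates
    end: int
    role: str


@dataclass(frozen=True)
class LocusTruth:
    name: str
    scaffold_id: str
    start: int
    end: int
    copies: tuple[CopyTruth, ...]
    ancestors: dict[str, str] = field(hash=False)


@dataclass(frozen=True)
class CircleTruth:
    circle_id: str
    locus: str
    family: str
    left_start: int
    left_end: int
    right_start: int
    right_end: int
    crossover: int  # homologous (ancestral) coordinate, 0..drj_len
    body_len: int
    drj_len: int
    length: int


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    circle_id: str
    start: int  # forward position on the circle
    length: int
    is_reverse: bool
    spans_junction: bool
    crossover_read_pos: int | None  # forward-orientation read coordinate
    n_errors: int


@dataclass
class SimTruth:
    loci: list[LocusTruth]
    circles: list[CircleTruth] = field(default_factory=list)
    reads: list[ReadTruth] = field(default_factory=list)


def _rand_seq(rng, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _mutate(rng, seq: str, rate: float) -> tuple[str, int]:
    """Independent per-base substitution to a uniformly different base."""
    if rate <= 0 or not seq:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode(), int(hit.size)


def _rngs(seed: int):
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(3)]


def simulate_genome(config: SimConfig):
    """Build scaffolds with embedded proviral loci.

    Returns (scaffolds, loci, SimTruth).  Single-family layout is
    DRJL-body-DRJR (optionally with one internal copy inside the body);
    two-family layout is F1L-F2L-body-F1R-F2R, which yields two
    overlapping circles.  Loci never overlap; placement failure raises.
    """
    rng = _rngs(config.seed)[0]
    scaffolds: list[Scaffold] = []
    loci: list[ProviralLocus] = []
    truths: list[LocusTruth] = []
    cursors = [0] * config.n_scaffolds
    parts: list[list[str]] = [[] for _ in range(config.n_scaffolds)]

    for li in range(config.n_loci):
        si = li % config.n_scaffolds
        name = f"Loc{li + 1}"
        d = config.drj_divergence / 2.0
        n_fam = 2 if rng.random() < config.p_second_family else 1
        ancestors = {}
        fam_copies = {}
        for fi in range(n_fam):
            label = f"DRJ{fi + 1}"
            anc_len = int(rng.integers(config.drj_len_range[0],
                                       config.drj_len_range[1] + 1))
            anc = _rand_seq(rng, anc_len)
            ancestors[label] = anc
            left, _ = _mutate(rng, anc, d)
            right, _ = _mutate(rng, anc, d)
            fam_copies[label] = [left, right]
        body_len = int(rng.integers(config.body_len_range[0],
                                    config.body_len_range[1] + 1))
        internal = None
        if n_fam == 1 and rng.random() < config.p_internal_copy:
            internal, _ = _mutate(rng, ancestors["DRJ1"], d)

        # assemble the locus and record copy offsets (locus-local)
        pieces: list[str] = []
        copies: list[tuple[str, int, int, str]] = []  # family, start, end, role
        pos = 0

        def put(seq: str):
            nonlocal pos
            pieces.append(seq)
            pos += len(seq)

        def put_copy(family: str, seq: str, role: str):
            copies.append((family, pos, pos + len(seq), role))
            put(seq)

        if n_fam == 1:
            put_copy("DRJ1", fam_copies["DRJ1"][0], "left")
            if internal is not None:
                cut = body_len // 2
                put(_rand_seq(rng, cut))
                put_copy("DRJ1", internal, "internal")
                put(_rand_seq(rng, body_len - cut))
            else:
                put(_rand_seq(rng, body_len))
            put_copy("DRJ1", fam_copies["DRJ1"][1], "right")
        else:
            put_copy("DRJ1", fam_copies["DRJ1"][0], "left")
            put(_rand_seq(rng, int(rng.integers(100, 401))))
            put_copy("DRJ2", fam_copies["DRJ2"][0], "left")
            put(_rand_seq(rng, body_len))
            put_copy("DRJ1", fam_copies["DRJ1"][1], "right")
            put(_rand_seq(rng, int(rng.integers(100, 401))))
            put_copy("DRJ2", fam_copies["DRJ2"][1], "right")
        locus_seq = "".join(pieces)

        gap = int(rng.integers(1_000, 3_001))
        start = cursors[si] + gap
        end = start + len(locus_seq)
        if end > config.scaffold_len_bp:
            raise ValueError(
                f"cannot place locus {name} on scaffold {si + 1} without "
                f"exceeding scaffold_len_bp; increase scaffold_len_bp or "
                f"reduce n_loci/body sizes"
            )
        parts[si].append(_rand_seq(rng, gap))
        parts[si].append(locus_seq)
        cursors[si] = end
        sc_id = f"scf{si + 1}"
        loci.append(ProviralLocus(name=name, scaffold_id=sc_id,
                                  start=start, end=end))
        truths.append(
            LocusTruth(
                name=name,
                scaffold_id=sc_id,
                start=start,
                end=end,
                copies=tuple(
                    CopyTruth(fam, start + s, start + e, role)
                    for fam, s, e, role in copies
                ),
                ancestors=ancestors,
            )
        )

    for si in range(config.n_scaffolds):
        tail = config.scaffold_len_bp - cursors[si]
        parts[si].append(_rand_seq(rng, tail))
        scaffolds.append(Scaffold(id=f"scf{si + 1}", sequence="".join(parts[si])))
    return scaffolds, loci, SimTruth(loci=truths)


def _sample_crossover(rng, dist: tuple, drj_len: int) -> int:
    if dist[0] == "uniform":
        return int(rng.integers(0, drj_len + 1))
    if dist[0] == "normal":
        _, center_frac, sd_bp = dist
        center = center_frac * drj_len
        for _ in range(1000):
            x = int(round(rng.normal(center, sd_bp)))
            if 0 <= x <= drj_len:
                return x
        return int(np.clip(round(center), 0, drj_len))
    raise ValueError(f"unknown crossover distribution {dist[0]!r}")


def simulate_circles(scaffolds, truth: SimTruth, config: SimConfig):
    """Excise circles from every same-family copy pair of every locus.

    Circle = scaffold[left.end, right.start) + right_copy[0:x) +
    left_copy[x:], with crossover x drawn from crossover_dist on the
    gapless homologous coordinate system (copies are substitution-derived,
    so both have the ancestral length).
    """
    rng = _rngs(config.seed)[1]
    by_id = {s.id: s for s in scaffolds}
    circles: list[CircleRead] = []
    for lt in truth.loci:
        seq = by_id[lt.scaffold_id].sequence
        families: dict[str, list[CopyTruth]] = {}
        for c in lt.copies:
            families.setdefault(c.family, []).append(c)
        for fam, copies in sorted(families.items()):
            copies = sorted(copies, key=lambda c: c.start)
            if len(copies) < 2:
                continue
            for i in range(len(copies)):
                for j in range(i + 1, len(copies)):
                    left, right = copies[i], copies[j]
                    left_seq = seq[left.start : left.end]
                    right_seq = seq[right.start : right.end]
                    drj_len = len(left_seq)
                    body = seq[left.end : right.start]
                    for n in range(config.circles_per_pair):
                        x = _sample_crossover(rng, config.crossover_dist, drj_len)
                        circ = body + right_seq[:x] + left_seq[x:]
                        cid = f"{lt.name}_{fam}_{i}{j}_c{n}"
                        circles.append(CircleRead(id=cid, sequence=circ))
                        truth.circles.append(
                            CircleTruth(
                                circle_id=cid,
                                locus=lt.name,
                                family=fam,
                                left_start=left.start,
                                left_end=left.end,
                                right_start=right.start,
                                right_end=right.end,
                                crossover=x,
                                body_len=len(body),
                                drj_len=drj_len,
                                length=len(circ),
                            )
                        )
    return circles, truth


def simulate_reads(circles, truth: SimTruth, config: SimConfig):
    """Sample error-bearing reads around each circle (wrap-around).

    With junction_only=True the start and length are chosen so every read
    covers the hybrid DRJ plus junction_margin of unique sequence on both
    sides.  Truth records forward-circle geometry; reverse reads are
    emitted reverse-complemented.
    """
    rng = _rngs(config.seed)[2]
    ct_by_id = {c.circle_id: c for c in truth.circles}
    reads: list[CircleRead] = []
    margin = config.junction_margin
    for circle in circles:
        ct = ct_by_id[circle.id]
        L = ct.length
        doubled = circle.sequence + circle.sequence
        for n in range(config.reads_per_circle):
            rl = int(rng.integers(config.read_len_range[0],
                                  config.read_len_range[1] + 1))
            if config.junction_only:
                rl = max(rl, ct.drj_len + 2 * margin + 2)
            rl = min(rl, L)
            if config.junction_only:
                if rl < ct.drj_len + 2 * margin:
                    continue  # circle DRJ too long to span at this length
                offset = int(rng.integers(margin, rl - ct.drj_len - margin + 1))
                a = (ct.body_len - offset) % L
            else:
                a = int(rng.integers(0, L))
            fwd = doubled[a : a + rl]
            seq, n_err = _mutate(rng, fwd, config.read_error_rate)
            is_rev = bool(rng.random() < config.p_reverse_read)
            offset_h = (ct.body_len - a) % L
            spans = margin <= offset_h and offset_h + ct.drj_len + margin <= rl
            cross_pos = offset_h + ct.crossover if spans else None
            rid = f"{circle.id}_r{n}"
            reads.append(
                CircleRead(id=rid, sequence=revcomp(seq) if is_rev else seq)
            )
            truth.reads.append(
                ReadTruth(
                    read_id=rid,
                    circle_id=circle.id,
                    start=a,
                    length=rl,
                    is_reverse=is_rev,
                    spans_junction=spans,
                    crossover_read_pos=cross_pos,
                    n_errors=n_err,
                )
            )
    return reads, truth


def simulate_dataset(config: SimConfig):
    """Genome + circles + reads + truth in one call."""
    scaffolds, loci, truth = simulate_genome(config)
    circles, truth = simulate_circles(scaffolds, truth, config)
    reads, truth = simulate_reads(circles, truth, config)
    return scaffolds, loci, circles, reads, truth
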