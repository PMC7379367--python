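"""k-mer motif occurrence and chi-square enrichment versus genome background.

Tests whether a candidate excision motif is over-represented in DRJ
sequences relative to all overlapping k-windows of the genome, using a
Pearson chi-square on the 2x2 table [motif, other] x [DRJ, genome] with no
continuity correction (counts in the intended use are large).  Windows are
counted on the forward strand by default; windows containing N are
excluded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy import stats

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class MotifConfig:
    k: int = 6
    strands: str = "forward"  # forward | both

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.strands not in ("forward", "both"):
            raise ValueError("strands must be 'forward' or 'both'")


@dataclass(frozen=True)
class KmerTally:
    total_windows: int
    motif_count: int = 0

    def __post_init__(self):
        if not 0 <= self.motif_count <= max(self.total_windows, 0):
            raise ValueError("motif_count out of range")


@dataclass(frozen=True)
class EnrichmentResult:
    chi2: float
    p: float
    odds_ratio: float
    haldane_corrected: bool
    table: tuple[tuple[int, int], tuple[int, int]]


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _strand_seqs(seqs, config: MotifConfig):
    seqs = [s.upper() for s in seqs]
    if config.strands == "both":
        seqs = seqs + [_revcomp(s) for s in seqs]
    return seqs


def _valid_windows(seq: str, k: int) -> int:
    """Overlapping k-windows without N."""
    if len(seq) < k:
        return 0
    if "N" not in seq:
        return len(seq) - k + 1
    is_n = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("N")
    bad = np.convolve(is_n.astype(np.int32), np.ones(k, dtype=np.int32))[k - 1 : len(seq)]
    return int((bad == 0).sum())


def count_windows(seqs: list[str], config: MotifConfig | None = None) -> KmerTally:
    """Total overlapping k-windows over a sequence set (N-windows excluded)."""
    config = config or MotifConfig()
    total = sum(_valid_windows(s, config.k) for s in _strand_seqs(seqs, config))
    return KmerTally(total_windows=total)


def _motif_regex(motif: str, k: int) -> re.Pattern:
    motif = motif.upper()
    if len(motif) != k:
        raise ValueError(f"motif length {len(motif)} != k={k}")
    classes = []
    for ch in motif:
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC letter {ch!r} in motif")
        classes.append(f"[{IUPAC[ch]}]")
    # lookahead makes overlapping occurrences count
    return re.compile("(?=" + "".join(classes) + ")")


def motif_occurrence(
    seqs: list[str], motif: str, config: MotifConfig | None = None
) -> tuple[int, float]:
    """Overlapping occurrences of motif and the fraction of sequences hit.

    IUPAC degeneracy in the motif is expanded to base sets; sequence N
    matches nothing.
    """
    config = config or MotifConfig()
    pattern = _motif_regex(motif, config.k)
    strand_seqs = _strand_seqs(seqs, config)
    count = sum(len(pattern.findall(s)) for s in strand_seqs)
    if not seqs:
        return 0, 0.0
    if config.strands == "both":
        n = len(seqs)
        hit = sum(
            1
            for fwd, rev in zip(strand_seqs[:n], strand_seqs[n:])
            if pattern.search(fwd) or pattern.search(rev)
        )
    else:
        hit = sum(1 for s in strand_seqs if pattern.search(s))
    return count, hit / len(seqs)


def tally_motif(
    seqs: list[str], motif: str, config: MotifConfig | None = None
) -> KmerTally:
    """KmerTally (windows + motif occurrences) for one sequence set."""
    config = config or MotifConfig()
    total = count_windows(seqs, config).total_windows
    count, _ = motif_occurrence(seqs, motif, config)
    return KmerTally(total_windows=total, motif_count=count)


def chi2_enrichment(drj: KmerTally, genome: KmerTally) -> EnrichmentResult:
    """Pearson chi-square (1 df, no continuity correction) of motif rate in
    DRJs versus the genome, with odds ratio (Haldane +0.5 when a cell is 0).
    """
    a, b = drj.motif_count, drj.total_windows - drj.motif_count
    c, d = genome.motif_count, genome.total_windows - genome.motif_count
    table = np.array([[a, b], [c, d]], dtype=np.float64)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a marginal total is zero")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    haldane = min(a, b, c, d) == 0
    if haldane:
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(
        chi2=float(chi2),
        p=float(p),
        odds_ratio=float(odds),
        haldane_corrected=haldane,
        table=((a, b), (c, d)),
    )
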