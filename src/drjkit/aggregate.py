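"""Per-DRJ-pair aggregation of breakpoint calls.

Each status-ok call contributes interval evidence: the read supports every
position its breakpoint region spans.  Summing that coverage in the frame
of the left DRJ copy gives the per-position excision-site distribution for
a segment; the right-copy frame is emitted alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .discovery import DrjPair
from .segmentation import (
    STATUS_INCONSISTENT,
    STATUS_NO_INFORMATIVE,
    STATUS_NO_SWITCH,
    STATUS_OK,
    BreakpointCall,
)

logger = logging.getLogger(__name__)


@dataclass
class BreakpointDistribution:
    """Read-support per position of the left DRJ copy for one pair."""

    pair: DrjPair
    frame_start: int  # scaffold coordinate of the left copy start
    support: np.ndarray  # per-position status-ok region coverage
    support_right: np.ndarray  # same, right-copy frame
    n_reads_ok: int
    n_no_informative: int
    n_no_switch: int
    n_inconsistent: int

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.frame_start, self.frame_start + self.support.size)

    @property
    def total_mass(self) -> int:
        return int(self.support.sum())


def _pair_key(pair: DrjPair):
    return (pair.left.locus_name, pair.family, pair.left.start, pair.right.start)


def aggregate(
    calls: list[BreakpointCall], midpoint: bool = False
) -> list[BreakpointDistribution]:
    """One distribution per DRJ pair with at least one call.

    By default a status-ok call adds 1 to every position its region spans
    (interval evidence); ``midpoint=True`` instead adds 1 only at the
    region midpoint.  Non-ok calls are tallied but add no coverage.
    Output order and content are independent of input call order.
    """
    groups: dict[tuple, list[BreakpointCall]] = {}
    for call in calls:
        groups.setdefault(_pair_key(call.pair), []).append(call)
    out = []
    for key in sorted(groups):
        batch = groups[key]
        pair = batch[0].pair
        ls, le = pair.left.start, pair.left.end
        rs, re_ = pair.right.start, pair.right.end
        support = np.zeros(le - ls, dtype=np.int64)
        support_r = np.zeros(re_ - rs, dtype=np.int64)
        tallies = {STATUS_OK: 0, STATUS_NO_INFORMATIVE: 0,
                   STATUS_NO_SWITCH: 0, STATUS_INCONSISTENT: 0}
        for call in batch:
            tallies[call.status] += 1
            if call.status != STATUS_OK:
                continue
            a, b = call.region_left_ref
            ra, rb = call.region_right_ref
            if midpoint:
                a = (a + b - 1) // 2
                b = a + 1
                ra = (ra + rb - 1) // 2
                rb = ra + 1
            support[max(0, a - ls) : max(0, b - ls)] += 1
            support_r[max(0, ra - rs) : max(0, rb - rs)] += 1
        out.append(
            BreakpointDistribution(
                pair=pair,
                frame_start=ls,
                support=support,
                support_right=support_r,
                n_reads_ok=tallies[STATUS_OK],
                n_no_informative=tallies[STATUS_NO_INFORMATIVE],
                n_no_switch=tallies[STATUS_NO_SWITCH],
                n_inconsistent=tallies[STATUS_INCONSISTENT],
            )
        )
    return out


def summarize(dist: BreakpointDistribution) -> dict:
    """Modal excision position(s) and read tallies for one pair.

    Ties on the mode are reported as the half-open interval from the first
    to the last modal position.
    """
    sup = dist.support
    if sup.size == 0:
        raise ValueError("empty distribution")
    modal_support = int(sup.max())
    if modal_support > 0:
        modal = np.flatnonzero(sup == modal_support)
        mode_lo = int(modal[0]) + dist.frame_start
        mode_hi = int(modal[-1]) + 1 + dist.frame_start
    else:
        mode_lo = mode_hi = dist.frame_start
    return {
        "locus": dist.pair.left.locus_name,
        "family": dist.pair.family,
        "frame_start": dist.frame_start,
        "frame_end": dist.frame_start + sup.size,
        "modal_support": modal_support,
        "mode_start": mode_lo,
        "mode_end": mode_hi,
        "n_supported_positions": int((sup > 0).sum()),
        "total_mass": dist.total_mass,
        "n_reads_ok": dist.n_reads_ok,
        "n_no_informative": dist.n_no_informative,
        "n_no_switch": dist.n_no_switch,
        "n_inconsistent": dist.n_inconsistent,
    }


def render_profiles(
    dists: list[BreakpointDistribution], out_dir, plots: bool = False
) -> list[Path]:
    """Write one two-column (position, support) profile per pair.

    With ``plots=True`` a PNG of each profile is saved alongside
    (cosmetic; requires matplotlib).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if not dists:
        logger.info("no distributions to render")
        return written
    for dist in dists:
        stem = f"{dist.pair.left.locus_name}_{dist.pair.family}"
        path = out_dir / f"{stem}_profile.tsv"
        with open(path, "w") as fh:
            fh.write("position\tsupport\n")
            for pos, sup in zip(dist.positions, dist.support):
                fh.write(f"{pos}\t{sup}\n")
        written.append(path)
        if plots:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(6, 2.5))
            ax.fill_between(dist.positions, dist.support, step="mid", alpha=0.6)
            ax.set_xlabel(f"{stem} scaffold position (left DRJ copy)")
            ax.set_ylabel("reads")
            fig.tight_layout()
            fig.savefig(out_dir / f"{stem}_profile.png", dpi=120)
            plt.close(fig)
    return written
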