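"""Breakpoint localization by two-changepoint piecewise-constant fitting.

The recombined DRJ carried by an excised circle is a hybrid: it matches the
right parental copy (DRJR) up to the crossover and the left copy (DRJL)
after it.  At every *informative* position — an alignment column where the
two parental copies differ — the read's base votes +1 (DRJR allele) or -1
(DRJL allele).  Fitting a piecewise-constant function with two changepoints
to that punctual-difference signal partitions the window into three
segments: homology with DRJR, the breakpoint region, and homology with
DRJL.  The breakpoint region is the open/closed interval between the last
DRJR-supporting site and the first DRJL-supporting site.

The fit minimises the residual sum of squares over all (k1, k2) with
0 <= k1 <= k2 <= m.  Ties are broken by smallest middle width (k2 - k1),
then smallest k1.  Comparisons are exact (integer rational arithmetic), so
the optimum never depends on floating-point rounding.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .discovery import DrjPair
from .mapper import Triplet

STATUS_OK = "ok"
STATUS_NO_INFORMATIVE = "no_informative"
STATUS_NO_SWITCH = "no_switch"
STATUS_INCONSISTENT = "inconsistent_orientation"


@dataclass(frozen=True)
class DifferenceSignal:
    """Punctual-difference signal of one triplet.

    positions: window coordinates of informative columns (strictly
    increasing); values: +1 = read matches the DRJR allele, -1 = DRJL.
    excluded_cols: window columns dropped (read matches neither parent, or
    a gap/N in the column).  col_to_left_ref / col_to_right_ref project
    every window column to a scaffold coordinate within each parental copy
    context (monotone non-decreasing, gap columns carry the nearest
    preceding aligned coordinate).
    """

    triplet_id: str
    positions: tuple[int, ...]
    values: tuple[int, ...]
    excluded_cols: tuple[int, ...]
    col_to_left_ref: tuple[int, ...]
    col_to_right_ref: tuple[int, ...]

    @property
    def m(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class SegmentationFit:
    """Optimal 3-segment partition of the informative-site sequence.

    Segment 1 = sites 1..k1, segment 2 = k1+1..k2, segment 3 = k2+1..m.
    Empty segments have mean None and contribute 0 to the sse.
    orientation_ok is True when both outer segments are non-empty and
    mean(seg1) > mean(seg3) (DRJR homology before DRJL homology).
    """

    k1: int
    k2: int
    mu1: float | None
    mu2: float | None
    mu3: float | None
    sse: float
    orientation_ok: bool


@dataclass(frozen=True)
class BreakpointCall:
    triplet_id: str
    pair: DrjPair
    status: str
    region_window: tuple[int, int]  # (last seg-1 site, first seg-3 site]
    region_left_ref: tuple[int, int]  # scaffold coords, half-open
    region_right_ref: tuple[int, int]
    n_support_R: int
    n_support_L: int
    sse: float
    ambiguous: bool = False


def _columns(ctx_gapped: str, win_gapped: str, ctx_start: int, win_len: int):
    """Per-window-column parent base and scaffold coordinate for one
    context alignment.  Gap columns yield base None."""
    base: list[str | None] = [None] * win_len
    ref: list[int | None] = [None] * win_len
    cpos, wpos = ctx_start, 0
    for x, y in zip(ctx_gapped, win_gapped):
        if y != "-":
            if x != "-":
                base[wpos] = x
                ref[wpos] = cpos
            wpos += 1
        if x != "-":
            cpos += 1
    # monotone fill for projection of gap columns
    filled: list[int] = []
    last = ctx_start
    for r in ref:
        if r is not None:
            last = r
        filled.append(last)
    return base, filled


def build_signal(triplet: Triplet) -> DifferenceSignal:
    """Merge the two parental context alignments into a +/-1 signal.

    Columns where the parents agree are uninformative and skipped; columns
    with a gap or N, or where the read matches neither parent, are
    excluded.  A +1 means the read carries the DRJR allele.
    """
    win = triplet.window_seq
    n = len(win)
    lbase, lref = _columns(*triplet.aln_left, triplet.left_ctx_start, n)
    rbase, rref = _columns(*triplet.aln_right, triplet.right_ctx_start, n)
    positions: list[int] = []
    values: list[int] = []
    excluded: list[int] = []
    for i in range(n):
        lb, rb, b = lbase[i], rbase[i], win[i]
        if lb is None or rb is None or "N" in (lb, rb, b):
            excluded.append(i)
            continue
        if lb == rb:
            continue
        if b == rb:
            positions.append(i)
            values.append(+1)
        elif b == lb:
            positions.append(i)
            values.append(-1)
        else:
            excluded.append(i)
    return DifferenceSignal(
        triplet_id=triplet.triplet_id,
        positions=tuple(positions),
        values=tuple(values),
        excluded_cols=tuple(excluded),
        col_to_left_ref=tuple(lref),
        col_to_right_ref=tuple(rref),
    )


def _q_exact(P: list[int], m: int, k1: int, k2: int) -> tuple[int, int]:
    """Sum of S^2/n over non-empty segments as an exact (num, den) pair."""
    parts = []
    for s, n in (
        (P[k1], k1),
        (P[k2] - P[k1], k2 - k1),
        (P[m] - P[k2], m - k2),
    ):
        if n > 0:
            parts.append((s * s, n))
    den = 1
    for _, n in parts:
        den *= n
    num = sum(ss * (den // n) for ss, n in parts)
    return num, den


def fit_two_changepoints(signal: DifferenceSignal | "list[int]") -> SegmentationFit:
    """Exact optimum of the three-segment piecewise-constant fit.

    A vectorised float screen shortlists near-optimal (k1, k2); the winner
    and the tie-breaks (smallest k2-k1, then smallest k1) are then decided
    in exact integer arithmetic, so the result equals exhaustive search.
    """
    values = signal.values if isinstance(signal, DifferenceSignal) else signal
    s = np.asarray(values, dtype=np.int64)
    m = int(s.size)
    if m < 1:
        raise ValueError("signal has no informative sites")
    P = np.concatenate([[0], np.cumsum(s)])

    idx = np.arange(m + 1)
    k1g = idx[:, None].astype(float)
    k2g = idx[None, :].astype(float)
    S1 = P[idx][:, None].astype(float)
    S2 = P[idx][None, :] - P[idx][:, None]
    S3 = float(P[m]) - P[idx][None, :].astype(float)
    n1, n2, n3 = k1g, k2g - k1g, float(m) - k2g
    with np.errstate(divide="ignore", invalid="ignore"):
        Q = (
            np.where(n1 > 0, S1 * S1 / np.maximum(n1, 1), 0.0)
            + np.where(n2 > 0, S2 * S2 / np.maximum(n2, 1), 0.0)
            + np.where(n3 > 0, S3 * S3 / np.maximum(n3, 1), 0.0)
        )
    Q[~np.triu(np.ones((m + 1, m + 1), dtype=bool))] = -np.inf
    qmax = Q.max()
    cand = np.argwhere(Q >= qmax - 1e-9 * max(1.0, abs(qmax)))

    Pl = [int(x) for x in P]
    best = None  # (num, den, width, k1, k2)
    for k1, k2 in cand:
        k1, k2 = int(k1), int(k2)
        num, den = _q_exact(Pl, m, k1, k2)
        if best is None:
            best = (num, den, k2 - k1, k1, k2)
            continue
        cmp = num * best[1] - best[0] * den
        if cmp > 0 or (cmp == 0 and (k2 - k1, k1) < (best[2], best[3])):
            best = (num, den, k2 - k1, k1, k2)
    assert best is not None
    num, den, _, k1, k2 = best

    def seg_mean(a: int, b: int) -> float | None:
        return None if b == a else float(P[b] - P[a]) / (b - a)

    mu1, mu2, mu3 = seg_mean(0, k1), seg_mean(k1, k2), seg_mean(k2, m)
    sse = float(m) - num / den
    s1, s3 = int(P[k1]), int(P[m] - P[k2])
    orientation_ok = k1 > 0 and k2 < m and s1 * (m - k2) > s3 * k1
    return SegmentationFit(k1=k1, k2=k2, mu1=mu1, mu2=mu2, mu3=mu3,
                           sse=sse, orientation_ok=orientation_ok)


def _clip_region(lo: int, hi: int, span: tuple[int, int]) -> tuple[int, int]:
    """Clip a half-open scaffold interval into a copy span, never empty."""
    a, b = span
    lo = min(max(lo, a), b - 1)
    hi = min(max(hi, lo + 1), b)
    return lo, max(hi, lo + 1)


def call_breakpoint(triplet: Triplet) -> BreakpointCall:
    """Locate the excision breakpoint region of one triplet.

    Status ok requires >= 2 informative sites, at least one site in each
    outer segment, and valid orientation (DRJR homology before DRJL).  The
    region is the half-open window interval (last seg-1 site, first seg-3
    site], projected into both parental copies and clipped to their spans.
    """
    pair = triplet.pair
    sig = build_signal(triplet)
    left_span = (pair.left.start, pair.left.end)
    right_span = (pair.right.start, pair.right.end)
    full = BreakpointCall(
        triplet_id=sig.triplet_id,
        pair=pair,
        status=STATUS_NO_INFORMATIVE,
        region_window=(-1, len(triplet.window_seq) - 1),
        region_left_ref=left_span,
        region_right_ref=right_span,
        n_support_R=0,
        n_support_L=0,
        sse=0.0,
        ambiguous=triplet.ambiguous,
    )
    if sig.m == 0:
        return full
    if len(set(sig.values)) == 1:
        n_r = sig.values.count(+1)
        return _replace(full, status=STATUS_NO_SWITCH,
                        n_support_R=n_r, n_support_L=sig.m - n_r)
    fit = fit_two_changepoints(sig)
    k1, k2, m = fit.k1, fit.k2, sig.m
    if k1 == 0 or k2 == m or not fit.orientation_ok:
        return _replace(full, status=STATUS_INCONSISTENT, sse=fit.sse,
                        n_support_R=k1, n_support_L=m - k2)
    lo_w = sig.positions[k1 - 1]
    hi_w = sig.positions[k2]
    region_left = _clip_region(sig.col_to_left_ref[lo_w] + 1,
                               sig.col_to_left_ref[hi_w] + 1, left_span)
    region_right = _clip_region(sig.col_to_right_ref[lo_w] + 1,
                                sig.col_to_right_ref[hi_w] + 1, right_span)
    return BreakpointCall(
        triplet_id=sig.triplet_id,
        pair=pair,
        status=STATUS_OK,
        region_window=(lo_w, hi_w),
        region_left_ref=region_left,
        region_right_ref=region_right,
        n_support_R=k1,
        n_support_L=m - k2,
        sse=fit.sse,
        ambiguous=triplet.ambiguous,
    )


def _replace(call: BreakpointCall, **kw) -> BreakpointCall:
    return dataclasses.replace(call, **kw)
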