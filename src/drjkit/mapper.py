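"""Mapping circularized-molecule reads and extracting read-DRJL-DRJR triplets.

A read sequenced from an excised circle crosses the circle junction: on the
linear reference it aligns in two pieces, one ending at/inside the right
DRJ copy context and one starting at/inside the left copy context.  A read
qualifies as junction evidence for a DRJ pair only when its alignments
jointly cover the full recombined-DRJ span plus ``flank_bp`` of unique
sequence on both sides; the covered read window is then re-aligned globally
to the two parental copy contexts, giving the triplet the breakpoint
segmentation consumes.

The mapper is a self-contained exact-seed / affine-gap-extend aligner, so
the pipeline has no runtime tool dependency.  Reads whose seeds favour the
minus strand are reverse-complemented once and processed on plus.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

from . import _align
from .discovery import DrjPair
from .io import CircleRead, Scaffold

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MapParams:
    seed_k: int = 15
    min_chain_len: int = 40
    flank_bp: int = 20
    max_hits_per_read: int = 50

    def __post_init__(self):
        if self.seed_k < 8:
            raise ValueError("seed_k must be >= 8")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")


@dataclass(frozen=True)
class LocalAlignment:
    """A local hit of the (strand-normalized) read on a scaffold.

    read_start/read_end are coordinates on the read *after* strand
    normalization (reverse-complemented once when strand is '-').
    """

    read_id: str
    read_start: int
    read_end: int
    scaffold_id: str
    ref_start: int
    ref_end: int
    strand: str
    identity_pct: float
    score: float
    aligned_ref: str
    aligned_read: str


@dataclass(frozen=True)
class Triplet:
    """One read window spanning a recombined DRJ, with its two parents.

    ``aln_left``/``aln_right`` are (gapped context, gapped window) string
    pairs from a global alignment of the window against each parental copy
    context (copy +/- flank_bp on the scaffold, origins in
    ``left_ctx_start``/``right_ctx_start``).
    """

    read_id: str
    pair: DrjPair
    window_start: int
    window_end: int
    window_seq: str
    is_reverse: bool
    left_ctx_start: int
    right_ctx_start: int
    aln_left: tuple[str, str]
    aln_right: tuple[str, str]
    ambiguous: bool = False

    @property
    def triplet_id(self) -> str:
        return f"{self.read_id}|{self.pair.left.locus_name}|{self.pair.family}"


class ReferenceIndex:
    """Exact k-mer lookup over the forward strand of every scaffold."""

    def __init__(self, scaffolds: list[Scaffold], k: int = 15):
        self.k = k
        self.scaffolds = list(scaffolds)
        self._kmers: dict[str, list[tuple[int, int]]] = {}
        for si, sc in enumerate(self.scaffolds):
            seq = sc.sequence
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                self._kmers.setdefault(kmer, []).append((si, i))

    def lookup(self, kmer: str) -> list[tuple[int, int]]:
        """Hits of ``kmer`` (forward strand) as (scaffold index, position).
        A reverse-complement query finds minus-strand placements."""
        return self._kmers.get(kmer, [])


def build_index(scaffolds: list[Scaffold], k: int = 15) -> ReferenceIndex:
    return ReferenceIndex(scaffolds, k=k)


_MAX_KMER_HITS = 64  # repeat-kmer guard
_DIAG_BAND = 30


def _seed_hits(seq: str, index: ReferenceIndex):
    """Per-scaffold seed hits (diag, ref pos, read pos) for one orientation."""
    k = index.k
    per_scaffold: dict[int, list[tuple[int, int, int]]] = {}
    n = 0
    for j in range(len(seq) - k + 1):
        hits = index.lookup(seq[j : j + k])
        if not hits or len(hits) > _MAX_KMER_HITS:
            continue
        for si, p in hits:
            per_scaffold.setdefault(si, []).append((p - j, p, j))
            n += 1
    return per_scaffold, n


def _chains(hits: list[tuple[int, int, int]], k: int, read_len: int):
    """Group seeds into diagonal bands; yield (read span, ref span)."""
    hits = sorted(hits)
    groups: list[list[tuple[int, int, int]]] = []
    cur: list[tuple[int, int, int]] = []
    for h in hits:
        if cur and (h[0] - cur[-1][0] > _DIAG_BAND or abs(h[1] - cur[-1][1]) > max(read_len, 2000)):
            groups.append(cur)
            cur = []
        cur.append(h)
    if cur:
        groups.append(cur)
    for g in groups:
        r0 = min(c[2] for c in g)
        r1 = max(c[2] for c in g) + k
        p0 = min(c[1] for c in g)
        p1 = max(c[1] for c in g) + k
        yield (r0, r1), (p0, p1)


def map_read(read: CircleRead, index: ReferenceIndex,
             params: MapParams | None = None) -> list[LocalAlignment]:
    """Seed-and-extend local alignments of one read against the reference.

    Deterministic: the orientation with more exact seed hits wins (forward
    on ties); chains shorter than min_chain_len are dropped; overlapping
    hits are merged keeping the best score.
    """
    params = params or MapParams()
    seq = read.sequence
    if len(seq) < params.min_chain_len:
        logger.warning("read %s shorter than min_chain_len; skipped", read.id)
        return []
    fwd_hits, n_fwd = _seed_hits(seq, index)
    rc = _align.revcomp(seq)
    rev_hits, n_rev = _seed_hits(rc, index)
    if n_rev > n_fwd:
        strand, norm_seq, per_scaffold = "-", rc, rev_hits
    else:
        strand, norm_seq, per_scaffold = "+", seq, fwd_hits

    out: list[LocalAlignment] = []
    for si, hits in per_scaffold.items():
        scaffold = index.scaffolds[si]
        for (r0, r1), (p0, p1) in _chains(hits, index.k, len(norm_seq)):
            if r1 - r0 < params.min_chain_len:
                continue
            w_lo = max(0, p0 - r0 - 50)
            w_hi = min(len(scaffold), p1 + (len(norm_seq) - r1) + 50)
            aln = _align.align_local(scaffold.sequence[w_lo:w_hi], norm_seq)
            if aln is None:
                continue
            t0, t1 = _align.target_span(aln)
            q0, q1 = _align.query_span(aln)
            ga, gb = _align.gapped_strings(aln)
            if q1 - q0 < params.min_chain_len:
                continue
            out.append(
                LocalAlignment(
                    read_id=read.id,
                    read_start=q0,
                    read_end=q1,
                    scaffold_id=scaffold.id,
                    ref_start=w_lo + t0,
                    ref_end=w_lo + t1,
                    strand=strand,
                    identity_pct=round(_align.identity_pct(ga, gb), 1),
                    score=float(aln.score),
                    aligned_ref=ga,
                    aligned_read=gb,
                )
            )
    # merge near-duplicate hits (same scaffold, heavy overlap in read & ref)
    out.sort(key=lambda a: (-a.score, a.scaffold_id, a.ref_start))
    kept: list[LocalAlignment] = []
    for a in out:
        dup = False
        for b in kept:
            if a.scaffold_id != b.scaffold_id:
                continue
            ref_ov = min(a.ref_end, b.ref_end) - max(a.ref_start, b.ref_start)
            read_ov = min(a.read_end, b.read_end) - max(a.read_start, b.read_start)
            if ref_ov > 0.5 * (a.ref_end - a.ref_start) and \
               read_ov > 0.5 * (a.read_end - a.read_start):
                dup = True
                break
        if not dup:
            kept.append(a)
        if len(kept) >= params.max_hits_per_read:
            break
    return kept


def _aln_ref_to_read(aln: LocalAlignment) -> dict[int, int]:
    """Map scaffold coordinate -> normalized-read coordinate over the hit."""
    out: dict[int, int] = {}
    rpos, qpos = aln.ref_start, aln.read_start
    for x, y in zip(aln.aligned_ref, aln.aligned_read):
        if x != "-" and y != "-":
            out[rpos] = qpos
        if x != "-":
            rpos += 1
        if y != "-":
            qpos += 1
    return out


def _project(aln: LocalAlignment, ref_pos: int, search: int = 8) -> int | None:
    """Read coordinate of ref_pos; nearest aligned column within +/-search."""
    mapping = _aln_ref_to_read(aln)
    for d in range(search + 1):
        for cand in (ref_pos + d, ref_pos - d):
            if cand in mapping:
                return mapping[cand] + (ref_pos - cand)
    return None


def _covered(intervals: list[tuple[int, int]], lo: int, hi: int) -> bool:
    """True when [lo, hi) is fully covered by the union of intervals."""
    pos = lo
    for a, b in sorted(intervals):
        if a > pos:
            return False
        pos = max(pos, b)
        if pos >= hi:
            return True
    return pos >= hi


def extract_triplets(
    read: CircleRead,
    alignments: list[LocalAlignment],
    pairs: list[DrjPair],
    scaffolds_by_id: dict[str, Scaffold],
    params: MapParams | None = None,
    locus_scaffold: dict[str, str] | None = None,
) -> list[Triplet]:
    """Triplets supported by one read's alignments.

    A read yields a triplet for pair P iff some alignment covers the
    unique flank preceding P's right copy and runs into it, another (or
    the same) runs out of the left copy through its following flank, and
    the union of read intervals covers the whole window in between.  A
    read satisfying this for several pairs is emitted for each, flagged
    ambiguous.
    """
    params = params or MapParams()
    if not alignments:
        return []
    is_reverse = alignments[0].strand == "-"
    norm_seq = _align.revcomp(read.sequence) if is_reverse else read.sequence
    f = params.flank_bp
    found: list[Triplet] = []
    for pair in pairs:
        scaffold_id = locus_scaffold.get(pair.left.locus_name) if locus_scaffold else None
        if scaffold_id is None:
            # fall back: the pair's scaffold is whichever holds its coordinates
            cands = {a.scaffold_id for a in alignments}
            scaffold_id = next(iter(cands)) if len(cands) == 1 else None
        ls, le = pair.left.start, pair.left.end
        rs, re_ = pair.right.start, pair.right.end
        alns = [a for a in alignments
                if scaffold_id is None or a.scaffold_id == scaffold_id]
        piece_a = [a for a in alns if a.ref_start <= rs - f and a.ref_end > rs]
        piece_b = [a for a in alns if a.ref_end >= le + f and a.ref_start < le]
        if not piece_a or not piece_b:
            continue
        piece_a = max(piece_a, key=lambda a: a.score)
        piece_b = max(piece_b, key=lambda a: a.score)
        w_start = _project(piece_a, rs - f)
        w_end_in = _project(piece_b, le + f - 1)
        if w_start is None or w_end_in is None:
            continue
        w_end = w_end_in + 1
        if w_end <= w_start:
            continue
        if not _covered([(a.read_start, a.read_end) for a in alns], w_start, w_end):
            continue
        scaffold = scaffolds_by_id[piece_a.scaffold_id]
        lc_lo = max(0, ls - f)
        lc_hi = min(len(scaffold), le + f)
        rc_lo = max(0, rs - f)
        rc_hi = min(len(scaffold), re_ + f)
        window = norm_seq[w_start:w_end]
        aln_l = _align.align_global(scaffold.sequence[lc_lo:lc_hi], window)
        aln_r = _align.align_global(scaffold.sequence[rc_lo:rc_hi], window)
        found.append(
            Triplet(
                read_id=read.id,
                pair=pair,
                window_start=w_start,
                window_end=w_end,
                window_seq=window,
                is_reverse=is_reverse,
                left_ctx_start=lc_lo,
                right_ctx_start=rc_lo,
                aln_left=_align.gapped_strings(aln_l),
                aln_right=_align.gapped_strings(aln_r),
            )
        )
    if len(found) > 1:
        found = [dataclasses.replace(t, ambiguous=True) for t in found]
    return found


def find_triplets(
    reads: list[CircleRead],
    scaffolds: list[Scaffold],
    pairs: list[DrjPair],
    params: MapParams | None = None,
    locus_scaffold: dict[str, str] | None = None,
    index: ReferenceIndex | None = None,
) -> list[Triplet]:
    """Map every read and extract all triplets (convenience pipeline step)."""
    params = params or MapParams()
    if index is None:
        index = build_index(scaffolds, k=params.seed_k)
    by_id = {s.id: s for s in scaffolds}
    out: list[Triplet] = []
    for read in reads:
        alns = map_read(read, index, params)
        out.extend(
            extract_triplets(read, alns, pairs, by_id, params, locus_scaffold)
        )
    return out
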