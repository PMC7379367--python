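"""Shared pairwise-alignment engine.

All discovery and breakpoint operations use one affine-gap scoring scheme
(match +2, mismatch -3, gap open -5, gap extend -2) so that results are
reproducible: a gap of length g costs 5 + 2*g.  ``N`` never scores as a
match, not even against another ``N``.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

MATCH = 2
MISMATCH = -3
GAP_OPEN = -5
GAP_EXTEND = -2

_ALPHABET = "ACGTN"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _matrix():
    mat = substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            if a == b and a != "N":
                mat[a, b] = MATCH
            else:
                mat[a, b] = MISMATCH
    return mat


@lru_cache(maxsize=None)
def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _matrix()
    # biopython charges open_gap_score for the first gap base, so open+extend
    # here reproduces the "5 + 2*g" affine cost.
    aligner.open_gap_score = GAP_OPEN + GAP_EXTEND
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def align_local(target: str, query: str):
    """Best local alignment, or None when nothing scores above zero."""
    if not target or not query:
        return None
    alignments = _aligner("local").align(target, query)
    try:
        aln = alignments[0]
    except IndexError:
        return None
    if aln.score <= 0:
        return None
    return aln


def align_global(target: str, query: str):
    return _aligner("global").align(target, query)[0]


def gapped_strings(aln) -> tuple[str, str]:
    return str(aln[0]), str(aln[1])


def identity_pct(gapped_a: str, gapped_b: str) -> float:
    """Percent identical columns over *all* alignment columns (gaps count
    against identity; N matches nothing)."""
    if len(gapped_a) != len(gapped_b):
        raise ValueError("gapped strings differ in length")
    if not gapped_a:
        raise ValueError("empty alignment")
    matches = sum(
        1 for x, y in zip(gapped_a, gapped_b) if x == y and x in "ACGT"
    )
    return 100.0 * matches / len(gapped_a)


def target_span(aln) -> tuple[int, int]:
    blocks = aln.aligned[0]
    return int(blocks[0][0]), int(blocks[-1][1])


def query_span(aln) -> tuple[int, int]:
    blocks = aln.aligned[1]
    return int(blocks[0][0]), int(blocks[-1][1])


def query_to_target_map(aln) -> dict[int, int]:
    """Map query coordinates to target coordinates over aligned blocks."""
    out: dict[int, int] = {}
    for (t0, t1), (q0, q1) in zip(aln.aligned[0], aln.aligned[1]):
        for i in range(q1 - q0):
            out[q0 + i] = t0 + i
    return out


def target_to_query_map(aln) -> dict[int, int]:
    out: dict[int, int] = {}
    for (t0, t1), (q0, q1) in zip(aln.aligned[0], aln.aligned[1]):
        for i in range(t1 - t0):
            out[t0 + i] = q0 + i
    return out
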