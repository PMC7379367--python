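import pytest

from drjkit.discovery import RepeatCopy, pair_from_copies
from drjkit.mapper import Triplet


def make_pair(left_seq: str, right_seq: str, left_start: int = 1000,
              right_start: int = 5000, locus: str = "LocT",
              family: str = "DRJ1"):
    """DrjPair from two raw copy sequences at chosen scaffold offsets."""
    left = RepeatCopy(locus, family, left_start, left_start + len(left_seq),
                      "left", left_seq)
    right = RepeatCopy(locus, family, right_start, right_start + len(right_seq),
                       "right", right_seq)
    return pair_from_copies(left, right)


def make_triplet(left_seq: str, right_seq: str, window: str,
                 read_id: str = "read1", flank: int = 0, **pair_kw) -> Triplet:
    """Hand-built triplet whose context alignments are gapless and
    positional (copies must have equal length and window the same
    length), so the expected signal can be derived by eye."""
    assert len(left_seq) == len(right_seq) == len(window)
    pair = make_pair(left_seq, right_seq, **pair_kw)
    return Triplet(
        read_id=read_id,
        pair=pair,
        window_start=0,
        window_end=len(window),
        window_seq=window,
        is_reverse=False,
        left_ctx_start=pair.left.start,
        right_ctx_start=pair.right.start,
        aln_left=(left_seq, window),
        aln_right=(right_seq, window),
    )


@pytest.fixture
def rng():
    import numpy as np

    return np.random.default_rng(20240917)
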