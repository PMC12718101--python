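"""Unclipped 5' coordinates, orientation, scoring and pair canonicalization."""

import pytest
from hypothesis import given, settings, strategies as st

from blockdup.alignment_model import (
    FLAG_MATE_UNMAPPED,
    FLAG_PAIRED,
    FLAG_READ1,
    FLAG_READ2,
    FLAG_REVERSE,
    FLAG_SECONDARY,
)
from blockdup.keying import (
    build_fragment_end,
    build_pair_ends,
    end_score,
    orientation_of,
    unclipped_5prime,
)

from conftest import rec


@pytest.mark.parametrize(
    "flag,pos,cigar,expected",
    [
        (0, 100, "5S95M", 95),  # leading soft clip pulls the 5' end back
        (0, 100, "100M", 100),
        (FLAG_REVERSE, 100, "10M2D10M3S", 124),  # end 121 + trailing clip 3
        (0, 50, "4H2S44M", 44),  # hard clips count too
    ],
)
def test_unclipped_5prime(flag, pos, cigar, expected):
    assert unclipped_5prime(rec(flag=flag, pos=pos, cigar=cigar)) == expected


def test_unclipped_5prime_rejects_empty_cigar():
    with pytest.raises(ValueError):
        unclipped_5prime(rec(cigar=""))


@pytest.mark.parametrize(
    "left,right,expected",
    [("F", "R", "FR"), ("R", "F", "RF"), ("F", "F", "FF"), ("R", "R", "RR")],
)
def test_orientation_of(left, right, expected):
    assert orientation_of(left, right) == expected


@pytest.mark.parametrize(
    "quals,expected",
    [
        ([20, 20, 10], 40),  # 10 excluded by the quality floor
        ([5] * 10, 0),
        ([40] * 2000, 32767),  # cap forced (raw sum 80000)
    ],
)
def test_end_score(quals, expected):
    assert end_score(quals) == expected


def test_end_score_empty():
    assert end_score([]) == 0
    assert end_score(None) == 0


def test_fragment_end_unpaired(header):
    fe = build_fragment_end(rec(pos=100, cigar="100M", quals=30, read_group="rg0"), header)
    assert (fe.unclipped5, fe.strand, fe.score, fe.is_paired_end) == (100, "F", 3000, False)
    assert fe.library == "libA"


def test_fragment_end_mate_unmapped_is_not_paired(header):
    fe = build_fragment_end(rec(flag=FLAG_PAIRED | FLAG_MATE_UNMAPPED), header)
    assert not fe.is_paired_end


def test_fragment_end_unknown_library(header):
    assert build_fragment_end(rec(read_group=None), header).library == "Unknown Library"
    assert build_fragment_end(rec(read_group="nonexistent"), header).library == "Unknown Library"


def test_fragment_end_rejects_secondary(header):
    with pytest.raises(ValueError):
        build_fragment_end(rec(flag=FLAG_SECONDARY), header)


def _pair(header, pos1, cigar1, strand1, pos2, cigar2, strand2, qname="p"):
    f1 = FLAG_PAIRED | FLAG_READ1 | (FLAG_REVERSE if strand1 == "R" else 0)
    f2 = FLAG_PAIRED | FLAG_READ2 | (FLAG_REVERSE if strand2 == "R" else 0)
    r1 = rec(qname=qname, flag=f1, pos=pos1, cigar=cigar1, index=0)
    r2 = rec(qname=qname, flag=f2, pos=pos2, cigar=cigar2, index=1)
    return r1, r2


def test_pair_ends_basic_fr(header):
    r1, r2 = _pair(header, 100, "100M", "F", 151, "100M", "R")
    pe = build_pair_ends(r1, r2, header)
    assert (pe.coord1, pe.strand1, pe.coord2, pe.strand2) == (100, "F", 250, "R")
    assert pe.orientation == "FR"
    assert pe.score == 6000


def test_pair_ends_canonicalizes_reverse_first(header):
    # read1 maps R at unclipped 300, read2 F at 100: left end is F -> FR
    r1, r2 = _pair(header, 201, "100M", "R", 100, "100M", "F")
    pe = build_pair_ends(r1, r2, header)
    assert (pe.coord1, pe.strand1, pe.coord2, pe.strand2) == (100, "F", 300, "R")
    assert pe.orientation == "FR"


def test_pair_ends_rf_orientation_kept_distinct(header):
    r1, r2 = _pair(header, 100, "100M", "R", 301, "100M", "F")
    pe = build_pair_ends(r1, r2, header)
    # left end (unclipped 199) is R, right (301) is F
    assert pe.orientation == "RF"
    assert (pe.coord1, pe.strand1) == (199, "R")


def test_pair_ends_identical_coords_same_strand(header):
    r1, r2 = _pair(header, 100, "100M", "F", 100, "100M", "F")
    pe = build_pair_ends(r1, r2, header)
    assert pe.orientation == "FF"
    assert (pe.coord1, pe.coord2) == (100, 100)
    assert pe.record_indices == (0, 1)


def test_pair_ends_input_order_irrelevant(header):
    r1, r2 = _pair(header, 201, "5S95M", "R", 100, "100M", "F")
    assert build_pair_ends(r1, r2, header) == build_pair_ends(r2, r1, header)


def test_pair_ends_rejects_mismatched_qnames(header):
    r1, _ = _pair(header, 100, "100M", "F", 200, "100M", "R", qname="a")
    _, r2 = _pair(header, 100, "100M", "F", 200, "100M", "R", qname="b")
    with pytest.raises(ValueError):
        build_pair_ends(r1, r2, header)


@settings(derandomize=True, max_examples=50)
@given(
    pos=st.integers(1000, 5000),
    lead=st.integers(0, 30),
    trail=st.integers(0, 30),
    reverse=st.booleans(),
)
def test_soft_hard_clip_equivalence(pos, lead, trail, reverse):
    """Replacing S with H of the same length never moves the unclipped 5' end."""
    flag = FLAG_REVERSE if reverse else 0

    def cigar(op):
        parts = []
        if lead:
            parts.append(f"{lead}{op}")
        parts.append("80M")
        if trail:
            parts.append(f"{trail}{op}")
        return "".join(parts)

    soft = unclipped_5prime(rec(flag=flag, pos=pos, cigar=cigar("S")))
    hard = unclipped_5prime(rec(flag=flag, pos=pos, cigar=cigar("H")))
    assert soft == hard
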