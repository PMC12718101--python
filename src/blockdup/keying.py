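"""Duplicate keys: unclipped 5' coordinates, orientation, and end scores.

Two reads are PCR duplicates of one another when their library, unclipped 5'
coordinates, strands and pair orientation all agree.  The *unclipped* 5'
coordinate is the position the read's 5' end would map to if leading (forward
strand) or trailing (reverse strand) soft/hard clips were part of the
alignment — the coordinate aligners removed by clipping but the original
molecule still determines.  Scores rank members of a key group so that the
highest-quality copy is retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .alignment_model import (
    CLIP_OPS,
    FLAG_MATE_UNMAPPED,
    FLAG_PAIRED,
    FLAG_READ1,
    FLAG_SECONDARY,
    FLAG_SUPPLEMENTARY,
    FLAG_UNMAPPED,
    HeaderInfo,
    REF_CONSUMING,
    ReadRecord,
)
from .physical_location import PhysicalLocation, parse_location

#: Default minimum base quality contributing to a read's score.
DEFAULT_QUAL_FLOOR = 15
#: Default per-end score cap.
DEFAULT_SCORE_CAP = 32767

_STRAND_RANK = {"F": 0, "R": 1}


@dataclass(slots=True)
class FragmentEnd:
    """A single mapped read keyed for fragment-level duplicate grouping."""

    library: str
    ref_id: int
    unclipped5: int
    strand: str
    score: int
    is_paired_end: bool
    record_index: int
    qname: str

    @property
    def key(self) -> tuple:
        return (self.library, self.ref_id, self.unclipped5, self.strand)


@dataclass(slots=True)
class PairEnds:
    """Both primary ends of a read pair, canonically ordered, keyed and scored.

    Ends are stored so that ``(ref1, coord1, strand-rank)`` <= ``(ref2,
    coord2, strand-rank)``; ``orientation`` is computed *before* any swap,
    from the genomically leftmost end's strand first.
    """

    library: str
    ref1: int
    coord1: int
    strand1: str
    ref2: int
    coord2: int
    strand2: str
    orientation: str
    score: int
    record_indices: tuple[int, int]
    location: Optional[PhysicalLocation]
    qname: str

    @property
    def key(self) -> tuple:
        return (
            self.library,
            self.ref1,
            self.coord1,
            self.strand1,
            self.ref2,
            self.coord2,
            self.strand2,
            self.orientation,
        )


def unclipped_5prime(record: ReadRecord) -> int:
    """1-based unclipped 5' coordinate of a mapped record.

    Forward strand: ``pos`` minus leading S/H clip lengths.  Reverse strand:
    alignment end (``pos`` + reference-consumed length - 1) plus trailing
    S/H clip lengths.
    """
    cig = record.cigar
    if not cig:
        raise ValueError(f"record {record.record_index} has an empty CIGAR")
    if record.is_reverse:
        ref_len = sum(ln for op, ln in cig if op in REF_CONSUMING)
        clip = 0
        for op, ln in reversed(cig):
            if op not in CLIP_OPS:
                break
            clip += ln
        return record.pos + ref_len - 1 + clip
    clip = 0
    for op, ln in cig:
        if op not in CLIP_OPS:
            break
        clip += ln
    return record.pos - clip


def clip_shift(record: ReadRecord) -> int:
    """How far unclipped5 lies from ``pos`` (used to bound block margins)."""
    return abs(unclipped_5prime(record) - record.pos)


def orientation_of(strand_left: str, strand_right: str) -> str:
    """Pair orientation from the strands taken in genomic left-to-right order."""
    return strand_left + strand_right


def end_score(base_quals, qual_floor: int = DEFAULT_QUAL_FLOOR, cap: int = DEFAULT_SCORE_CAP) -> int:
    """Score of one end: sum of base qualities >= qual_floor, capped."""
    if base_quals is None or len(base_quals) == 0:
        return 0
    a = np.asarray(base_quals, dtype=np.int64)
    s = int(a[a >= qual_floor].sum())
    return min(s, cap)


def _check_primary_mapped(record: ReadRecord) -> None:
    if record.flag & (FLAG_UNMAPPED | FLAG_SECONDARY | FLAG_SUPPLEMENTARY):
        raise ValueError(
            f"record {record.record_index} is not a primary mapped alignment"
        )


def build_fragment_end(
    record: ReadRecord,
    header: HeaderInfo,
    qual_floor: int = DEFAULT_QUAL_FLOOR,
    cap: int = DEFAULT_SCORE_CAP,
) -> FragmentEnd:
    """Key a primary mapped record for fragment-level grouping.

    ``is_paired_end`` is true when the FLAG declares a mapped mate — such
    ends suppress co-located lone fragments but are themselves adjudicated
    only in their pair group.
    """
    _check_primary_mapped(record)
    return FragmentEnd(
        library=header.library_of(record.read_group),
        ref_id=record.ref_id,
        unclipped5=unclipped_5prime(record),
        strand=record.strand,
        score=end_score(record.base_quals, qual_floor, cap),
        is_paired_end=bool(record.flag & FLAG_PAIRED) and not record.flag & FLAG_MATE_UNMAPPED,
        record_index=record.record_index,
        qname=record.qname,
    )


def build_pair_ends(
    record1: ReadRecord,
    record2: ReadRecord,
    header: HeaderInfo,
    qual_floor: int = DEFAULT_QUAL_FLOOR,
    cap: int = DEFAULT_SCORE_CAP,
    name_pattern=None,
) -> PairEnds:
    """Join the two primary ends of a pair into one keyed, scored object.

    Input order of the two records does not matter: ends are canonically
    ordered by (ref, coord, strand-rank) with F < R, and ties fall back to
    read1-first, so a key group is independent of file order.
    """
    if record1.qname != record2.qname:
        raise ValueError(f"mismatched qnames: {record1.qname!r} vs {record2.qname!r}")
    for r in (record1, record2):
        _check_primary_mapped(r)
        if not r.flag & FLAG_PAIRED:
            raise ValueError(f"record {r.record_index} is not paired")

    # read1-first ordering used for tie-breaks and record_indices
    if record2.flag & FLAG_READ1 and not record1.flag & FLAG_READ1:
        r1, r2 = record2, record1
    else:
        r1, r2 = record1, record2

    e1 = (r1.ref_id, unclipped_5prime(r1), r1.strand)
    e2 = (r2.ref_id, unclipped_5prime(r2), r2.strand)

    # genomically leftmost end first; coordinate ties broken read1-first
    if (e2[0], e2[1]) < (e1[0], e1[1]):
        left, right = e2, e1
    else:
        left, right = e1, e2
    orientation = orientation_of(left[2], right[2])

    # canonical storage order includes strand rank
    a = (e1[0], e1[1], _STRAND_RANK[e1[2]])
    b = (e2[0], e2[1], _STRAND_RANK[e2[2]])
    first, second = (e1, e2) if a <= b else (e2, e1)

    loc = parse_location(r1.qname, read_group=r1.read_group, pattern=name_pattern)
    return PairEnds(
        library=header.library_of(r1.read_group),
        ref1=first[0],
        coord1=first[1],
        strand1=first[2],
        ref2=second[0],
        coord2=second[1],
        strand2=second[2],
        orientation=orientation,
        score=end_score(r1.base_quals, qual_floor, cap) + end_score(r2.base_quals, qual_floor, cap),
        record_indices=(r1.record_index, r2.record_index),
        location=loc,
        qname=r1.qname,
    )
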