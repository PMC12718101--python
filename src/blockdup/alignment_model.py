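"""Format-neutral alignment data model and SAM/BAM I/O.

Records are held in a small structured type (:class:`ReadRecord`) carrying
exactly the fields duplicate detection needs, plus a handle on the underlying
pysam segment so that the second pass can rewrite files with every non-FLAG
byte preserved.  Coordinates are 1-based inclusive throughout, matching SAM
text; pysam's 0-based positions are converted at this boundary and nowhere
else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pysam

# SAM FLAG bits
FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100
FLAG_QCFAIL = 0x200
FLAG_DUPLICATE = 0x400
FLAG_SUPPLEMENTARY = 0x800

CIGAR_OPS = "MIDNSHP=X"
#: CIGAR operations that consume reference bases.
REF_CONSUMING = frozenset("MDN=X")
#: Clipping operations (soft and hard both shift the unclipped 5' coordinate).
CLIP_OPS = frozenset("SH")

UNKNOWN_LIBRARY = "Unknown Library"


class FormatError(Exception):
    """Input file is not a usable SAM/BAM (missing header, unreadable)."""


class SortOrderError(Exception):
    """Input violates the coordinate-sort requirement."""

    def __init__(self, msg: str, indices: tuple[int, int] | None = None):
        super().__init__(msg)
        self.indices = indices


class ConsistencyError(Exception):
    """Internal contract violated (e.g. a record without a verdict)."""


@dataclass(slots=True)
class ReadRecord:
    """One SAM alignment line in structured form.

    ``pos`` and ``mate_pos`` are 1-based leftmost mapping positions (0 when
    absent).  ``cigar`` is a list of ``(op, length)`` with ``op`` one of
    ``MIDNSHP=X``; it is empty iff the record is unmapped.  ``record_index``
    is the 0-based ordinal of the record in its source file and is the
    identity duplicate verdicts attach to.
    """

    qname: str
    flag: int
    ref_id: int
    pos: int
    mapq: int
    cigar: list[tuple[str, int]]
    mate_ref_id: int
    mate_pos: int
    base_quals: object  # sequence of Phred ints (array/list/ndarray) or None
    read_group: Optional[str]
    record_index: int
    _seg: Optional[pysam.AlignedSegment] = field(default=None, repr=False, compare=False)

    @property
    def is_mapped(self) -> bool:
        return not self.flag & FLAG_UNMAPPED

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def strand(self) -> str:
        return "R" if self.flag & FLAG_REVERSE else "F"

    @classmethod
    def from_pysam(cls, seg: pysam.AlignedSegment, index: int) -> "ReadRecord":
        cig = seg.cigartuples
        try:
            rg = seg.get_tag("RG")
        except KeyError:
            rg = None
        return cls(
            qname=seg.query_name or "",
            flag=seg.flag,
            ref_id=seg.reference_id,
            pos=(seg.reference_start + 1) if seg.reference_start is not None and seg.reference_start >= 0 else 0,
            mapq=seg.mapping_quality,
            cigar=[(CIGAR_OPS[op], ln) for op, ln in cig] if cig else [],
            mate_ref_id=seg.next_reference_id,
            mate_pos=(seg.next_reference_start + 1) if seg.next_reference_start >= 0 else 0,
            base_quals=seg.query_qualities,
            read_group=rg if isinstance(rg, str) else (rg.decode() if isinstance(rg, bytes) else rg),
            record_index=index,
            _seg=seg,
        )


@dataclass
class HeaderInfo:
    """Parsed header: reference order, read-group->library map, sort order."""

    references: list[tuple[str, int]]
    rg_to_library: dict[str, str]
    sort_order: Optional[str]
    raw: dict

    def library_of(self, read_group: Optional[str]) -> str:
        if read_group is None:
            return UNKNOWN_LIBRARY
        return self.rg_to_library.get(read_group, UNKNOWN_LIBRARY)

    @property
    def libraries(self) -> list[str]:
        seen: list[str] = []
        for lib in self.rg_to_library.values():
            if lib not in seen:
                seen.append(lib)
        return seen

    @classmethod
    def from_pysam(cls, header: pysam.AlignmentHeader) -> "HeaderInfo":
        d = header.to_dict()
        refs = [(sq["SN"], int(sq["LN"])) for sq in d.get("SQ", [])]
        rgmap: dict[str, str] = {}
        for rg in d.get("RG", []):
            rgmap[rg["ID"]] = rg.get("LB", UNKNOWN_LIBRARY)
        so = d.get("HD", {}).get("SO")
        return cls(references=refs, rg_to_library=rgmap, sort_order=so, raw=d)


def _open_mode(path: str, write: bool = False) -> str:
    p = str(path)
    if write:
        return "wb" if p.endswith(".bam") else "wh"
    return "rb" if p.endswith(".bam") else "r"


def read_alignment_file(path) -> tuple[HeaderInfo, Iterator[ReadRecord]]:
    """Open a coordinate-sortable SAM/BAM and stream its records.

    Returns the parsed header and a generator yielding :class:`ReadRecord`
    in file order with ``record_index`` assigned 0,1,2,...
    """
    try:
        af = pysam.AlignmentFile(str(path), _open_mode(path), check_sq=False)
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot open alignment file {path}: {exc}") from exc
    header = HeaderInfo.from_pysam(af.header)
    if not header.references and "HD" not in header.raw:
        af.close()
        raise FormatError(f"{path}: missing header")

    def gen() -> Iterator[ReadRecord]:
        try:
            for i, seg in enumerate(af):
                yield ReadRecord.from_pysam(seg, i)
        finally:
            af.close()

    return header, gen()


def validate_sorted(records: Iterable[ReadRecord]) -> tuple[bool, Optional[tuple[int, int]]]:
    """Check coordinate order: (ref_id, pos) non-decreasing over mapped records.

    Unmapped records placed at mate coordinates (ref_id >= 0) are accepted
    anywhere; unmapped records with no coordinate are accepted only in the
    file tail.  Returns ``(True, None)`` or ``(False, (i, j))`` naming the
    record indices of the first violation.
    """
    prev_idx = -1
    prev_key: Optional[tuple[int, int]] = None
    tail_start: Optional[int] = None
    for rec in records:
        if rec.ref_id < 0:
            if tail_start is None:
                tail_start = rec.record_index
            continue
        if tail_start is not None:
            return False, (tail_start, rec.record_index)
        if not rec.is_mapped:
            continue  # mate-placed unmapped record: unconstrained
        key = (rec.ref_id, rec.pos)
        if prev_key is not None and key < prev_key:
            return False, (prev_idx, rec.record_index)
        prev_key, prev_idx = key, rec.record_index
    return True, None


def _append_pg(header_dict: dict, version: str) -> dict:
    d = {k: (list(v) if isinstance(v, list) else dict(v)) for k, v in header_dict.items()}
    pgs = [dict(pg) for pg in d.get("PG", [])]
    existing = {pg.get("ID") for pg in pgs}
    pg_id = "blockdup"
    n = 1
    while pg_id in existing:
        pg_id = f"blockdup.{n}"
        n += 1
    entry = {"ID": pg_id, "PN": "blockdup", "VN": version}
    if pgs:
        entry["PP"] = pgs[-1].get("ID")
    pgs.append(entry)
    d["PG"] = pgs
    return d


def write_alignment_file(
    records: Iterable[ReadRecord],
    header: HeaderInfo,
    verdicts,
    remove_duplicates: bool,
    path,
) -> int:
    """Second-pass writer: apply duplicate verdicts and emit SAM/BAM.

    FLAG bit 0x400 is set exactly on records whose verdict is a duplicate and
    cleared otherwise (pre-existing flags are overwritten, making the tool
    idempotent).  With ``remove_duplicates`` those records are omitted.  All
    other fields are preserved byte-for-byte; a @PG line is appended.
    Returns the number of records written.
    """
    from . import __version__
    from .group_marking import DUPLICATE_STATES

    hdr = _append_pg(header.raw, __version__)
    n_written = 0
    with pysam.AlignmentFile(str(path), _open_mode(path, write=True), header=hdr) as out:
        out_header = out.header
        for rec in records:
            try:
                state = verdicts[rec.record_index]
            except KeyError:
                raise ConsistencyError(
                    f"no verdict for record {rec.record_index} ({rec.qname})"
                ) from None
            is_dup = state in DUPLICATE_STATES
            if is_dup and remove_duplicates:
                continue
            seg = rec._seg
            if seg is None:
                seg = _segment_from_fields(rec, out_header)
            if is_dup:
                seg.flag |= FLAG_DUPLICATE
            else:
                seg.flag &= ~FLAG_DUPLICATE
            out.write(seg)
            n_written += 1
    return n_written


def _segment_from_fields(rec: ReadRecord, header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
    """Reconstruct a minimal segment for records not read from a file."""
    seg = pysam.AlignedSegment(header)
    seg.query_name = rec.qname
    seg.flag = rec.flag
    seg.reference_id = rec.ref_id
    seg.reference_start = rec.pos - 1 if rec.pos > 0 else -1
    seg.mapping_quality = rec.mapq
    if rec.cigar:
        seg.cigartuples = [(CIGAR_OPS.index(op), ln) for op, ln in rec.cigar]
    seg.next_reference_id = rec.mate_ref_id
    seg.next_reference_start = rec.mate_pos - 1 if rec.mate_pos > 0 else -1
    if rec.base_quals is not None and len(rec.base_quals) > 0:
        seg.query_sequence = "N" * len(rec.base_quals)
        seg.query_qualities = list(int(q) for q in rec.base_quals)
    if rec.read_group is not None:
        seg.set_tag("RG", rec.read_group)
    return seg
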