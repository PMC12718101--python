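"""Block-wise speculation-and-test duplicate marking.

The input is coordinate-sorted by *recorded* mapping position, but duplicate
keys use *unclipped* 5' coordinates, which can differ from the recorded
position by clipping (and, for reverse reads, by the reference span).  A
conventional tool therefore re-sorts every end globally before adjudicating.
This engine never does: it partitions the sorted stream into blocks, marks
each block as if it were an independent file (speculation), and then
reconciles the only two ways a block-local decision can be wrong (test
overlap):

1. a key group whose canonical coordinate lies within a safety *margin* of a
   block edge, and could therefore have same-key members in a neighbouring
   block, is withheld as provisional and merged by key across blocks;
2. a pair whose mates landed in different blocks is withheld as an orphan
   and joined globally by query name.

The margin is the maximum observed distance between a record's position and
its unclipped 5' coordinate (plus one), so any group that *could* span
blocks is provisional by construction; settled verdicts are final.  The
merged result is provably identical to a single global computation, at any
block size and any worker count: speculation is a pure map over blocks and
reconciliation a deterministic reduce.
"""

from __future__ import annotations

import logging
import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .alignment_model import (
    FLAG_SECONDARY,
    FLAG_SUPPLEMENTARY,
    HeaderInfo,
    ReadRecord,
    SortOrderError,
    read_alignment_file,
    validate_sorted,
    write_alignment_file,
)
from .group_marking import (
    Classification,
    MarkResult,
    VerdictState,
    classify_record,
    mark_fragment_group,
    mark_pair_group,
)
from .keying import (
    DEFAULT_QUAL_FLOOR,
    DEFAULT_SCORE_CAP,
    build_fragment_end,
    build_pair_ends,
    clip_shift,
    unclipped_5prime,
)
from .metrics import LibraryMetrics, accumulate_metrics, write_metrics_file
from .physical_location import DEFAULT_OPTICAL_PIXEL_DISTANCE

logger = logging.getLogger(__name__)

DEFAULT_BLOCK_RECORDS = 100_000


@dataclass
class MarkOptions:
    """Knobs shared by the block engine and the oracle."""

    block_records: int = DEFAULT_BLOCK_RECORDS
    threads: int = 1
    optical_pixel_distance: int = DEFAULT_OPTICAL_PIXEL_DISTANCE
    qual_floor: int = DEFAULT_QUAL_FLOOR
    score_cap: int = DEFAULT_SCORE_CAP
    margin_override: Optional[int] = None
    read_name_pattern: Optional[str] = None
    remove_duplicates: bool = False
    engine: str = "block"


@dataclass
class Block:
    """A contiguous slice of the sorted stream, never splitting a coordinate.

    ``start`` / ``end`` bound the mapping positions of the block's records,
    half-open; the edges are -inf / +inf at reference boundaries (a key
    cannot collide across references, so no margin is needed there).
    """

    block_id: int
    ref_id: int
    start: float
    end: float
    records: list[ReadRecord]


@dataclass
class BlockResult:
    """Product of speculating one block in isolation."""

    block_id: int
    settled: dict = field(default_factory=dict)
    provisional_pairs: dict = field(default_factory=dict)
    provisional_frags: dict = field(default_factory=dict)
    orphans: dict = field(default_factory=dict)  # qname -> ReadRecord
    frag_only: dict = field(default_factory=dict)
    pairs: list = field(default_factory=list)
    aux: dict = field(default_factory=dict)


def partition_blocks(records: Iterable[ReadRecord], target_block_records: int) -> list[Block]:
    """Cut the sorted stream into blocks of roughly the target record count.

    Boundaries are pushed forward so records sharing (ref_id, pos) stay
    together; a reference change always starts a new block.  Records with no
    coordinate (ref_id < 0) ride along in the current block.
    """
    if target_block_records < 1:
        raise ValueError("target_block_records must be >= 1")
    raw: list[tuple[int, list[ReadRecord]]] = []  # (ref_id, records)
    cur: list[ReadRecord] = []
    cur_ref: Optional[int] = None
    last_pos: Optional[int] = None
    for rec in records:
        if rec.ref_id < 0:
            cur.append(rec)
            continue
        if cur_ref is None:
            cur_ref = rec.ref_id
        elif rec.ref_id != cur_ref or (len(cur) >= target_block_records and rec.pos != last_pos):
            raw.append((cur_ref, cur))
            cur, cur_ref = [], rec.ref_id
        cur.append(rec)
        last_pos = rec.pos
    if cur:
        raw.append((cur_ref if cur_ref is not None else -1, cur))

    blocks: list[Block] = []
    for i, (ref, recs) in enumerate(raw):
        first_pos = next((r.pos for r in recs if r.ref_id >= 0), 0)
        prev_same = i > 0 and raw[i - 1][0] == ref
        next_same = i + 1 < len(raw) and raw[i + 1][0] == ref
        start: float = first_pos if prev_same else -math.inf
        if next_same:
            end: float = next(r.pos for r in raw[i + 1][1] if r.ref_id >= 0)
        else:
            end = math.inf
        blocks.append(Block(block_id=i, ref_id=ref, start=start, end=end, records=recs))
    return blocks


def speculate_block(block: Block, margin: int, header: HeaderInfo, options: Optional[MarkOptions] = None) -> BlockResult:
    """Mark one block as if it were an independent file.

    Key groups that provably cannot interact with other blocks are settled
    here; groups within ``margin`` of a block edge — or whose canonical
    coordinate matches an in-block orphan's unclipped 5' position, since the
    orphan's mate-joined pair may share their key — are emitted provisionally.
    Pure function of its arguments: invocations are independent and may run
    in any order on any worker.
    """
    opts = options or MarkOptions()
    res = BlockResult(block_id=block.block_id)
    by_qname: dict[str, list[ReadRecord]] = {}
    frag_ends = []

    for rec in block.records:
        cls = classify_record(rec)
        if cls is Classification.NOT_CONSIDERED:
            res.settled[rec.record_index] = VerdictState.NOT_CONSIDERED
            lib = header.library_of(rec.read_group)
            c = res.aux.setdefault(lib, [0, 0])
            c[0 if rec.flag & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY) else 1] += 1
            continue
        fe = build_fragment_end(rec, header, opts.qual_floor, opts.score_cap)
        frag_ends.append(fe)
        if cls is Classification.PAIRABLE:
            by_qname.setdefault(rec.qname, []).append(rec)
        else:
            res.frag_only[rec.record_index] = fe.library

    pair_ends = []
    orphan_coords: set[int] = set()
    for qname, recs in by_qname.items():
        if len(recs) == 2:
            pe = build_pair_ends(
                recs[0], recs[1], header, opts.qual_floor, opts.score_cap, opts.read_name_pattern
            )
            pair_ends.append(pe)
            res.pairs.append((pe.record_indices[0], pe.record_indices[1], pe.library))
        elif len(recs) == 1:
            res.orphans[qname] = recs[0]
            orphan_coords.add(unclipped_5prime(recs[0]))
        else:
            raise ValueError(f"more than two primary records share qname {qname!r}")

    lo = block.start + margin
    hi = block.end - margin

    pair_ends.sort(key=lambda p: p.key)  # within-block sort of the keyed ends
    pair_groups: dict[tuple, list] = {}
    for pe in pair_ends:
        pair_groups.setdefault(pe.key, []).append(pe)
    for key, grp in pair_groups.items():
        coord1 = key[2]
        if coord1 < lo or coord1 >= hi or coord1 in orphan_coords:
            res.provisional_pairs[key] = grp
        else:
            res.settled.update(mark_pair_group(grp, opts.optical_pixel_distance))

    frag_groups: dict[tuple, list] = {}
    for fe in frag_ends:
        frag_groups.setdefault(fe.key, []).append(fe)
    for key, grp in frag_groups.items():
        coord = key[2]
        if coord < lo or coord >= hi:
            res.provisional_frags[key] = grp
        else:
            res.settled.update(mark_fragment_group(grp))

    return res


def test_overlap(results: Sequence[BlockResult], header: HeaderInfo, options: Optional[MarkOptions] = None) -> MarkResult:
    """Resolve inter-block dependencies and merge to the final verdict table.

    Orphans are joined globally by query name (mates can be arbitrarily far
    apart — proximity is an optimization assumption, not a correctness one);
    provisional groups sharing a key are merged across all blocks and
    adjudicated with exactly the rules used for settled groups.
    """
    opts = options or MarkOptions()
    out = MarkResult()

    def merge_verdicts(vs: dict) -> None:
        for idx, state in vs.items():
            if idx in out.verdicts:
                raise ValueError(f"record {idx} adjudicated twice")
            out.verdicts[idx] = state

    merged_pairs: dict[tuple, list] = {}
    merged_frags: dict[tuple, list] = {}
    orphan_map: dict[str, list[ReadRecord]] = {}
    n_provisional = 0
    for res in results:
        merge_verdicts(res.settled)
        out.frag_only.update(res.frag_only)
        out.pairs.extend(res.pairs)
        for lib, (sec, unm) in res.aux.items():
            c = out.aux.setdefault(lib, [0, 0])
            c[0] += sec
            c[1] += unm
        for key, grp in res.provisional_pairs.items():
            merged_pairs.setdefault(key, []).extend(grp)
            n_provisional += 1
        for key, grp in res.provisional_frags.items():
            merged_frags.setdefault(key, []).extend(grp)
            n_provisional += 1
        for qname, rec in res.orphans.items():
            orphan_map.setdefault(qname, []).append(rec)

    lone: list[ReadRecord] = []
    n_joined = 0
    for qname, recs in orphan_map.items():
        if len(recs) == 2:
            pe = build_pair_ends(
                recs[0], recs[1], header, opts.qual_floor, opts.score_cap, opts.read_name_pattern
            )
            merged_pairs.setdefault(pe.key, []).append(pe)
            out.pairs.append((pe.record_indices[0], pe.record_indices[1], pe.library))
            n_joined += 1
        elif len(recs) == 1:
            lone.append(recs[0])
        else:
            raise ValueError(f"more than two primary records share qname {qname!r}")

    for key, grp in merged_pairs.items():
        merge_verdicts(mark_pair_group(grp, opts.optical_pixel_distance))
    for key, grp in merged_frags.items():
        merge_verdicts(mark_fragment_group(grp))

    if lone:
        out.lone_orphans = len(lone)
        logger.warning("%d paired records had no mate in the file; treated as fragments", len(lone))
        lone_groups: dict[tuple, list] = {}
        for rec in lone:
            fe = build_fragment_end(rec, header, opts.qual_floor, opts.score_cap)
            fe.is_paired_end = False
            out.frag_only[rec.record_index] = fe.library
            lone_groups.setdefault(fe.key, []).append(fe)
        for grp in lone_groups.values():
            merge_verdicts(mark_fragment_group(grp))

    logger.info(
        "test overlap: %d provisional groups, %d orphans (%d joined, %d lone)",
        n_provisional,
        sum(len(v) for v in orphan_map.values()),
        n_joined,
        len(lone),
    )
    return out


def compute_margin(records: Iterable[ReadRecord]) -> tuple[int, bool, Optional[tuple[int, int]]]:
    """One streaming scan: sort validation and the block-safety margin.

    The margin is the maximum observed |unclipped5 - pos| over mapped primary
    records, plus one — a conservative bound on how far a duplicate key can
    sit from the recorded position that placed its record in a block.
    """
    max_shift = 0
    prev_key: Optional[tuple[int, int]] = None
    prev_idx = -1
    tail_start: Optional[int] = None
    for rec in records:
        if rec.ref_id < 0:
            if tail_start is None:
                tail_start = rec.record_index
            continue
        if tail_start is not None:
            return max_shift + 1, False, (tail_start, rec.record_index)
        if not rec.is_mapped:
            continue
        key = (rec.ref_id, rec.pos)
        if prev_key is not None and key < prev_key:
            return max_shift + 1, False, (prev_idx, rec.record_index)
        prev_key, prev_idx = key, rec.record_index
        if rec.cigar:
            s = clip_shift(rec)
            if s > max_shift:
                max_shift = s
    return max_shift + 1, True, None


def mark_records(records: Sequence[ReadRecord], header: HeaderInfo, options: Optional[MarkOptions] = None,
                 margin: Optional[int] = None) -> MarkResult:
    """Run partition -> speculate (parallel map) -> test overlap in memory."""
    opts = options or MarkOptions()
    if margin is None:
        margin = opts.margin_override
    if margin is None:
        margin, ok, viol = compute_margin(records)
        if not ok:
            raise SortOrderError(
                f"input is not coordinate-sorted (records {viol[0]} and {viol[1]})", viol
            )
    blocks = partition_blocks(records, opts.block_records)
    logger.info("partitioned %d records into %d blocks (margin %d)", len(records), len(blocks), margin)
    if opts.threads > 1:
        with ThreadPoolExecutor(max_workers=opts.threads) as pool:
            results = list(pool.map(lambda b: speculate_block(b, margin, header, opts), blocks))
    else:
        results = [speculate_block(b, margin, header, opts) for b in blocks]
    return test_overlap(results, header, opts)


def run_two_pass(
    input_path,
    output_path,
    metrics_path,
    options: Optional[MarkOptions] = None,
) -> dict[str, LibraryMetrics]:
    """Full tool run: verdicts over the whole file, then a rewriting pass.

    Pass 1 streams the file once to validate sort order and size the safety
    margin, then again to partition, speculate and reconcile.  Pass 2
    re-reads the input and applies the verdict table, so flag decisions
    always see complete group information.  Returns the per-library metrics
    (also written to ``metrics_path``).
    """
    opts = options or MarkOptions()

    header, stream = read_alignment_file(input_path)
    margin, ok, viol = compute_margin(stream)
    if not ok:
        raise SortOrderError(
            f"{input_path}: not coordinate-sorted (records {viol[0]} and {viol[1]})", viol
        )
    if header.sort_order not in (None, "coordinate"):
        raise SortOrderError(f"{input_path}: header declares sort order {header.sort_order!r}")
    if opts.margin_override is not None:
        margin = opts.margin_override

    header, stream = read_alignment_file(input_path)
    if opts.engine == "oracle":
        from .reference_oracle import oracle_mark

        result = oracle_mark(list(stream), header, opts)
    else:
        result = mark_records(list(stream), header, opts, margin=margin)

    metrics = accumulate_metrics(result, header.libraries)
    if metrics_path is not None:
        write_metrics_file(metrics, metrics_path, command=f"input: {input_path}")

    header2, stream2 = read_alignment_file(input_path)
    n = write_alignment_file(stream2, header2, result.verdicts, opts.remove_duplicates, output_path)
    logger.info(
        "wrote %d records, %d flagged duplicate, %d lone orphans",
        n,
        len(result.flagged_indices()),
        result.lone_orphans,
    )
    return metrics
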