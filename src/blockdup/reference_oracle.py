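"""Brute-force global duplicate marking: the ground truth the block engine
must match.

Implements the conventional workflow — build every end, sort all of them by
key globally, adjudicate each key group — with no blocks, no speculation and
no boundary reconciliation.  It shares the keying and group-adjudication
rules with the block engine (so both rank and tie-break identically) but
none of the block machinery, making equality between the two a meaningful
check of the speculation mechanism rather than a tautology.
"""

from __future__ import annotations

import logging
from itertools import groupby
from typing import Iterable, Sequence

from .alignment_model import (
    FLAG_SECONDARY,
    FLAG_SUPPLEMENTARY,
    HeaderInfo,
    ReadRecord,
)
from .group_marking import (
    Classification,
    MarkResult,
    classify_record,
    mark_fragment_group,
    mark_pair_group,
    VerdictState,
)
from .keying import build_fragment_end, build_pair_ends

logger = logging.getLogger(__name__)


def oracle_mark(records: Iterable[ReadRecord], header: HeaderInfo, options=None) -> MarkResult:
    """Mark duplicates over the whole file at once (fixture scale only)."""
    from .block_engine import MarkOptions  # options container shared with the engine

    opts = options or MarkOptions()
    result = MarkResult()
    frag_ends = []
    by_qname: dict[str, list[ReadRecord]] = {}

    for rec in records:
        cls = classify_record(rec)
        if cls is Classification.NOT_CONSIDERED:
            result.verdicts[rec.record_index] = VerdictState.NOT_CONSIDERED
            result.count_aux(
                header.library_of(rec.read_group),
                secondary=bool(rec.flag & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY)),
            )
            continue
        fe = build_fragment_end(rec, header, opts.qual_floor, opts.score_cap)
        frag_ends.append(fe)
        if cls is Classification.PAIRABLE:
            by_qname.setdefault(rec.qname, []).append(rec)
        else:
            result.frag_only[rec.record_index] = fe.library

    pair_ends = []
    downgraded = []
    for qname, recs in by_qname.items():
        if len(recs) == 2:
            pe = build_pair_ends(
                recs[0], recs[1], header, opts.qual_floor, opts.score_cap, opts.read_name_pattern
            )
            pair_ends.append(pe)
            result.pairs.append((pe.record_indices[0], pe.record_indices[1], pe.library))
        elif len(recs) == 1:
            downgraded.append(recs[0])
        else:
            raise ValueError(f"more than two primary records share qname {qname!r}")

    # global sort by key, then adjudicate each group
    pair_ends.sort(key=lambda p: p.key)
    for _, grp in groupby(pair_ends, key=lambda p: p.key):
        result.verdicts.update(mark_pair_group(list(grp), opts.optical_pixel_distance))

    frag_ends.sort(key=lambda f: f.key)
    for _, grp in groupby(frag_ends, key=lambda f: f.key):
        result.verdicts.update(mark_fragment_group(list(grp)))

    if downgraded:
        result.lone_orphans = len(downgraded)
        logger.warning("%d paired records had no mate in the file; treated as fragments", len(downgraded))
        lone_ends = []
        for rec in downgraded:
            fe = build_fragment_end(rec, header, opts.qual_floor, opts.score_cap)
            fe.is_paired_end = False
            lone_ends.append(fe)
            result.frag_only[rec.record_index] = fe.library
        lone_ends.sort(key=lambda f: f.key)
        for _, grp in groupby(lone_ends, key=lambda f: f.key):
            result.verdicts.update(mark_fragment_group(list(grp)))

    return result
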