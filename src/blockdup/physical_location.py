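"""Flow-cell physical coordinates and optical duplicate classification.

Optical duplicates arise from sequencer image artifacts: two clusters on the
same tile within a small pixel distance read the same molecule.  They are a
sub-classification *within* an already-established duplicate group — the
box-distance test never creates a duplicate, it only relabels one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

#: Default per-axis pixel box for optical duplicate calls.
DEFAULT_OPTICAL_PIXEL_DISTANCE = 100

_SUFFIX = re.compile(r"[/#].*$")


@dataclass(frozen=True, slots=True)
class PhysicalLocation:
    """Tile and pixel coordinates parsed from an Illumina-style query name."""

    read_group: Optional[str]
    tile: int
    x: int
    y: int


def parse_location(qname: str, read_group: Optional[str] = None, pattern=None) -> Optional[PhysicalLocation]:
    """Extract (tile, x, y) from a query name, or None when unparsable.

    Default convention: colon-split names with 5 or 7 fields whose last three
    fields are tile, x, y (y may carry a trailing ``/1`` or ``#...`` suffix).
    A custom regex with three integer capture groups may be supplied instead.
    """
    if pattern is not None:
        m = re.search(pattern, qname) if isinstance(pattern, str) else pattern.search(qname)
        if not m or len(m.groups()) < 3:
            return None
        try:
            tile, x, y = (int(m.group(i)) for i in (1, 2, 3))
        except ValueError:
            return None
    else:
        parts = qname.split(":")
        if len(parts) not in (5, 7):
            return None
        tile_s, x_s, y_s = parts[-3], parts[-2], _SUFFIX.sub("", parts[-1])
        try:
            tile, x, y = int(tile_s), int(x_s), int(y_s)
        except ValueError:
            return None
    if tile < 0 or x < 0 or y < 0:
        return None
    return PhysicalLocation(read_group=read_group, tile=tile, x=x, y=y)


def find_optical_duplicates(
    group: Sequence,
    representative_index: int,
    max_pixel_distance: int = DEFAULT_OPTICAL_PIXEL_DISTANCE,
) -> set[int]:
    """Positions in ``group`` whose duplicate call should be labelled optical.

    Members sharing a read group and tile within ``max_pixel_distance`` on
    both axes are linked; within each connected component every member but
    one anchor is optical.  The anchor is the group representative when the
    component contains it, else the member with the lexicographically least
    query name.  Transitive (component) clustering makes the result invariant
    under permuting group members.  Members without locations are never
    flagged.
    """
    located = [i for i, p in enumerate(group) if p.location is not None]
    if len(located) < 2:
        return set()

    parent = {i: i for i in located}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a_pos in range(len(located)):
        i = located[a_pos]
        li = group[i].location
        for b_pos in range(a_pos + 1, len(located)):
            j = located[b_pos]
            lj = group[j].location
            if (
                li.read_group == lj.read_group
                and li.tile == lj.tile
                and abs(li.x - lj.x) <= max_pixel_distance
                and abs(li.y - lj.y) <= max_pixel_distance
            ):
                parent[find(i)] = find(j)

    components: dict[int, list[int]] = {}
    for i in located:
        components.setdefault(find(i), []).append(i)

    flagged: set[int] = set()
    for members in components.values():
        if len(members) < 2:
            continue
        if representative_index in members:
            anchor = representative_index
        else:
            anchor = min(members, key=lambda i: group[i].qname)
        flagged.update(m for m in members if m != anchor)
    return flagged
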