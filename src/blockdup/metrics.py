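"""Per-library duplication metrics and library-size estimation.

The metrics file follows the de-facto gold-standard tab-table layout
(comment lines, a header row, one row per library) so downstream pipeline
parsers accept it unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .group_marking import (
    DUPLICATE_STATES,
    MarkResult,
    VerdictState,
)

METRICS_FIELDS = [
    "LIBRARY",
    "UNPAIRED_READS_EXAMINED",
    "READ_PAIRS_EXAMINED",
    "SECONDARY_OR_SUPPLEMENTARY_RDS",
    "UNMAPPED_READS",
    "UNPAIRED_READ_DUPLICATES",
    "READ_PAIR_DUPLICATES",
    "READ_PAIR_OPTICAL_DUPLICATES",
    "PERCENT_DUPLICATION",
    "ESTIMATED_LIBRARY_SIZE",
]


@dataclass
class LibraryMetrics:
    library: str
    unpaired_reads_examined: int = 0
    read_pairs_examined: int = 0
    secondary_or_supplementary: int = 0
    unmapped_reads: int = 0
    unpaired_read_duplicates: int = 0
    read_pair_duplicates: int = 0
    read_pair_optical_duplicates: int = 0
    percent_duplication: float = 0.0
    estimated_library_size: Optional[float] = None

    def finalize(self) -> None:
        denom = self.unpaired_reads_examined + 2 * self.read_pairs_examined
        num = self.unpaired_read_duplicates + 2 * self.read_pair_duplicates
        self.percent_duplication = num / denom if denom else 0.0
        self.estimated_library_size = estimate_library_size(
            self.read_pairs_examined - self.read_pair_optical_duplicates,
            self.read_pairs_examined - self.read_pair_duplicates,
        )


def estimate_library_size(read_pairs: float, unique_read_pairs: float) -> Optional[float]:
    """Distinct-molecule estimate: the root X of U = X * (1 - exp(-N/X)).

    Models sampling N read pairs with replacement from X molecules and asks
    which X makes the expected number of distinct molecules seen equal U.
    Returns None when U = 0 or U >= N (no finite root).  Solved by doubling
    an upper bound from X0 = U, then bisection to relative tolerance 1e-9.
    """
    n, u = float(read_pairs), float(unique_read_pairs)
    if u <= 0 or u >= n:
        return None

    def seen(x: float) -> float:
        # x * (1 - exp(-n/x)), stable for large x
        return -x * math.expm1(-n / x)

    lo = u
    hi = 2.0 * u
    while seen(hi) < u:
        lo = hi
        hi *= 2.0
    while (hi - lo) > 1e-9 * hi:
        mid = 0.5 * (lo + hi)
        if seen(mid) < u:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def accumulate_metrics(result: MarkResult, header_libraries=()) -> dict[str, LibraryMetrics]:
    """Tally final verdicts into per-library metrics (pairs counted once)."""
    out: dict[str, LibraryMetrics] = {}

    def lib_metrics(lib: str) -> LibraryMetrics:
        if lib not in out:
            out[lib] = LibraryMetrics(library=lib)
        return out[lib]

    for lib in header_libraries:
        lib_metrics(lib)

    verdicts = result.verdicts
    for idx, lib in result.frag_only.items():
        m = lib_metrics(lib)
        m.unpaired_reads_examined += 1
        if verdicts.get(idx) in DUPLICATE_STATES:
            m.unpaired_read_duplicates += 1
    for i1, i2, lib in result.pairs:
        m = lib_metrics(lib)
        m.read_pairs_examined += 1
        state = verdicts.get(i1)
        if state in DUPLICATE_STATES:
            m.read_pair_duplicates += 1
            if state is VerdictState.OPTICAL_DUPLICATE:
                m.read_pair_optical_duplicates += 1
    for lib, (sec, unmapped) in result.aux.items():
        m = lib_metrics(lib)
        m.secondary_or_supplementary += sec
        m.unmapped_reads += unmapped

    for m in out.values():
        m.finalize()
    return out


def write_metrics_file(metrics: dict[str, LibraryMetrics], path, command: Optional[str] = None) -> None:
    """Write the tab-separated per-library metrics table."""
    with open(path, "w") as fh:
        fh.write("# blockdup duplication metrics\n")
        if command:
            fh.write(f"# {command}\n")
        fh.write("\t".join(METRICS_FIELDS) + "\n")
        for lib in sorted(metrics):
            m = metrics[lib]
            els = "" if m.estimated_library_size is None else repr(m.estimated_library_size)
            fh.write(
                "\t".join(
                    [
                        m.library,
                        str(m.unpaired_reads_examined),
                        str(m.read_pairs_examined),
                        str(m.secondary_or_supplementary),
                        str(m.unmapped_reads),
                        str(m.unpaired_read_duplicates),
                        str(m.read_pair_duplicates),
                        str(m.read_pair_optical_duplicates),
                        repr(m.percent_duplication),
                        els,
                    ]
                )
                + "\n"
            )


def read_metrics_file(path) -> dict[str, LibraryMetrics]:
    """Parse a metrics file written by :func:`write_metrics_file`."""
    out: dict[str, LibraryMetrics] = {}
    with open(path) as fh:
        header: Optional[list[str]] = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                if header != METRICS_FIELDS:
                    raise ValueError(f"unexpected metrics header in {path}")
                continue
            f = line.split("\t")
            m = LibraryMetrics(
                library=f[0],
                unpaired_reads_examined=int(f[1]),
                read_pairs_examined=int(f[2]),
                secondary_or_supplementary=int(f[3]),
                unmapped_reads=int(f[4]),
                unpaired_read_duplicates=int(f[5]),
                read_pair_duplicates=int(f[6]),
                read_pair_optical_duplicates=int(f[7]),
                percent_duplication=float(f[8]),
                estimated_library_size=float(f[9]) if f[9] else None,
            )
            out[m.library] = m
    return out
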