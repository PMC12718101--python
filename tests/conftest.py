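import re

import pytest

from blockdup.alignment_model import HeaderInfo, ReadRecord

_CIG = re.compile(r"(\d+)([MIDNSHP=X])")


def cig(cigar: str):
    """Parse a CIGAR string into the (op, length) list ReadRecord uses."""
    if cigar in ("", "*"):
        return []
    return [(op, int(n)) for n, op in _CIG.findall(cigar)]


def rec(
    qname="q",
    flag=0,
    ref_id=0,
    pos=100,
    cigar="100M",
    quals=30,
    mate_ref_id=-1,
    mate_pos=0,
    read_group=None,
    index=0,
    mapq=60,
):
    """Build a ReadRecord by hand; int quals mean a uniform quality read."""
    c = cig(cigar)
    if isinstance(quals, int):
        n = sum(ln for op, ln in c if op in "MIS=X") or 100
        quals = [quals] * n
    return ReadRecord(
        qname=qname,
        flag=flag,
        ref_id=ref_id,
        pos=pos,
        mapq=mapq,
        cigar=c,
        mate_ref_id=mate_ref_id,
        mate_pos=mate_pos,
        base_quals=quals,
        read_group=read_group,
        record_index=index,
    )


@pytest.fixture
def header():
    return HeaderInfo(
        references=[("chr1", 10_000_000), ("chr2", 10_000_000)],
        rg_to_library={"rg0": "libA", "rg1": "libB"},
        sort_order="coordinate",
        raw={
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": "chr1", "LN": 10_000_000},
                {"SN": "chr2", "LN": 10_000_000},
            ],
            "RG": [
                {"ID": "rg0", "LB": "libA"},
                {"ID": "rg1", "LB": "libB"},
            ],
        },
    )


SAM_HEADER = (
    "@HD\tVN:1.6\tSO:coordinate\n"
    "@SQ\tSN:chr1\tLN:10000000\n"
    "@SQ\tSN:chr2\tLN:10000000\n"
    "@RG\tID:rg0\tLB:libA\n"
)


def sam_line(
    qname="q",
    flag=0,
    rname="chr1",
    pos=100,
    mapq=60,
    cigar="10M",
    rnext="*",
    pnext=0,
    tlen=0,
    seq=None,
    qual=None,
    rg="rg0",
):
    if seq is None:
        n = sum(ln for op, ln in cig(cigar) if op in "MIS=X") or 10
        seq = "A" * n
    if qual is None:
        qual = chr(30 + 33) * len(seq)
    tags = f"\tRG:Z:{rg}" if rg else ""
    return (
        f"{qname}\t{flag}\t{rname}\t{pos}\t{mapq}\t{cigar}\t{rnext}\t{pnext}\t{tlen}\t{seq}\t{qual}{tags}\n"
    )


def write_sam(path, lines, header_text=SAM_HEADER):
    path.write_text(header_text + "".join(lines))
    return path
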