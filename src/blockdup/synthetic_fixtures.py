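"""Deterministic generator of coordinate-sorted SAM/BAM files with known
duplicate structure.

Templates are original molecules; a duplicate template copies an earlier
template's library, unclipped 5' coordinates, strands and orientation but
re-draws clipping (so the recorded position can differ while the duplicate
key matches) and base qualities (so scores differ, exercising best-member
selection).  Optical copies additionally land on the original's tile within
a 50-pixel box.  Discordant pairs place the mate on another reference,
forcing orphan resolution across distant blocks.  Every stochastic choice
flows from the single seed, so one spec yields one byte sequence.

The generator emulates the coordinate structure, pairing and duplicate
geometry of short-read alignments — not sequence content, error profiles or
aligner behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pysam

from .alignment_model import (
    FLAG_MATE_REVERSE,
    FLAG_PAIRED,
    FLAG_PROPER_PAIR,
    FLAG_READ1,
    FLAG_READ2,
    FLAG_REVERSE,
    read_alignment_file,
)
from .group_marking import Classification, classify_record
from .keying import build_fragment_end, build_pair_ends

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic file."""

    seed: int = 1
    n_templates: int = 10_000
    paired_fraction: float = 0.9
    dup_rate: float = 0.1
    optical_fraction: float = 0.2
    read_length: int = 150
    clip_prob: float = 0.2
    max_clip: int = 20
    ref_lengths: tuple[int, ...] = (1_000_000, 800_000)
    insert_mean: float = 300.0
    insert_sd: float = 50.0
    qual_mean: float = 30.0
    qual_sd: float = 5.0
    discordant_fraction: float = 0.01
    libraries: tuple[str, ...] = ("lib1",)


#: qname -> ("unique", None) | ("pcr_duplicate_of", orig) | ("optical_duplicate_of", orig)
GroundTruth = dict


@dataclass
class _Site:
    """Geometry shared by every member of a duplicate cluster."""

    library_i: int
    paired: bool
    ref1: int
    u1: int  # unclipped 5' of the forward end (or the single end)
    strand1: str
    ref2: int = -1
    u2: int = 0
    strand2: str = "R"
    read1_is_first: bool = True
    location: tuple[int, int, int] = (0, 0, 0)


def generate_fixture(spec: FixtureSpec, out_path, truth_path=None) -> GroundTruth:
    """Write a coordinate-sorted SAM/BAM and return its ground-truth table."""
    rng = np.random.default_rng(spec.seed)
    used_names: set[tuple[int, int, int]] = set()
    guard = spec.read_length + spec.max_clip + 10

    def draw_location(near: Optional[tuple[int, int, int]] = None) -> tuple[int, int, int]:
        for _ in range(10_000):
            if near is not None:
                tile = near[0]
                x = max(0, near[1] + int(rng.integers(-50, 51)))
                y = max(0, near[2] + int(rng.integers(-50, 51)))
            else:
                tile = int(rng.integers(1101, 1117))
                x = int(rng.integers(1000, 100_001))
                y = int(rng.integers(1000, 100_001))
            if (tile, x, y) not in used_names:
                used_names.add((tile, x, y))
                return tile, x, y
        raise RuntimeError("could not draw a unique flow-cell location")

    def qname_of(loc: tuple[int, int, int]) -> str:
        return f"sim{spec.seed}:1:FCX:1:{loc[0]}:{loc[1]}:{loc[2]}"

    def new_site() -> _Site:
        lib_i = int(rng.integers(len(spec.libraries)))
        paired = bool(rng.random() < spec.paired_fraction)
        ref1 = int(rng.integers(len(spec.ref_lengths)))
        if not paired:
            strand = "R" if rng.random() < 0.5 else "F"
            u = int(rng.integers(guard, spec.ref_lengths[ref1] - guard))
            return _Site(lib_i, False, ref1, u, strand, location=draw_location())
        if rng.random() < spec.discordant_fraction and len(spec.ref_lengths) > 1:
            ref2 = int(rng.integers(len(spec.ref_lengths) - 1))
            if ref2 >= ref1:
                ref2 += 1
            u1 = int(rng.integers(guard, spec.ref_lengths[ref1] - guard))
            u2 = int(rng.integers(guard, spec.ref_lengths[ref2] - guard))
            strand2 = "R" if rng.random() < 0.5 else "F"
            return _Site(
                lib_i, True, ref1, u1, "F", ref2, u2, strand2,
                read1_is_first=bool(rng.random() < 0.5), location=draw_location(),
            )
        insert = max(int(rng.normal(spec.insert_mean, spec.insert_sd)), spec.read_length + 10)
        u1 = int(rng.integers(guard, spec.ref_lengths[ref1] - guard - insert))
        return _Site(
            lib_i, True, ref1, u1, "F", ref1, u1 + insert - 1, "R",
            read1_is_first=bool(rng.random() < 0.5), location=draw_location(),
        )

    def emit_read(site_ref: int, u: int, strand: str) -> dict:
        """Place one read: clipping re-drawn per read, key preserved."""
        lead = trail = 0
        if rng.random() < spec.clip_prob:
            lead = int(rng.integers(0, spec.max_clip + 1))
            trail = int(rng.integers(0, spec.max_clip + 1))
        mlen = spec.read_length - lead - trail
        if strand == "F":
            pos = u + lead
        else:
            pos = u - trail - mlen + 1
        cig = []
        if lead:
            cig.append((4, lead))
        cig.append((0, mlen))
        if trail:
            cig.append((4, trail))
        quals = np.clip(
            np.rint(rng.normal(spec.qual_mean, spec.qual_sd, spec.read_length)), 2, 41
        ).astype(np.uint8)
        seq = _BASES[rng.integers(0, 4, spec.read_length)].tobytes().decode()
        return {"ref": site_ref, "pos": pos, "strand": strand, "cigar": cig,
                "quals": quals, "seq": seq}

    truth: GroundTruth = {}
    originals: list[tuple[str, _Site]] = []
    rows = []  # (ref_id, pos, qname, which_end, record dict)

    for _ in range(spec.n_templates):
        if originals and rng.random() < spec.dup_rate:
            orig_qname, site = originals[int(rng.integers(len(originals)))]
            optical = rng.random() < spec.optical_fraction
            loc = draw_location(near=site.location if optical else None)
            qname = qname_of(loc)
            truth[qname] = (
                ("optical_duplicate_of", orig_qname) if optical else ("pcr_duplicate_of", orig_qname)
            )
            site = replace(site, location=loc)
        else:
            site = new_site()
            qname = qname_of(site.location)
            truth[qname] = ("unique", None)
            originals.append((qname, site))

        if not site.paired:
            r = emit_read(site.ref1, site.u1, site.strand1)
            r["flag"] = FLAG_REVERSE if site.strand1 == "R" else 0
            r["lib_i"] = site.library_i
            r["qname"] = qname
            r["mate"] = None
            rows.append(r)
            continue

        r1 = emit_read(site.ref1, site.u1, site.strand1)
        r2 = emit_read(site.ref2, site.u2, site.strand2)
        concordant = site.ref1 == site.ref2
        for r, other, first in ((r1, r2, True), (r2, r1, False)):
            flag = FLAG_PAIRED
            if concordant:
                flag |= FLAG_PROPER_PAIR
            flag |= FLAG_READ1 if (first == site.read1_is_first) else FLAG_READ2
            if r["strand"] == "R":
                flag |= FLAG_REVERSE
            if other["strand"] == "R":
                flag |= FLAG_MATE_REVERSE
            r["flag"] = flag
            r["lib_i"] = site.library_i
            r["qname"] = qname
            r["mate"] = other
        rows.append(r1)
        rows.append(r2)

    rows.sort(key=lambda r: (r["ref"], r["pos"], r["qname"], r["flag"] & FLAG_READ2))

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": f"chr{i + 1}", "LN": int(ln)} for i, ln in enumerate(spec.ref_lengths)
        ],
        "RG": [
            {"ID": f"rg{i}", "LB": lib, "SM": "synthetic", "PL": "ILLUMINA"}
            for i, lib in enumerate(spec.libraries)
        ],
    }
    mode = "wb" if str(out_path).endswith(".bam") else "wh"
    with pysam.AlignmentFile(str(out_path), mode, header=header) as out:
        for r in rows:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = r["qname"]
            seg.flag = r["flag"]
            seg.reference_id = r["ref"]
            seg.reference_start = r["pos"] - 1
            seg.mapping_quality = 60
            seg.cigartuples = r["cigar"]
            seg.query_sequence = r["seq"]
            seg.query_qualities = r["quals"]
            mate = r["mate"]
            if mate is not None:
                seg.next_reference_id = mate["ref"]
                seg.next_reference_start = mate["pos"] - 1
                if r["ref"] == mate["ref"]:
                    left = min(r["pos"], mate["pos"])
                    right = max(
                        r["pos"] + sum(ln for op, ln in r["cigar"] if op == 0),
                        mate["pos"] + sum(ln for op, ln in mate["cigar"] if op == 0),
                    )
                    tlen = right - left
                    seg.template_length = tlen if r["pos"] <= mate["pos"] else -tlen
            else:
                seg.next_reference_id = -1
                seg.next_reference_start = -1
            seg.set_tag("RG", f"rg{r['lib_i']}")
            out.write(seg)

    if truth_path is not None:
        save_ground_truth(truth, truth_path)
    return truth


def save_ground_truth(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("QNAME\tSTATUS\tORIGINAL\n")
        for qname in sorted(truth):
            status, orig = truth[qname]
            fh.write(f"{qname}\t{status}\t{orig or ''}\n")


def load_ground_truth(path) -> GroundTruth:
    truth: GroundTruth = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            qname, status, orig = line.rstrip("\n").split("\t")
            truth[qname] = (status, orig or None)
    return truth


def truth_to_expected_flags(truth: GroundTruth, path, qual_floor: int = 15, cap: int = 32767) -> set[int]:
    """Predict exactly which record indices must carry the duplicate flag.

    Third, independent route besides the two engines: starting from the
    generator's cluster table, recompute keys and scores from the file and
    apply the best-score / least-qname retention rules inline.  Clusters
    that collide on a key by chance (including truth-unique templates) are
    merged, exactly as any key-based tool must treat them.  Raises if a
    duplicate template's key does not match its original's — a generator
    defect, not a marking one.
    """
    header, stream = read_alignment_file(path)
    records = list(stream)

    by_qname: dict[str, list] = {}
    frag_ends = []
    for rec in records:
        if classify_record(rec) is Classification.NOT_CONSIDERED:
            continue
        fe = build_fragment_end(rec, header, qual_floor, cap)
        if classify_record(rec) is Classification.PAIRABLE:
            by_qname.setdefault(rec.qname, []).append(rec)
            fe_pairable = True
        else:
            fe_pairable = False
        frag_ends.append((fe, fe_pairable))

    pair_key_of: dict[str, tuple] = {}
    pair_groups: dict[tuple, list] = {}
    for qname, recs in by_qname.items():
        pe = build_pair_ends(recs[0], recs[1], header, qual_floor, cap)
        pair_key_of[qname] = pe.key
        pair_groups.setdefault(pe.key, []).append(pe)

    frag_key_of: dict[str, tuple] = {}
    frag_groups: dict[tuple, list] = {}
    for fe, pairable in frag_ends:
        if not pairable:
            frag_key_of[fe.qname] = fe.key
        frag_groups.setdefault(fe.key, []).append(fe)

    # generator invariant: every duplicate template shares its original's key
    for qname, (status, orig) in truth.items():
        if orig is None:
            continue
        if qname in pair_key_of and orig in pair_key_of:
            if pair_key_of[qname] != pair_key_of[orig]:
                raise AssertionError(f"{qname} does not share {orig}'s pair key")
        elif qname in frag_key_of and orig in frag_key_of:
            if frag_key_of[qname] != frag_key_of[orig]:
                raise AssertionError(f"{qname} does not share {orig}'s fragment key")

    expected: set[int] = set()
    for grp in pair_groups.values():
        keep = min(grp, key=lambda p: (-p.score, p.qname))
        for pe in grp:
            if pe is not keep:
                expected.update(pe.record_indices)
    for grp in frag_groups.values():
        lone = [fe for fe in grp if not fe.is_paired_end]
        if not lone:
            continue
        if len(lone) < len(grp):
            expected.update(fe.record_index for fe in lone)
        else:
            keep = min(lone, key=lambda f: (-f.score, f.qname))
            expected.update(fe.record_index for fe in lone if fe is not keep)
    return expected


def validation_suite(base_seed: int = 1, n_templates: int = 10_000) -> list[FixtureSpec]:
    """The ten-fixture condition grid used for identity validation:
    duplication rates {0, 0.1, 0.3}, clip probabilities {0, 0.5},
    discordant-mate fractions {0, 0.05}, one to three libraries."""
    grid = [
        (0.0, 0.0, 0.0, 1),
        (0.1, 0.0, 0.0, 1),
        (0.3, 0.0, 0.0, 1),
        (0.1, 0.5, 0.0, 1),
        (0.3, 0.5, 0.0, 2),
        (0.1, 0.0, 0.05, 1),
        (0.3, 0.5, 0.05, 3),
        (0.0, 0.5, 0.05, 2),
        (0.1, 0.5, 0.05, 3),
        (0.3, 0.0, 0.05, 2),
    ]
    return [
        FixtureSpec(
            seed=base_seed + i,
            n_templates=n_templates,
            dup_rate=dup,
            clip_prob=clip,
            discordant_fraction=disc,
            libraries=tuple(f"lib{j + 1}" for j in range(nlib)),
        )
        for i, (dup, clip, disc, nlib) in enumerate(grid)
    ]
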