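"""Toy exact aligner and the three alignment-filtering steps.

Real junction libraries arrive as SAM produced by an external aligner; the
built-in aligner only places error-free reads on synthetic genomes by exact
substring search so that the downstream contracts can be tested without any
external tool. Filtering applies, in order: flag/quality filtering (MAPQ >=
30, exclude flag mask 3852, require flag mask 3), positional PCR-duplicate
removal on fragment outer coordinates, and removal of read pairs whose R1
carries more than 5 soft-clipped bases at its sequencing 5' end.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio.Seq import reverse_complement

from .simulate import ToyGenome

EXCLUDE_FLAG_MASK = 3852  # unmapped|mate-unmapped|secondary|qcfail|dup|supplementary
REQUIRE_FLAG_MASK = 3  # paired, proper pair

_REF_CONSUMING = {0, 2, 7, 8}  # M, D, =, X


def make_header(genome: ToyGenome) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": name, "LN": length}
                for name, length in genome.chrom_lengths.items()
            ],
        }
    )


def _find_all(sub: str, genome: ToyGenome, limit: int = 2) -> list[tuple[str, int, str]]:
    """Up to ``limit`` exact placements of ``sub`` on either strand."""
    hits: list[tuple[str, int, str]] = []
    rc = reverse_complement(sub)
    for name, seq in genome.records:
        for query, strand in ((sub, "+"), (rc, "-")):
            i = seq.find(query)
            while i != -1:
                hits.append((name, i, strand))
                if len(hits) >= limit:
                    return hits
                i = seq.find(query, i + 1)
    return hits


def _segment(
    header: pysam.AlignmentHeader,
    name: str,
    seq: str,
    qual: str,
    flag: int,
    ref: str | None,
    pos: int,
    mapq: int,
) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = seq
    a.query_qualities = pysam.qualitystring_to_array(qual)
    a.flag = flag
    if ref is not None:
        a.reference_id = header.get_tid(ref)
        a.reference_start = pos
        a.mapping_quality = mapq
        a.cigarstring = f"{len(seq)}M"
    else:
        a.reference_id = -1
        a.reference_start = -1
        a.mapping_quality = 0
    return a


def align_toy(pairs: Iterable, genome: ToyGenome) -> list[pysam.AlignedSegment]:
    """Place trimmed read pairs on a toy genome by exact substring search.

    Unique placements get MAPQ 60; ambiguous ones MAPQ 0; reads that occur
    nowhere (e.g. containing errors or Ns) are flagged unmapped. Proper-pair
    flags require both mates uniquely placed on the same contig in FR
    orientation within a 2 kb span.
    """
    records: list[pysam.AlignedSegment] = []
    header = make_header(genome)
    for pair in pairs:
        hits1 = _find_all(pair.r1, genome)
        hits2 = _find_all(pair.r2, genome)
        place1 = hits1[0] if len(hits1) >= 1 else None
        place2 = hits2[0] if len(hits2) >= 1 else None
        mapq1 = 60 if len(hits1) == 1 else 0
        mapq2 = 60 if len(hits2) == 1 else 0
        proper = False
        if place1 and place2 and len(hits1) == 1 and len(hits2) == 1:
            c1, p1, s1 = place1
            c2, p2, s2 = place2
            if c1 == c2 and s1 != s2:
                lo = min(p1, p2)
                hi = max(p1 + len(pair.r1), p2 + len(pair.r2))
                proper = hi - lo <= 2000

        def flags(place, mate_place, is_r1: bool) -> int:
            f = 1 | (64 if is_r1 else 128)
            if proper:
                f |= 2
            if place is None:
                f |= 4
            elif place[2] == "-":
                f |= 16
            if mate_place is None:
                f |= 8
            elif mate_place[2] == "-":
                f |= 32
            return f

        for place, mate_place, seq, qual, is_r1, mapq in (
            (place1, place2, pair.r1, pair.q1, True, mapq1),
            (place2, place1, pair.r2, pair.q2, False, mapq2),
        ):
            if place is not None and place[2] == "-":
                # SAM stores the forward-reference orientation of the read
                seq, qual = reverse_complement(seq), qual[::-1]
            a = _segment(
                header,
                pair.name,
                seq,
                qual,
                flags(place, mate_place, is_r1),
                place[0] if place else None,
                place[1] if place else 0,
                mapq,
            )
            if mate_place is not None:
                a.next_reference_id = header.get_tid(mate_place[0])
                a.next_reference_start = mate_place[1]
            records.append(a)
        # template length for proper pairs
        if proper:
            r1a, r2a = records[-2], records[-1]
            lo = min(r1a.reference_start, r2a.reference_start)
            hi = max(r1a.reference_end, r2a.reference_end)
            tlen = hi - lo
            for a in (r1a, r2a):
                a.template_length = tlen if not a.is_reverse else -tlen
    return records


def write_sam(
    records: Sequence[pysam.AlignedSegment],
    path: str | Path,
    header: pysam.AlignmentHeader,
) -> None:
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            out.write(rec)


def read_sam(path: str | Path) -> tuple[list[pysam.AlignedSegment], pysam.AlignmentHeader]:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        records = list(fh)
        return records, fh.header


def r1_5p_softclip(rec: pysam.AlignedSegment) -> int:
    """Soft-clipped bases at the sequencing 5' end of a mapped read.

    The sequencing 5' end is the leftmost CIGAR element for forward
    alignments and the rightmost for reverse alignments; that end carries
    the IR-genome junction on R1.
    """
    cig = rec.cigartuples
    if not cig:
        return 0
    op, length = cig[-1] if rec.is_reverse else cig[0]
    return length if op == 4 else 0


def reference_span(rec: pysam.AlignedSegment) -> int:
    return sum(length for op, length in (rec.cigartuples or []) if op in _REF_CONSUMING)


def filter_alignments(
    records: Iterable[pysam.AlignedSegment],
    min_mapq: int = 30,
    exclude_flag: int = EXCLUDE_FLAG_MASK,
    require_flag: int = REQUIRE_FLAG_MASK,
    max_r1_5p_softclip: int = 5,
) -> tuple[list[pysam.AlignedSegment], dict]:
    """Apply flag/quality and R1-soft-clip filtering, keeping whole pairs.

    A record survives the per-record rules iff mapq >= ``min_mapq``, no bit
    of ``exclude_flag`` is set and every bit of ``require_flag`` is set. A
    pair survives iff both mates survive and the R1 carries at most
    ``max_r1_5p_softclip`` soft-clipped bases at its 5' end; orphans are
    dropped. Returns survivors plus a per-rule removal log.
    """
    log = {
        "records_in": 0,
        "fail_mapq": 0,
        "fail_flag": 0,
        "fail_r1_softclip_pairs": 0,
        "orphans": 0,
        "records_out": 0,
    }
    by_name: dict[str, dict[str, pysam.AlignedSegment]] = {}
    for rec in records:
        log["records_in"] += 1
        if rec.flag & exclude_flag:
            log["fail_flag"] += 1
            continue
        if rec.flag & require_flag != require_flag:
            log["fail_flag"] += 1
            continue
        if rec.mapping_quality < min_mapq:
            log["fail_mapq"] += 1
            continue
        slot = "r1" if rec.is_read1 else "r2"
        by_name.setdefault(rec.query_name, {})[slot] = rec

    survivors: list[pysam.AlignedSegment] = []
    for name in sorted(by_name):
        mates = by_name[name]
        if "r1" not in mates or "r2" not in mates:
            log["orphans"] += len(mates)
            continue
        if r1_5p_softclip(mates["r1"]) > max_r1_5p_softclip:
            log["fail_r1_softclip_pairs"] += 1
            continue
        survivors.extend((mates["r1"], mates["r2"]))
    log["records_out"] = len(survivors)
    return survivors, log


def fragment_key(
    r1: pysam.AlignedSegment, r2: pysam.AlignedSegment
) -> tuple[str, int, int, str]:
    """Positional identity of the sequenced fragment (both mates' outer ends)."""
    start = min(r1.reference_start, r2.reference_start)
    end = max(r1.reference_end, r2.reference_end)
    return (r1.reference_name, start, end, "R" if r1.is_reverse else "F")


def deduplicate_fragments(
    records: Iterable[pysam.AlignedSegment],
) -> tuple[list[pysam.AlignedSegment], int]:
    """Collapse pairs sharing a fragment key to one representative pair.

    The representative is the pair with the highest summed MAPQ; ties break
    to the first pair in (reference, start, name) order. Returns surviving
    records and the number of duplicate pairs removed.
    """
    pairs: dict[str, dict[str, pysam.AlignedSegment]] = {}
    for rec in records:
        pairs.setdefault(rec.query_name, {})["r1" if rec.is_read1 else "r2"] = rec
    complete = [
        (name, mates["r1"], mates["r2"])
        for name, mates in pairs.items()
        if "r1" in mates and "r2" in mates
    ]
    complete.sort(key=lambda t: (t[1].reference_name, t[1].reference_start, t[0]))
    best: dict[tuple, tuple[int, str, pysam.AlignedSegment, pysam.AlignedSegment]] = {}
    order: list[tuple] = []
    n_pairs = 0
    for name, r1, r2 in complete:
        n_pairs += 1
        key = fragment_key(r1, r2)
        score = r1.mapping_quality + r2.mapping_quality
        if key not in best:
            best[key] = (score, name, r1, r2)
            order.append(key)
        elif score > best[key][0]:
            best[key] = (score, name, r1, r2)
    survivors: list[pysam.AlignedSegment] = []
    for key in order:
        _, _, r1, r2 = best[key]
        survivors.extend((r1, r2))
    return survivors, n_pairs - len(order)
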