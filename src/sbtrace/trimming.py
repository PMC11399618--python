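"""Four-step structured trimming of junction read pairs.

Each read pair carries a fixed construct around the genomic junction
sequence; trimming peels it off in four ordered stages, each an anchored or
3'-adjacent approximate adapter match with an absolute edit-distance budget
and a minimum surviving length of 20 bp:

  1. R1/R2 outer adapter trimming (5'-anchored, up to 5 errors)
  2. IR (inverted repeat) trimming on R1 (5'-anchored, up to 4 errors)
  3. R1/R2 adapter readthrough trimming (3'-adjacent, up to 4 errors)
  4. IR readthrough trimming on R2 (3'-adjacent, up to 3 errors)

What survives is genomic-only sequence whose R1 5' end sits on the first
base downstream of the integrated transposon. Stage order matters for
readthrough-containing pairs and is pinned.
"""

from __future__ import annotations

import dataclasses
import gzip
from pathlib import Path
from typing import Iterable, Iterator

import edlib
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .simulate import (
    IR_JUNCTION,
    R1_PRIMER_ADAPTER,
    R2_PRIMER_ADAPTER,
    TN5_MOSAIC_END,
)
from Bio.Seq import reverse_complement

_N_EQUALITIES = [("N", b) for b in "ACGT"]
MIN_OVERLAP = 3  # shortest 3'-adapter overlap considered a real match


@dataclasses.dataclass(frozen=True)
class AdapterSpec:
    """One adapter-matching rule; ``pattern`` may contain N wildcards."""

    pattern: str
    end: str  # "anchored_5p" | "adjacent_3p"
    applies_to: str  # "R1" | "R2"
    max_errors: int
    min_len_after: int = 20
    required: bool = False

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty adapter pattern")
        if self.max_errors < 0:
            raise ValueError("max_errors must be >= 0")
        if self.end not in ("anchored_5p", "adjacent_3p"):
            raise ValueError(f"unknown end: {self.end}")


@dataclasses.dataclass
class ReadPair:
    name: str
    r1: str
    q1: str
    r2: str
    q2: str


@dataclasses.dataclass
class StageResult:
    stage: int
    r1_matched: bool = False
    r1_removed: int = 0
    r2_matched: bool = False
    r2_removed: int = 0


@dataclasses.dataclass
class TrimmedPair:
    name: str
    r1: str
    q1: str
    r2: str
    q2: str
    stage_log: list[StageResult] = dataclasses.field(default_factory=list)
    discarded: str | None = None


def match_anchored(seq: str, spec: AdapterSpec) -> int | None:
    """Locate ``spec.pattern`` in ``seq``; return the cut coordinate.

    For 5'-anchored specs the return value is the length of the matched
    prefix (bases to remove from the start); for 3'-adjacent specs it is the
    index at which the read is truncated (``seq[:cut]`` is kept). ``None``
    means no match within the error budget — the read is left untouched.
    """
    if not seq:
        return None
    if spec.end == "anchored_5p":
        res = edlib.align(
            spec.pattern,
            seq,
            mode="SHW",
            task="locations",
            k=spec.max_errors,
            additionalEqualities=_N_EQUALITIES,
        )
        if res["editDistance"] == -1:
            return None
        # maximal trimming: the right-most end among best-scoring prefixes
        return max(end for _, end in res["locations"]) + 1

    # 3'-adjacent: full occurrence anywhere, else a partial match hanging
    # off the 3' end (readthrough truncated by the read length).
    res = edlib.align(
        spec.pattern,
        seq,
        mode="HW",
        task="locations",
        k=spec.max_errors,
        additionalEqualities=_N_EQUALITIES,
    )
    if res["editDistance"] != -1:
        return min(start for start, _ in res["locations"])
    max_overlap = min(len(spec.pattern) - 1, len(seq))
    for overlap in range(max_overlap, MIN_OVERLAP - 1, -1):
        start = len(seq) - overlap
        allowed = (spec.max_errors * overlap) // len(spec.pattern)
        mism = 0
        for p, s in zip(spec.pattern[:overlap], seq[start:]):
            if p != "N" and p != s:
                mism += 1
                if mism > allowed:
                    break
        if mism <= allowed:
            return start
    return None


def default_stages(require_ir: bool = True) -> list[list[AdapterSpec]]:
    """The pinned four-stage trimming configuration.

    ``require_ir`` controls whether a pair whose R1 lacks the stage-2 IR
    junction is discarded (recommended for insertion calling) or passed
    through untrimmed at that stage (strict replication of an adapter
    trimmer's pass-through default).
    """
    rc = reverse_complement
    return [
        [  # stage 1: outer adapters, 5'-anchored
            AdapterSpec("NNNN" + R1_PRIMER_ADAPTER, "anchored_5p", "R1", 5),
            AdapterSpec(
                R2_PRIMER_ADAPTER + "N" * 8 + TN5_MOSAIC_END, "anchored_5p", "R2", 5
            ),
        ],
        [  # stage 2: IR junction on R1
            AdapterSpec(IR_JUNCTION, "anchored_5p", "R1", 4, required=require_ir),
        ],
        [  # stage 3: adapter readthrough on both mates
            AdapterSpec(
                rc(TN5_MOSAIC_END) + "N" * 8 + rc(R2_PRIMER_ADAPTER),
                "adjacent_3p",
                "R1",
                4,
            ),
            AdapterSpec(rc(R1_PRIMER_ADAPTER) + "N" * 4, "adjacent_3p", "R2", 4),
        ],
        [  # stage 4: IR readthrough on R2
            AdapterSpec(rc(IR_JUNCTION), "adjacent_3p", "R2", 3),
        ],
    ]


def trim_pair(pair: ReadPair, stages: list[list[AdapterSpec]] | None = None) -> TrimmedPair:
    """Apply the staged trimming rules to one read pair."""
    if stages is None:
        stages = default_stages()
    out = TrimmedPair(pair.name, pair.r1, pair.q1, pair.r2, pair.q2)
    for stage_no, specs in enumerate(stages, start=1):
        result = StageResult(stage=stage_no)
        min_len = 20
        for spec in specs:
            min_len = spec.min_len_after
            seq = out.r1 if spec.applies_to == "R1" else out.r2
            cut = match_anchored(seq, spec)
            if cut is None:
                if spec.required:
                    out.stage_log.append(result)
                    out.discarded = f"no-ir stage {stage_no}"
                    return out
                continue
            if spec.end == "anchored_5p":
                new_seq, removed = seq[cut:], cut
                if spec.applies_to == "R1":
                    out.q1 = out.q1[cut:]
                else:
                    out.q2 = out.q2[cut:]
            else:
                new_seq, removed = seq[:cut], len(seq) - cut
                if spec.applies_to == "R1":
                    out.q1 = out.q1[:cut]
                else:
                    out.q2 = out.q2[:cut]
            if spec.applies_to == "R1":
                out.r1 = new_seq
                result.r1_matched, result.r1_removed = True, removed
            else:
                out.r2 = new_seq
                result.r2_matched, result.r2_removed = True, removed
        out.stage_log.append(result)
        if len(out.r1) < min_len or len(out.r2) < min_len:
            out.discarded = f"min-length stage {stage_no}"
            return out
    return out


def _open_maybe_gz(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_read_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[ReadPair]:
    """Stream synchronized read pairs from two FASTQ files."""
    with _open_maybe_gz(r1_path) as f1, _open_maybe_gz(r2_path) as f2:
        it1, it2 = FastqGeneralIterator(f1), FastqGeneralIterator(f2)
        for i, ((n1, s1, q1), (n2, s2, q2)) in enumerate(zip(it1, it2)):
            base1, base2 = n1.split()[0], n2.split()[0]
            if base1.endswith("/1"):
                base1 = base1[:-2]
            if base2.endswith("/2"):
                base2 = base2[:-2]
            if base1 != base2:
                raise ValueError(f"read pair mismatch at record {i}: {n1} vs {n2}")
            yield ReadPair(base1, s1, q1, s2, q2)


def trim_pairs(
    pairs: Iterable[ReadPair], stages: list[list[AdapterSpec]] | None = None
) -> tuple[list[TrimmedPair], dict]:
    """Trim a stream of pairs; return survivors and a per-stage summary."""
    if stages is None:
        stages = default_stages()
    survivors: list[TrimmedPair] = []
    summary = {
        "pairs_in": 0,
        "pairs_out": 0,
        "discarded": {},
    }
    for pair in pairs:
        summary["pairs_in"] += 1
        tp = trim_pair(pair, stages)
        if tp.discarded is None:
            survivors.append(tp)
            summary["pairs_out"] += 1
        else:
            summary["discarded"][tp.discarded] = (
                summary["discarded"].get(tp.discarded, 0) + 1
            )
    return survivors, summary


def trim_fastq(
    r1_path: str | Path,
    r2_path: str | Path,
    out_prefix: str | Path,
    require_ir: bool = True,
) -> dict:
    """File-to-file trimming; writes trimmed FASTQ pair and a summary TSV."""
    survivors, summary = trim_pairs(
        iter_read_pairs(r1_path, r2_path), default_stages(require_ir=require_ir)
    )
    p1, p2 = Path(f"{out_prefix}_R1.fastq"), Path(f"{out_prefix}_R2.fastq")
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for tp in survivors:
            f1.write(f"@{tp.name}/1\n{tp.r1}\n+\n{tp.q1}\n")
            f2.write(f"@{tp.name}/2\n{tp.r2}\n+\n{tp.q2}\n")
    with open(f"{out_prefix}_trim_summary.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"pairs_in\t{summary['pairs_in']}\n")
        fh.write(f"pairs_out\t{summary['pairs_out']}\n")
        for reason, n in sorted(summary["discarded"].items()):
            fh.write(f"discarded[{reason}]\t{n}\n")
    return summary
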