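"""Insertion-site calling, 5-bp merging, artifact filtering and replicate consensus.

Site tables are pandas DataFrames with columns ``chrom`` (str), ``pos``
(0-based int, the first genomic base downstream of the transposon on the
junction strand), ``strand`` ('+'/'-') and ``count`` (deduplicated fragment
support). (chrom, pos, strand) is unique within a table.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .alignment import reference_span

SITE_COLUMNS = ["chrom", "pos", "strand", "count"]


def empty_site_table() -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=np.int64),
         "strand": pd.Series(dtype=str), "count": pd.Series(dtype=np.int64)}
    )


def call_read_insertion(record: pysam.AlignedSegment) -> tuple[str, int, str]:
    """Junction coordinate of a surviving R1: its 5'-most non-soft-clipped base.

    Forward R1 -> the alignment start (leading soft clips consume no
    reference); reverse R1 -> the last reference-consuming base of the
    alignment, reported on the minus strand.
    """
    if record.is_unmapped or not record.is_read1:
        raise ValueError("insertion calling requires a mapped R1 record")
    if record.is_reverse:
        pos = record.reference_start + reference_span(record) - 1
        return (record.reference_name, pos, "-")
    return (record.reference_name, record.reference_start, "+")


def sites_from_alignments(records: Iterable[pysam.AlignedSegment]) -> pd.DataFrame:
    """Tally junction coordinates of the R1 records into a site table."""
    counts: dict[tuple[str, int, str], int] = {}
    for rec in records:
        if not rec.is_read1:
            continue
        key = call_read_insertion(rec)
        counts[key] = counts.get(key, 0) + 1
    if not counts:
        return empty_site_table()
    rows = [(c, p, s, n) for (c, p, s), n in counts.items()]
    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return df.sort_values(["chrom", "strand", "pos"], ignore_index=True)


def _merged_position(positions: np.ndarray, counts: np.ndarray) -> int:
    """Representative coordinate of a cluster: the member with the largest
    count, or the median of the tied members when several share the maximum
    (floored to an integer coordinate for even-sized ties)."""
    top = positions[counts == counts.max()]
    if len(top) == 1:
        return int(top[0])
    return int(np.floor(np.median(top)))


def merge_sites(table: pd.DataFrame, window: int = 5) -> pd.DataFrame:
    """Cluster sites within ``window`` bases (per chrom and strand) and sum counts.

    Clusters are built left-to-right by single linkage: consecutive
    positions at most ``window`` apart chain into one cluster, whose count
    is the member sum and whose position follows the largest-count/median
    rule. ``window=0`` disables merging. Total count is conserved and the
    operation is idempotent.
    """
    if table.empty or window <= 0:
        return table.copy().sort_values(["chrom", "strand", "pos"], ignore_index=True)
    out_rows = []
    for (chrom, strand), grp in table.groupby(["chrom", "strand"], sort=True):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        cnt = grp["count"].to_numpy()
        start = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] > window:
                p = _merged_position(pos[start:i], cnt[start:i])
                out_rows.append((chrom, p, strand, int(cnt[start:i].sum())))
                start = i
    df = pd.DataFrame(out_rows, columns=SITE_COLUMNS)
    return df.sort_values(["chrom", "strand", "pos"], ignore_index=True)


def filter_cross_sample_artifacts(
    tables: Mapping[str, pd.DataFrame],
    min_count: int = 2,
    min_samples: int = 2,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Remove sites supported in several biological samples (method artifacts).

    A (chrom, pos, strand) with count >= ``min_count`` in >= ``min_samples``
    distinct samples is dropped from every sample's table. With a single
    sample the filter is a no-op (with a warning). Returns the filtered
    tables and the table of removed site keys.
    """
    removed_cols = ["chrom", "pos", "strand", "n_samples"]
    if len(tables) < 2:
        warnings.warn("artifact filter needs >= 2 samples; no-op")
        return {k: v.copy() for k, v in tables.items()}, pd.DataFrame(columns=removed_cols)
    support: dict[tuple[str, int, str], int] = {}
    for df in tables.values():
        hits = df[df["count"] >= min_count]
        for chrom, pos, strand in zip(hits["chrom"], hits["pos"], hits["strand"]):
            support[(chrom, int(pos), strand)] = support.get((chrom, int(pos), strand), 0) + 1
    bad = {k for k, n in support.items() if n >= min_samples}
    removed = pd.DataFrame(
        [(c, p, s, support[(c, p, s)]) for c, p, s in sorted(bad)], columns=removed_cols
    )
    out = {}
    for sample, df in tables.items():
        keys = list(zip(df["chrom"], df["pos"].astype(int), df["strand"]))
        mask = np.array([k not in bad for k in keys], dtype=bool) if keys else np.array([], dtype=bool)
        out[sample] = df[mask].reset_index(drop=True)
    return out, removed


def replicate_consensus(
    replicate_tables: Sequence[pd.DataFrame],
    min_replicates: int = 2,
    window: int = 0,
) -> pd.DataFrame:
    """Retain sites seen in at least ``min_replicates`` technical replicates.

    With ``window=0`` replicate sites must agree exactly in coordinate;
    otherwise positions within ``window`` on the same chrom/strand are
    chained (single linkage) and a chain counts as one site supported by the
    replicates it spans, placed at the position with the largest total
    count. Retained sites carry the summed count over supporting replicates.
    """
    if len(replicate_tables) < min_replicates:
        raise ValueError(
            f"need >= {min_replicates} replicate tables, got {len(replicate_tables)}"
        )
    frames = []
    for rep_id, df in enumerate(replicate_tables):
        d = df.copy()
        d["replicate"] = rep_id
        frames.append(d)
    allsites = pd.concat(frames, ignore_index=True)
    if allsites.empty:
        return empty_site_table()
    out_rows = []
    if window <= 0:
        grouped = allsites.groupby(["chrom", "pos", "strand"], sort=True)
        for (chrom, pos, strand), grp in grouped:
            if grp["replicate"].nunique() >= min_replicates:
                out_rows.append((chrom, int(pos), strand, int(grp["count"].sum())))
    else:
        for (chrom, strand), grp in allsites.groupby(["chrom", "strand"], sort=True):
            grp = grp.sort_values("pos")
            pos = grp["pos"].to_numpy()
            cnt = grp["count"].to_numpy()
            rep = grp["replicate"].to_numpy()
            start = 0
            for i in range(1, len(pos) + 1):
                if i == len(pos) or pos[i] - pos[i - 1] > window:
                    if len(set(rep[start:i])) >= min_replicates:
                        # collapse duplicate coordinates before picking the site
                        agg: dict[int, int] = {}
                        for p, c in zip(pos[start:i], cnt[start:i]):
                            agg[int(p)] = agg.get(int(p), 0) + int(c)
                        ps = np.array(sorted(agg))
                        cs = np.array([agg[p] for p in ps])
                        out_rows.append(
                            (chrom, _merged_position(ps, cs), strand, int(cs.sum()))
                        )
                    start = i
    df = pd.DataFrame(out_rows, columns=SITE_COLUMNS)
    return df.sort_values(["chrom", "strand", "pos"], ignore_index=True)


def write_bed(table: pd.DataFrame, path: str | Path, name: str = "site") -> None:
    """Site table as BED6: chrom, pos, pos+1, name, count, strand."""
    with open(path, "w") as fh:
        for row in table.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{name}\t{row.count}\t{row.strand}\n"
            )


def read_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            rows.append((f[0], int(f[1]), f[5], int(f[4])))
    return pd.DataFrame(rows, columns=SITE_COLUMNS)
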