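"""Clonality summaries, insertion-motif logo matrices and karyotype positions.

The clonality report measures the distribution of deduplicated junction
fragments over unique insertion sites; its top-clone fraction is the
headline safety readout (a dominant clone would indicate clonal expansion).
The logo matrix tallies base frequencies in a +/-``flank`` window around the
junction, with position 0 the first base downstream of the transposon on
the junction strand — Sleeping Beauty integration puts T at 0 and A at +1.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .simulate import ToyGenome

LOGO_BASES = "ACGT"


@dataclasses.dataclass
class ClonalityReport:
    sample_id: str
    n_unique_fragments: int
    n_unique_sites: int
    table: pd.DataFrame  # chrom, pos, strand, count, fraction_pct; sorted desc

    @property
    def top_clone_pct(self) -> float:
        if self.table.empty:
            return 0.0
        return float(self.table["fraction_pct"].iloc[0])

    @property
    def site_fractions(self) -> np.ndarray:
        return self.table["fraction_pct"].to_numpy()

    def positions_by_chrom(self) -> dict[str, list[int]]:
        return {
            chrom: sorted(grp["pos"].tolist())
            for chrom, grp in self.table.groupby("chrom")
        }

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def clonality_report(sites: pd.DataFrame, sample_id: str = "sample") -> ClonalityReport:
    """Per-site fragment fractions (percent), sorted by descending fraction."""
    if sites.empty:
        import warnings

        warnings.warn(f"empty site table for {sample_id}")
        return ClonalityReport(sample_id, 0, 0, sites.assign(fraction_pct=[]))
    total = int(sites["count"].sum())
    df = sites.copy()
    df["fraction_pct"] = 100.0 * df["count"] / total
    df = df.sort_values(
        ["fraction_pct", "chrom", "pos"], ascending=[False, True, True],
        ignore_index=True,
    )
    return ClonalityReport(
        sample_id=sample_id,
        n_unique_fragments=total,
        n_unique_sites=len(df),
        table=df,
    )


@dataclasses.dataclass
class LogoMatrix:
    """Per-position base frequencies around the junction.

    ``freq`` is 4 x (2*flank+1) over rows A, C, G, T; column j corresponds
    to offset j - flank from the junction. Columns with coverage 0 (sites
    too close to a contig edge only) are all-zero.
    """

    freq: np.ndarray
    coverage: np.ndarray
    flank: int

    def frequency(self, base: str, offset: int) -> float:
        return float(self.freq[LOGO_BASES.index(base), offset + self.flank])

    def information_content(self) -> np.ndarray:
        """Letter heights in bits: per-column information (2 - Shannon
        entropy) scaled by each base's frequency, as drawn in a logo."""
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(self.freq > 0, self.freq * np.log2(self.freq), 0.0)
        ic = 2.0 + plogp.sum(axis=0)
        ic[self.coverage == 0] = 0.0
        return ic * self.freq

    def to_tsv(self, path: str | Path) -> None:
        cols = [str(i - self.flank) for i in range(2 * self.flank + 1)]
        df = pd.DataFrame(self.freq, index=list(LOGO_BASES), columns=cols)
        df.to_csv(path, sep="\t")


def _genome_lookup(genome) -> Mapping[str, str]:
    if isinstance(genome, ToyGenome):
        return dict(genome.records)
    if isinstance(genome, (str, Path)):
        import pyfaidx

        fa = pyfaidx.Fasta(str(genome))
        return {name: str(fa[name][:]).upper() for name in fa.keys()}
    return genome  # assume mapping chrom -> sequence


def logo_matrix(
    sites: pd.DataFrame,
    genome,
    flank: int = 20,
    weight_by_count: bool = False,
) -> LogoMatrix:
    """Base-frequency matrix in a +/-``flank`` bp window around each site.

    For + sites the window is genome[pos-flank .. pos+flank]; for - sites
    the same genomic window reverse-complemented, so that position 0 always
    reads the first base downstream of the transposon on the junction
    strand. Each unique site contributes once unless ``weight_by_count``;
    sites close to a contig edge contribute only their covered positions.
    """
    seqs = _genome_lookup(genome)
    width = 2 * flank + 1
    counts = np.zeros((4, width), dtype=float)
    coverage = np.zeros(width, dtype=float)
    base_idx = {b: i for i, b in enumerate(LOGO_BASES)}
    for row in sites.itertuples(index=False):
        if row.chrom not in seqs:
            raise KeyError(f"chromosome {row.chrom!r} missing from genome")
        seq = seqs[row.chrom]
        w = float(row.count) if weight_by_count else 1.0
        lo, hi = row.pos - flank, row.pos + flank + 1
        window = seq[max(lo, 0) : min(hi, len(seq))]
        left_pad = max(0, -lo)
        padded = "N" * left_pad + window + "N" * max(0, hi - len(seq))
        if row.strand == "-":
            padded = reverse_complement(padded)
        for j, b in enumerate(padded):
            if b in base_idx:
                counts[base_idx[b], j] += w
                coverage[j] += w
    freq = np.zeros_like(counts)
    nz = coverage > 0
    freq[:, nz] = counts[:, nz] / coverage[nz]
    return LogoMatrix(freq=freq, coverage=coverage, flank=flank)


def karyotype_positions(sites: pd.DataFrame) -> pd.DataFrame:
    """(chrom, pos) pairs for karyotype-style plotting, sorted."""
    return (
        sites[["chrom", "pos"]]
        .sort_values(["chrom", "pos"])
        .reset_index(drop=True)
    )


def plot_karyotype(
    sites: pd.DataFrame, chrom_lengths: Mapping[str, int], path: str | Path
) -> None:
    """Minimal ideogram: one bar per chromosome with site tick marks."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(chrom_lengths)
    fig, ax = plt.subplots(figsize=(8, 0.5 * max(len(chroms), 2) + 1))
    for i, chrom in enumerate(chroms):
        ax.hlines(i, 0, chrom_lengths[chrom], color="lightgray", linewidth=6)
        sub = sites[sites["chrom"] == chrom]
        ax.vlines(sub["pos"], i - 0.2, i + 0.2, color="crimson", linewidth=0.8)
    ax.set_yticks(range(len(chroms)), chroms)
    ax.set_xlabel("position (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
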