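"""Genomic-feature annotation of insertion sites and genome-wide background.

Every base (and hence every site) gets exactly one of six categories under a
fixed precedence: promoter > 3' UTR > exon > intron > downstream > distal
intergenic. Promoters span TSS-2000..TSS+200 in transcript orientation,
downstream windows extend 3 kb past the 3'-most end of each gene, introns
are transcript-span bases not in an exon. The genome-wide background paints
categories onto per-chromosome arrays (highest precedence last), so the
reported fractions are an exact partition of the genome.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

CATEGORIES = ["promoter", "3' UTR", "exon", "intron", "downstream", "distal intergenic"]
_CAT_CODE = {c: i for i, c in enumerate(CATEGORIES)}


@dataclasses.dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open span
    end: int
    exons: list[tuple[int, int]]
    utr3: list[tuple[int, int]]

    @property
    def tss(self) -> int:
        """0-based coordinate of the transcription start site base."""
        return self.start if self.strand == "+" else self.end - 1


@dataclasses.dataclass
class FeatureModel:
    transcripts: list[Transcript]
    chrom_lengths: dict[str, int]
    tss_upstream: int = 2000
    tss_downstream: int = 200
    gene_downstream: int = 3000
    _trees: dict = dataclasses.field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._build()

    def _intervals(self) -> dict[str, dict[str, list[tuple[int, int]]]]:
        """Per-category genomic intervals (0-based half-open), per chrom."""
        out: dict[str, dict[str, list[tuple[int, int]]]] = {
            c: {} for c in CATEGORIES[:-1]
        }

        def add(cat: str, chrom: str, lo: int, hi: int) -> None:
            L = self.chrom_lengths.get(chrom)
            if L is not None:
                lo, hi = max(0, lo), min(L, hi)
            if hi > lo:
                out[cat].setdefault(chrom, []).append((lo, hi))

        gene_span: dict[tuple[str, str, str], tuple[int, int]] = {}
        for t in self.transcripts:
            if t.strand == "+":
                add("promoter", t.chrom, t.tss - self.tss_upstream,
                    t.tss + self.tss_downstream)
            else:
                add("promoter", t.chrom, t.tss - self.tss_downstream + 1,
                    t.tss + self.tss_upstream + 1)
            for lo, hi in t.utr3:
                add("3' UTR", t.chrom, lo, hi)
            for lo, hi in t.exons:
                add("exon", t.chrom, lo, hi)
            add("intron", t.chrom, t.start, t.end)
            key = (t.gene_id, t.chrom, t.strand)
            lo, hi = gene_span.get(key, (t.start, t.end))
            gene_span[key] = (min(lo, t.start), max(hi, t.end))
        for (gene, chrom, strand), (lo, hi) in gene_span.items():
            if strand == "+":
                add("downstream", chrom, hi, hi + self.gene_downstream)
            else:
                add("downstream", chrom, lo - self.gene_downstream, lo)
        return out

    def _build(self) -> None:
        self._trees = {}
        for cat, per_chrom in self._intervals().items():
            for chrom, ivals in per_chrom.items():
                tree = self._trees.setdefault(chrom, {}).setdefault(
                    cat, IntervalTree()
                )
                for lo, hi in ivals:
                    tree.addi(lo, hi)

    def classify(self, chrom: str, pos: int) -> str:
        """Category of a single base under the fixed precedence."""
        trees = self._trees.get(chrom)
        if trees is None:
            return "distal intergenic"
        for cat in CATEGORIES[:-1]:
            tree = trees.get(cat)
            if tree is not None and tree.overlaps_point(pos):
                return cat
        return "distal intergenic"

    def nearest_gene(self, chrom: str, pos: int) -> tuple[str | None, int | None]:
        """Nearest gene by distance to TSS; ties break on gene id.

        The returned distance is signed in transcript orientation: positive
        downstream of the TSS, negative upstream.
        """
        best: tuple[int, str, int] | None = None
        for t in self.transcripts:
            if t.chrom != chrom:
                continue
            delta = pos - t.tss if t.strand == "+" else t.tss - pos
            key = (abs(delta), t.gene_id, delta)
            if best is None or key < best:
                best = key
        if best is None:
            return None, None
        return best[1], best[2]


def build_feature_model(
    gtf_path: str | Path,
    chrom_lengths: Mapping[str, int],
    tss_upstream: int = 2000,
    tss_downstream: int = 200,
    gene_downstream: int = 3000,
) -> FeatureModel:
    """Load transcript models from a GTF into a queryable feature model."""
    import pyranges as pr

    with open(gtf_path) as fh:
        has_records = any(line.strip() and not line.startswith("#") for line in fh)
    if not has_records:
        raise ValueError(f"no usable records in GTF {gtf_path}")
    gr = pr.read_gtf(str(gtf_path))
    df = gr.df  # pyranges converts to 0-based half-open coordinates
    if df.empty or "Feature" not in df.columns:
        raise ValueError(f"no usable records in GTF {gtf_path}")
    tx_rows = df[df["Feature"] == "transcript"]
    if tx_rows.empty:
        raise ValueError(f"GTF {gtf_path} contains no transcript records")
    transcripts: list[Transcript] = []
    for row in tx_rows.itertuples(index=False):
        tid = row.transcript_id
        sub = df[df.get("transcript_id") == tid]
        exons = [
            (int(r.Start), int(r.End))
            for r in sub[sub["Feature"] == "exon"].itertuples(index=False)
        ]
        utr3 = [
            (int(r.Start), int(r.End))
            for r in sub[sub["Feature"] == "three_prime_utr"].itertuples(index=False)
        ]
        transcripts.append(
            Transcript(
                transcript_id=tid,
                gene_id=row.gene_id,
                chrom=str(row.Chromosome),
                strand=str(row.Strand),
                start=int(row.Start),
                end=int(row.End),
                exons=sorted(exons),
                utr3=sorted(utr3),
            )
        )
    return FeatureModel(
        transcripts=transcripts,
        chrom_lengths=dict(chrom_lengths),
        tss_upstream=tss_upstream,
        tss_downstream=tss_downstream,
        gene_downstream=gene_downstream,
    )


def annotate_sites(sites: pd.DataFrame, model: FeatureModel) -> pd.DataFrame:
    """Category, nearest gene and signed TSS distance for each site."""
    import warnings

    rows = []
    for row in sites.itertuples(index=False):
        if row.chrom not in model.chrom_lengths:
            warnings.warn(f"site chromosome {row.chrom!r} absent from model")
        cat = model.classify(row.chrom, int(row.pos))
        gene, dist = model.nearest_gene(row.chrom, int(row.pos))
        rows.append((row.chrom, int(row.pos), row.strand, int(row.count), cat, gene, dist))
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "count", "category", "nearest_gene",
                 "tss_distance"],
    )


def genome_feature_background(model: FeatureModel) -> dict[str, float]:
    """Fraction of the genome in each category (an exact partition).

    Implemented by painting category codes onto per-chromosome arrays in
    reverse precedence order, so each base ends with its highest-precedence
    category. Fractions sum to 1 for any model.
    """
    intervals = model._intervals()
    total = sum(model.chrom_lengths.values())
    counts = {c: 0 for c in CATEGORIES}
    paint_order = ["downstream", "intron", "exon", "3' UTR", "promoter"]
    for chrom, L in model.chrom_lengths.items():
        arr = np.full(L, _CAT_CODE["distal intergenic"], dtype=np.uint8)
        for cat in paint_order:
            for lo, hi in intervals[cat].get(chrom, []):
                arr[lo:hi] = _CAT_CODE[cat]
        codes, n = np.unique(arr, return_counts=True)
        for code, k in zip(codes, n):
            counts[CATEGORIES[code]] += int(k)
    return {c: counts[c] / total for c in CATEGORIES}


def category_fractions(annotated: pd.DataFrame) -> dict[str, float]:
    """Fraction of annotated sites per category (unweighted by count)."""
    if annotated.empty:
        return {c: 0.0 for c in CATEGORIES}
    vc = annotated["category"].value_counts()
    n = len(annotated)
    return {c: float(vc.get(c, 0)) / n for c in CATEGORIES}
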