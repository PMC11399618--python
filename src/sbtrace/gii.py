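"""Genomic Instability Index (GII) from per-sample variant call sets.

A variant key is (chrom, pos, ref, alt) after left-normalization; a key is
*private* to a sample when it occurs in that sample and in no other sample
of the cohort (treated and control pooled), otherwise *shared* for every
sample carrying it. GII = n_private / n_total, computed for all variants and
separately for SNPs and INDELs. Group comparisons use a two-sided
Mann-Whitney rank-sum test (exact enumeration for small cohorts, normal
approximation with tie correction otherwise) and a one-way ANOVA F test.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

VAR_CLASSES = ["all", "SNP", "INDEL"]


@dataclasses.dataclass(frozen=True)
class VariantKey:
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str

    @property
    def var_class(self) -> str:
        return "SNP" if len(self.ref) == 1 and len(self.alt) == 1 else "INDEL"


def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Trim shared suffix then shared prefix (keeping >= 1 base each side).

    This is the standard left-normalization that makes indel identity
    canonical so the private/shared comparison matches exact keys.
    """
    if ref == alt:
        raise ValueError("ref and alt alleles are identical")
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(chrom, pos, ref, alt)


def read_vcf_keys(path: str | Path) -> set[VariantKey]:
    """Normalized variant keys from a VCF; multi-allelic records are split."""
    import pysam

    keys: set[VariantKey] = set()
    dupes = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                if alt in (None, ".", "<NON_REF>", "*"):
                    continue
                key = normalize_variant(rec.chrom, rec.pos, rec.ref, alt)
                if key in keys:
                    dupes += 1
                else:
                    keys.add(key)
    if dupes:
        warnings.warn(f"{path}: {dupes} duplicate variant keys collapsed")
    return keys


def classify_variants(
    cohort: Mapping[str, set[VariantKey]],
) -> dict[str, tuple[set[VariantKey], set[VariantKey]]]:
    """Split each sample's keys into (private, shared) over the whole cohort."""
    if len(cohort) < 2:
        raise ValueError("private/shared classification needs >= 2 samples")
    occurrence: dict[VariantKey, int] = {}
    for keys in cohort.values():
        for k in keys:
            occurrence[k] = occurrence.get(k, 0) + 1
    out = {}
    for sample, keys in cohort.items():
        private = {k for k in keys if occurrence[k] == 1}
        out[sample] = (private, keys - private)
    return out


@dataclasses.dataclass
class GIIResult:
    sample_id: str
    group: str
    counts: dict[str, tuple[int, int]]  # class -> (n_private, n_shared)

    def n_private(self, var_class: str = "all") -> int:
        return self.counts[var_class][0]

    def n_total(self, var_class: str = "all") -> int:
        return sum(self.counts[var_class])

    def gii(self, var_class: str = "all") -> float | None:
        total = self.n_total(var_class)
        if total == 0:
            return None
        return self.counts[var_class][0] / total


def compute_gii(
    sample_id: str,
    group: str,
    private: set[VariantKey],
    shared: set[VariantKey],
) -> GIIResult:
    counts = {}
    for vc in VAR_CLASSES:
        p = sum(1 for k in private if vc == "all" or k.var_class == vc)
        s = sum(1 for k in shared if vc == "all" or k.var_class == vc)
        counts[vc] = (p, s)
    return GIIResult(sample_id=sample_id, group=group, counts=counts)


# ---------------------------------------------------------------------------
# Group comparison statistics
# ---------------------------------------------------------------------------

def exact_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U by full enumeration of rank assignments.

    Mid-ranks handle ties; the two-sided p doubles the smaller tail
    probability and is capped at 1. Returns (U of the first group, p).
    """
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(x + y)
    u_obs = float(ranks[:n1].sum()) - n1 * (n1 + 1) / 2.0
    n_le = n_ge = n_all = 0
    eps = 1e-9
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = float(sum(ranks[i] for i in combo)) - n1 * (n1 + 1) / 2.0
        n_all += 1
        if u <= u_obs + eps:
            n_le += 1
        if u >= u_obs - eps:
            n_ge += 1
    p = min(1.0, 2.0 * min(n_le, n_ge) / n_all)
    return u_obs, p


def asymptotic_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Normal approximation with tie correction and continuity correction."""
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    n = n1 + n2
    ranks = stats.rankdata(x + y)
    u = float(ranks[:n1].sum()) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(np.asarray(x + y, dtype=float), return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)
    return u, min(1.0, 2.0 * stats.norm.sf(max(z, 0.0)))


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], exact_threshold: int = 12
) -> tuple[float, float]:
    """Mann-Whitney U and two-sided p; exact when n1+n2 <= ``exact_threshold``."""
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if len(x) + len(y) <= exact_threshold:
        return exact_rank_sum(x, y)
    return asymptotic_rank_sum(x, y)


def anova_f(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """One-way ANOVA F and p; identical data yields F=0, p=1 by convention."""
    vals = list(x) + list(y)
    if len(set(vals)) == 1:
        warnings.warn("all GII values identical; F=0, p=1 by convention")
        return 0.0, 1.0
    f, p = stats.f_oneway(list(x), list(y))
    return float(f), float(p)


@dataclasses.dataclass
class GroupComparison:
    """Per-variant-class rank-sum and ANOVA results."""

    stats: dict[str, dict[str, float]]  # class -> {U, p_mannwhitney, F, p_anova}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stats).T


def compare_groups(
    results: Sequence[GIIResult], exact_threshold: int = 12
) -> GroupComparison:
    """Compare treated vs control GII for all variants, SNPs and INDELs.

    Samples with an undefined GII in a class (no variants of that class)
    are excluded from that class's comparison.
    """
    groups = sorted({r.group for r in results})
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    g1, g2 = groups[::-1] if "treated" in groups and groups[0] != "treated" else groups
    out: dict[str, dict[str, float]] = {}
    for vc in VAR_CLASSES:
        x = [r.gii(vc) for r in results if r.group == g1 and r.gii(vc) is not None]
        y = [r.gii(vc) for r in results if r.group == g2 and r.gii(vc) is not None]
        if not x or not y:
            continue
        u, p_u = rank_sum_test(x, y, exact_threshold=exact_threshold)
        f, p_f = anova_f(x, y)
        out[vc] = {"U": u, "p_mannwhitney": p_u, "F": f, "p_anova": p_f}
    return GroupComparison(stats=out)


def cohort_gii(
    manifest: Mapping[str, tuple[str, str | Path]] | pd.DataFrame,
    exact_threshold: int = 12,
) -> tuple[list[GIIResult], GroupComparison]:
    """End-to-end GII analysis from per-sample VCF paths.

    ``manifest`` maps sample_id -> (group, vcf_path), or is a DataFrame with
    columns sample_id, group, path.
    """
    if isinstance(manifest, pd.DataFrame):
        manifest = {
            r.sample_id: (r.group, r.path) for r in manifest.itertuples(index=False)
        }
    cohort = {sid: read_vcf_keys(path) for sid, (_, path) in manifest.items()}
    split = classify_variants(cohort)
    results = [
        compute_gii(sid, manifest[sid][0], private, shared)
        for sid, (private, shared) in split.items()
    ]
    return results, compare_groups(results, exact_threshold=exact_threshold)
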