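"""Synthetic data with known ground truth for the junction-sequencing pipeline.

Everything downstream of this module (trimming, alignment filtering, insertion
calling, clonality summaries, GII statistics) is validated against libraries
generated here: toy genomes with an indexed TA-dinucleotide landscape, clonal
populations of Sleeping Beauty-style insertions, TRACE-structured paired reads
with PCR duplicates and adapter readthrough, and variant cohorts with a
controlled private/shared composition.

Read structure emulated (junction strand, 5'->3'):

    R1:  NNNN + CGAGTTTTAATGACTCCAACT + TAAGTGTATGTAAACTTCCGACTTCAACTG + genomic
    R2:  AGTGGCACAGCAGTTAGG + NNNNNNNN + AGATGTGTATAAGAGACAG + revcomp(genomic)

Fragments shorter than the read length produce 3' readthrough into the
reverse complement of the opposite end's adapter construct, which is what the
readthrough trimming stages remove.
"""

from __future__ import annotations

import dataclasses
import gzip
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Seq import reverse_complement

# Adapter constructs flanking the genomic fragment (see module docstring).
R1_PRIMER_ADAPTER = "CGAGTTTTAATGACTCCAACT"
IR_JUNCTION = "TAAGTGTATGTAAACTTCCGACTTCAACTG"
R2_PRIMER_ADAPTER = "AGTGGCACAGCAGTTAGG"
TN5_MOSAIC_END = "AGATGTGTATAAGAGACAG"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class ConfigurationError(ValueError):
    """Invalid generator configuration (bad lengths, fractions, counts)."""


class InfeasibleError(ValueError):
    """Requested population or library cannot be realised on this genome."""


# ---------------------------------------------------------------------------
# Toy genome
# ---------------------------------------------------------------------------

def _scan_ta(seq: str) -> np.ndarray:
    """0-based offsets of every 'TA' dinucleotide in ``seq``."""
    out = []
    i = seq.find("TA")
    while i != -1:
        out.append(i)
        i = seq.find("TA", i + 1)
    return np.asarray(out, dtype=np.int64)


@dataclasses.dataclass
class ToyGenome:
    """Small multi-contig genome with an index of TA dinucleotide positions."""

    records: list[tuple[str, str]]
    ta_positions: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ta_positions:
            self.ta_positions = {name: _scan_ta(seq) for name, seq in self.records}

    def seq(self, chrom: str) -> str:
        for name, seq in self.records:
            if name == chrom:
                return seq
        raise KeyError(chrom)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.records}

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.records:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ToyGenome":
        records: list[tuple[str, str]] = []
        name, chunks = None, []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if name is not None:
                        records.append((name, "".join(chunks)))
                    name, chunks = line[1:].split()[0], []
                elif line:
                    chunks.append(line.upper())
        if name is not None:
            records.append((name, "".join(chunks)))
        return cls(records=records)


def generate_genome(
    n_chrom: int,
    lengths: Sequence[int],
    ta_enrichment: float = 1.0,
    seed: int = 0,
) -> ToyGenome:
    """Generate a random A/C/G/T genome with optional extra TA dinucleotides.

    ``ta_enrichment`` is the expected number of injected TA dinucleotides per
    100 bp on top of the ~1/16 background density of random sequence; 0 leaves
    the background untouched. Deterministic for a given seed.
    """
    lengths = list(lengths)
    if n_chrom != len(lengths):
        raise ConfigurationError(f"n_chrom={n_chrom} but {len(lengths)} lengths given")
    if any(L < 1000 for L in lengths):
        raise ConfigurationError("chromosome lengths must be >= 1000 bp")
    if ta_enrichment < 0:
        raise ConfigurationError("ta_enrichment must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    for i, L in enumerate(lengths):
        arr = rng.choice(_BASES, size=L)
        n_inject = int(round(L * ta_enrichment / 100.0))
        if n_inject:
            pos = rng.choice(L - 1, size=n_inject, replace=False)
            arr[pos] = b"T"
            arr[pos + 1] = b"A"
        records.append((f"chr{i + 1}", arr.tobytes().decode()))
    return ToyGenome(records=records)


# ---------------------------------------------------------------------------
# Clonal insertion populations
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Clone:
    """One insertion clone.

    ``pos`` is the 0-based offset of the T of the target TA dinucleotide.
    The junction coordinate (first genomic base downstream of the transposon
    on the junction strand) is ``pos`` for + insertions and ``pos + 1`` for
    - insertions — the TA target is palindromic, so the downstream flank
    starts with TA on either strand.
    """

    chrom: str
    pos: int
    strand: str
    abundance: float

    @property
    def junction_pos(self) -> int:
        return self.pos if self.strand == "+" else self.pos + 1


@dataclasses.dataclass
class ClonePopulation:
    clones: list[Clone]

    def truth_sites(self) -> list[tuple[str, int, str]]:
        """(chrom, junction_pos, strand) per clone, in clone order."""
        return [(c.chrom, c.junction_pos, c.strand) for c in self.clones]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tjunction_pos\tstrand\tabundance\n")
            for c in self.clones:
                fh.write(
                    f"{c.chrom}\t{c.pos}\t{c.junction_pos}\t{c.strand}\t{c.abundance:.10g}\n"
                )


def simulate_clonal_population(
    genome: ToyGenome,
    n_clones: int,
    abundances: Sequence[float] | None = None,
    alpha: float = 1.0,
    motif: bool = True,
    min_separation: int = 10,
    edge_margin: int = 650,
    seed: int = 0,
) -> ClonePopulation:
    """Place ``n_clones`` insertions on the genome with given clone fractions.

    With ``motif=True`` every insertion targets a TA dinucleotide (the
    Sleeping Beauty signature); otherwise positions are unconstrained.
    ``abundances`` gives explicit clone fractions; when None they are drawn
    from a symmetric Dirichlet(``alpha``). Sites keep ``min_separation`` bp
    between each other and ``edge_margin`` bp from contig ends so that every
    clone yields fully mappable fragments and logo windows; this emulates the
    extreme sparsity of real insertions on a desk-scale contig.
    """
    rng = np.random.default_rng(seed)
    candidates: list[tuple[str, int]] = []
    for name, seq in genome.records:
        if motif:
            pool = genome.ta_positions[name]
        else:
            pool = np.arange(len(seq), dtype=np.int64)
        pool = pool[(pool >= edge_margin) & (pool < len(seq) - edge_margin)]
        candidates.extend((name, int(p)) for p in pool)
    if n_clones > len(candidates):
        raise InfeasibleError(
            f"requested {n_clones} clones but only {len(candidates)} candidate sites"
        )
    order = rng.permutation(len(candidates))
    chosen: list[tuple[str, int]] = []
    taken: dict[str, list[int]] = {}
    for idx in order:
        chrom, pos = candidates[idx]
        near = taken.get(chrom, [])
        if all(abs(pos - q) >= min_separation for q in near):
            chosen.append((chrom, pos))
            taken.setdefault(chrom, []).append(pos)
            if len(chosen) == n_clones:
                break
    if len(chosen) < n_clones:
        raise InfeasibleError("could not place clones with the requested separation")

    if abundances is None:
        ab = rng.dirichlet(np.full(n_clones, float(alpha)))
    else:
        ab = np.asarray(list(abundances), dtype=float)
        if len(ab) != n_clones:
            raise ConfigurationError("abundances length must equal n_clones")
        if abs(ab.sum() - 1.0) > 1e-9:
            raise ConfigurationError("abundances must sum to 1")
    strands = rng.choice(np.array(["+", "-"]), size=n_clones)
    clones = [
        Clone(chrom=c, pos=p, strand=str(s), abundance=float(a))
        for (c, p), s, a in zip(chosen, strands, ab)
    ]
    return ClonePopulation(clones=clones)


# ---------------------------------------------------------------------------
# TRACE libraries
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Fragment:
    clone_index: int
    length: int
    tag4: str
    tag8: str
    duplicate_of: int | None = None


@dataclasses.dataclass
class TraceLibraryTruth:
    """A simulated junction library plus the truth needed to grade recovery."""

    population: ClonePopulation
    fragments: list[Fragment]
    reads: list[tuple[str, str, str, str, str]]  # (name, r1, q1, r2, q2)
    site_counts: dict[int, int]  # clone index -> unique (non-duplicate) fragments

    @property
    def n_unique_fragments(self) -> int:
        return sum(1 for f in self.fragments if f.duplicate_of is None)

    def write_fastq(self, out_prefix: str | Path, compress: bool = False) -> tuple[Path, Path]:
        suffix = ".fastq.gz" if compress else ".fastq"
        p1 = Path(f"{out_prefix}_R1{suffix}")
        p2 = Path(f"{out_prefix}_R2{suffix}")
        op = gzip.open if compress else open
        with op(p1, "wt") as f1, op(p2, "wt") as f2:
            for name, r1, q1, r2, q2 in self.reads:
                f1.write(f"@{name}/1\n{r1}\n+\n{q1}\n")
                f2.write(f"@{name}/2\n{r2}\n+\n{q2}\n")
        return p1, p2

    def write_truth_tsv(self, path: str | Path) -> None:
        pop = self.population
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tstrand\tclone_fraction\tfragment_count\n")
            for i, c in enumerate(pop.clones):
                fh.write(
                    f"{c.chrom}\t{c.junction_pos}\t{c.strand}\t"
                    f"{c.abundance:.10g}\t{self.site_counts.get(i, 0)}\n"
                )

    def truth_site_table(self):
        """Truth as an insertion-site table (chrom, pos, strand, count)."""
        import pandas as pd

        rows = [
            (c.chrom, c.junction_pos, c.strand, self.site_counts.get(i, 0))
            for i, c in enumerate(self.population.clones)
            if self.site_counts.get(i, 0) > 0
        ]
        return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count"])


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        others = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = bytes([others[rng.integers(3)]])
    return arr.tobytes().decode()


def simulate_trace_library(
    pop: ClonePopulation,
    genome: ToyGenome,
    n_fragments: int,
    read_len: int = 150,
    dup_rate: float = 0.0,
    error_rate: float = 0.0,
    frag_len_range: tuple[int, int] = (150, 600),
    seed: int = 0,
) -> TraceLibraryTruth:
    """Simulate a paired-end junction library from a clonal population.

    ``n_fragments`` unique molecules are drawn clone-wise from the abundance
    distribution with fragment lengths uniform over ``frag_len_range``
    (without replacement within a clone, so each unique molecule has a unique
    pair of outer coordinates). PCR duplicates are injected so that a fraction
    ``dup_rate`` of all emitted pairs are re-emissions of existing molecules,
    giving ~ n/(1-dup_rate) total pairs. Errors are uniform substitutions.
    """
    if not pop.clones:
        raise InfeasibleError("empty clone population")
    if n_fragments < 1:
        raise ConfigurationError("n_fragments must be >= 1")
    lo, hi = frag_len_range
    if lo < 25 or hi < lo:
        raise ConfigurationError("invalid fragment length range")
    rng = np.random.default_rng(seed)
    ab = np.array([c.abundance for c in pop.clones])
    ab = ab / ab.sum()

    fragments: list[Fragment] = []
    used_lengths: dict[int, set[int]] = {}
    site_counts: dict[int, int] = {}
    n_unique = 0
    while n_unique < n_fragments:
        if fragments and dup_rate > 0 and rng.random() < dup_rate:
            src = int(rng.integers(len(fragments)))
            # chase to the original molecule so duplicate_of is canonical
            while fragments[src].duplicate_of is not None:
                src = fragments[src].duplicate_of
            f = fragments[src]
            fragments.append(
                Fragment(f.clone_index, f.length, f.tag4, f.tag8, duplicate_of=src)
            )
        else:
            ci = int(rng.choice(len(ab), p=ab))
            used = used_lengths.setdefault(ci, set())
            if len(used) >= hi - lo + 1:
                raise InfeasibleError(
                    f"clone {ci} exhausted all fragment lengths in {frag_len_range}"
                )
            while True:
                L = int(rng.integers(lo, hi + 1))
                if L not in used:
                    break
            used.add(L)
            tag4 = "".join(rng.choice(_BASES, size=4).astype(str))
            tag8 = "".join(rng.choice(_BASES, size=8).astype(str))
            fragments.append(Fragment(ci, L, tag4, tag8))
            site_counts[ci] = site_counts.get(ci, 0) + 1
            n_unique += 1

    reads: list[tuple[str, str, str, str, str]] = []
    for fid, f in enumerate(fragments):
        clone = pop.clones[f.clone_index]
        seq = genome.seq(clone.chrom)
        p = clone.junction_pos
        if clone.strand == "+":
            g = seq[p : p + f.length]
        else:
            g = reverse_complement(seq[p - f.length + 1 : p + 1])
        top = (
            f.tag4
            + R1_PRIMER_ADAPTER
            + IR_JUNCTION
            + g
            + reverse_complement(TN5_MOSAIC_END)
            + reverse_complement(f.tag8)
            + reverse_complement(R2_PRIMER_ADAPTER)
        )
        r1 = top[:read_len]
        r2 = reverse_complement(top)[:read_len]
        r1 = _mutate(r1, error_rate, rng)
        r2 = _mutate(r2, error_rate, rng)
        name = f"frag{fid:06d}"
        reads.append((name, r1, "I" * len(r1), r2, "I" * len(r2)))

    return TraceLibraryTruth(
        population=pop, fragments=fragments, reads=reads, site_counts=site_counts
    )


# ---------------------------------------------------------------------------
# Variant cohorts
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SampleTruth:
    sample_id: str
    group: str
    vcf_path: Path | None
    n_private: int
    n_shared: int
    variants: list[tuple[str, int, str, str]]  # (chrom, 1-based pos, ref, alt)

    @property
    def true_gii(self) -> float:
        total = self.n_private + self.n_shared
        return self.n_private / total if total else float("nan")


@dataclasses.dataclass
class VariantCohortTruth:
    samples: list[SampleTruth]
    contig: str = "chr1"
    contig_length: int = 1_000_000

    def write_manifest(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tgroup\tpath\n")
            for s in self.samples:
                fh.write(f"{s.sample_id}\t{s.group}\t{s.vcf_path}\n")


def _random_variant(
    pos: int, contig: str, indel: bool, rng: np.random.Generator
) -> tuple[str, int, str, str]:
    bases = "ACGT"
    ref = bases[rng.integers(4)]
    if not indel:
        alt = bases[(bases.index(ref) + 1 + rng.integers(3)) % 4]
        return (contig, pos, ref, alt)
    if rng.random() < 0.5:  # insertion
        ins = "".join(bases[rng.integers(4)] for _ in range(1 + rng.integers(3)))
        return (contig, pos, ref, ref + ins)
    dele = "".join(bases[rng.integers(4)] for _ in range(1 + rng.integers(3)))
    return (contig, pos, ref + dele, ref)


def simulate_variant_cohort(
    n_treated: int,
    n_control: int,
    n_shared_per_sample: int,
    n_private_per_sample: int,
    indel_fraction: float = 0.1,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> VariantCohortTruth:
    """Simulate per-sample VCFs with a controlled private/shared composition.

    Shared variants form a common pool present in every sample (hence in >=2);
    private variants are unique to their sample. Every sample's true GII is
    therefore n_private / (n_private + n_shared) in each variant class drawn.
    """
    if min(n_treated, n_control, n_shared_per_sample, n_private_per_sample) < 0:
        raise ConfigurationError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    contig, contig_len = "chr1", 1_000_000
    n_samples = n_treated + n_control
    total_vars = n_shared_per_sample + n_private_per_sample * n_samples
    positions = rng.choice(
        np.arange(100, contig_len - 100), size=total_vars, replace=False
    )
    positions = [int(p) for p in positions]
    is_indel = rng.random(total_vars) < indel_fraction
    pool = [
        _random_variant(positions[i], contig, bool(is_indel[i]), rng)
        for i in range(total_vars)
    ]
    shared = pool[:n_shared_per_sample]
    private_chunks = [
        pool[n_shared_per_sample + i * n_private_per_sample :
             n_shared_per_sample + (i + 1) * n_private_per_sample]
        for i in range(n_samples)
    ]

    samples: list[SampleTruth] = []
    ids = [f"BM{i + 1}" for i in range(n_treated)] + [
        f"N{i + 1}" for i in range(n_control)
    ]
    groups = ["treated"] * n_treated + ["control"] * n_control
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for i, (sid, grp) in enumerate(zip(ids, groups)):
        variants = sorted(shared + private_chunks[i], key=lambda v: v[1])
        vcf_path = None
        if out is not None:
            vcf_path = out / f"{sid}.vcf"
            _write_vcf(vcf_path, sid, contig, contig_len, variants)
        samples.append(
            SampleTruth(
                sample_id=sid,
                group=grp,
                vcf_path=vcf_path,
                n_private=len(private_chunks[i]),
                n_shared=len(shared),
                variants=variants,
            )
        )
    return VariantCohortTruth(samples=samples, contig=contig, contig_length=contig_len)


def _write_vcf(
    path: Path,
    sample_id: str,
    contig: str,
    contig_len: int,
    variants: list[tuple[str, int, str, str]],
) -> None:
    import pysam

    header = pysam.VariantHeader()
    header.contigs.add(contig, length=contig_len)
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample_id)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for chrom, pos, ref, alt in variants:
            rec = vf.new_record(contig=chrom, start=pos - 1, alleles=(ref, alt))
            rec.samples[sample_id]["GT"] = (0, 1)
            vf.write(rec)


# ---------------------------------------------------------------------------
# Toy transcript models (for annotation tests)
# ---------------------------------------------------------------------------

def simulate_transcript_models(
    genome: ToyGenome,
    n_genes: int,
    seed: int = 0,
    gtf_path: str | Path | None = None,
) -> list[dict]:
    """Random single-transcript gene models over a toy genome, written as GTF.

    Each gene gets 1-4 exons, a strand, and a 3' UTR carved from the last
    exon. Returns the models as dicts with 0-based half-open coordinates; the
    GTF on disk uses the standard 1-based closed convention.
    """
    rng = np.random.default_rng(seed)
    models = []
    for gi in range(n_genes):
        name, seq = genome.records[int(rng.integers(len(genome.records)))]
        L = len(seq)
        span = int(rng.integers(500, 3000))
        start = int(rng.integers(0, max(1, L - span)))
        end = start + span
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 5))
        cuts = sorted(rng.choice(np.arange(1, span), size=2 * n_exons - 2, replace=False).tolist()) if n_exons > 1 else []
        bounds = [0] + cuts + [span]
        exons = []
        for k in range(n_exons):
            exons.append((start + bounds[2 * k], start + bounds[2 * k + 1]))
        # 3' UTR: tail of the 3'-most exon
        if strand == "+":
            e0, e1 = exons[-1]
            utr_len = max(1, (e1 - e0) // 4)
            utr3 = [(e1 - utr_len, e1)]
        else:
            e0, e1 = exons[0]
            utr_len = max(1, (e1 - e0) // 4)
            utr3 = [(e0, e0 + utr_len)]
        models.append(
            dict(
                gene_id=f"gene{gi + 1}",
                transcript_id=f"tx{gi + 1}",
                chrom=name,
                strand=strand,
                start=start,
                end=end,
                exons=exons,
                utr3=utr3,
            )
        )
    if gtf_path is not None:
        with open(gtf_path, "w") as fh:
            for m in models:
                attrs = f'gene_id "{m["gene_id"]}"; transcript_id "{m["transcript_id"]}";'
                def line(feat, s, e):
                    return (
                        f"{m['chrom']}\tsbtrace\t{feat}\t{s + 1}\t{e}\t.\t"
                        f"{m['strand']}\t.\t{attrs}\n"
                    )
                fh.write(line("transcript", m["start"], m["end"]))
                for e0, e1 in m["exons"]:
                    fh.write(line("exon", e0, e1))
                for u0, u1 in m["utr3"]:
                    fh.write(line("three_prime_utr", u0, u1))
    return models
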