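# Methods

## Read structure and staged trimming

A TRACE junction library is a nested-PCR amplification of Tn5-tagmented
fragments that span the transposon IR-genome junction. The molecule model
used throughout the package (5′→3′ on the junction strand) is

```
tag(4 nt) · CGAGTTTTAATGACTCCAACT · TAAGTGTATGTAAACTTCCGACTTCAACTG · genomic …
… genomic · CTGTCTCTTATACACATCT · tag(8 nt, rc) · CCTAACTGCTGTGCCACT
```

R1 reads this strand from the left, R2 reads its reverse complement from
the right; 150-bp reads truncate whatever does not fit, and fragments
shorter than the read produce 3′ readthrough into the reverse complement of
the opposite end's construct. Trimming reduces each pair to genomic-only
sequence in four pinned stages (outer adapters 5′-anchored, ≤ 5 errors; IR
5′-anchored on R1, ≤ 4; adapter readthrough 3′-adjacent, ≤ 4; IR
readthrough 3′-adjacent on R2, ≤ 3), each with a 20-bp minimum surviving
length for both mates. Error budgets are absolute edit distances
(substitutions + indels), with `N` wildcard positions free.

Numerical/semantic choices that the published command line does not pin:

- **Partial 3′ matches.** A readthrough adapter truncated by the read end
  is matched as a pattern *prefix* against the read suffix, with the error
  budget scaled by overlap (`⌊e·overlap/|pattern|⌋`) and a minimum overlap
  of 3 — the convention of standard adapter trimmers. Full-pattern matches
  anywhere use the stage budget, leftmost occurrence winning (maximal
  trimming, conservative against readthrough contamination).
- **IR requirement.** Reads lacking the stage-2 IR junction carry no
  insertion evidence; they are discarded by default (`require_ir=True`).
  An adapter trimmer would pass them through; the toggle exists for strict
  replication of that behaviour.
- Base qualities are ignored (no filter in the pipeline uses them);
  surviving tags are discarded, i.e., deduplication is positional, not
  UMI-based.

## Alignment filtering and junction calling

Filtering keeps records with MAPQ ≥ 30, no bit of flag mask 3852, all bits
of mask 3, enforces pair integrity, and drops pairs whose R1 has > 5
soft-clipped bases at its *sequencing* 5′ end (leftmost CIGAR element for
forward alignments, rightmost for reverse) — that end carries the
junction, so a clipped one is unreliable. PCR duplicates are pairs sharing
both mates' outer reference coordinates and orientation; the
representative is the highest summed-MAPQ pair, ties breaking to the first
in (reference, start, name) order.

The junction of a surviving R1 is its 5′-most non-soft-clipped base:
`reference_start` for forward reads, `reference_start + reference_span − 1`
(span = Σ M/D/=/X) on the minus strand for reverse reads. Coordinates are
0-based internally and in BED output.

## Merging, artifact filter, replicate consensus

Sites on the same chromosome and strand chain left-to-right by single
linkage with gap ≤ 5 bp. A cluster's count is the member sum; its position
is the member with the largest count, or, when several members tie for the
maximum, the median of the tied positions (floored to an integer
coordinate for even-sized ties, so an odd tie lands on an observed member).
Merging conserves total counts and is idempotent.

The artifact filter removes any (chrom, pos, strand) with count ≥ 2 in ≥ 2
distinct biological samples from every sample — the same genomic site
arising independently in different animals is overwhelmingly a method
artifact. Matching is exact-coordinate post-merge; "samples" means
biological samples, with technical replicates pooled for the check.
Replicate consensus then retains sites present in ≥ 2 of 3 technical
replicates (exact coordinate by default; a window option enables chained
matching) and sums counts over the supporting replicates. The pipeline
order is merge → artifact filter → consensus.

## Clonality and motif

The clonality report is the fragment-fraction distribution over unique
sites (percentages summing to 100) and its maximum, the top-clone
fraction. The logo matrix tallies base frequencies at offsets −20..+20
around the junction; minus-strand windows are reverse-complemented so that
offset 0 is always the first base downstream of the transposon on the
junction strand. Each unique site contributes once by default — the motif
characterizes integration preference, not clone abundance — with
count-weighting available. Sites near contig edges contribute only covered
columns. The information-content transform (letter height = frequency ×
(2 − column entropy) bits) is provided for plotting; the frequency matrix
is the contract.

## Annotation

Six categories partition the genome with precedence promoter > 3′ UTR >
exon > intron > downstream > distal intergenic. Promoters span TSS −2000
to +200 in transcript orientation; downstream windows extend 3000 bp past
each gene's 3′-most end; intron is transcript-span minus exon. 5′ UTR is
not a separate category (5′ UTR bases count as exon unless inside a
promoter window); overlapping transcripts resolve to the
highest-precedence category. Site queries use interval trees; the
genome-wide background paints category codes onto per-chromosome arrays in
reverse precedence order, giving an exact partition (fractions sum to 1 by
construction). Nearest gene is nearest TSS, ties broken by gene id.

## GII statistics

Variant identity is (chrom, pos, ref, alt) after trimming shared allele
suffix then prefix (keeping ≥ 1 base; position advanced accordingly);
multi-allelic records split at the reader. Private/shared status is
evaluated over the pooled treated + control cohort. GII is computed for
all variants and separately for SNPs (|ref| = |alt| = 1) and INDELs; a
class with no variants is undefined and excluded from comparisons. No
genotype-quality or depth filtering is applied — the VCFs are taken as
already filtered upstream.

The rank-sum test enumerates all C(n1+n2, n1) rank assignments (mid-ranks
for ties) when n1+n2 ≤ 12, doubling the smaller tail probability and
capping at 1; larger cohorts use the normal approximation with tie and
continuity corrections. ANOVA is the standard one-way F; identical values
in every sample yield F = 0, p = 1 by convention. With two groups these
tests are the conventional pair for a small-animal cohort; the exact
enumeration matters because at n = 5 vs 3 the attainable two-sided levels
are multiples of 2/56.

## The synthetic-data generator

The generator defines the study conditions under which the pipeline is
validated:

- **Toy genomes** are uniform random A/C/G/T (default TA injection rate
  1 per 100 bp on top of the ~1/16 background), 2 × 60 kb for end-to-end
  runs — large enough that ≥ 25-nt reads place uniquely, small enough for
  desk-scale runtimes.
- **Clone populations** default to symmetric Dirichlet(α = 1) abundances
  over TA-dinucleotide targets, the polyclonal, no-dominant-clone regime
  the analysis is designed to detect departures from. Sites keep ≥ 10 bp
  pairwise separation and a 650-bp contig-edge margin: real insertions on
  a 2.7-Gb genome are effectively never within a 5-bp merge window of each
  other, and toy contigs are ~10⁵× smaller, so the separation emulates
  genomic sparsity rather than easing the task. The TA target is
  palindromic, so the downstream flank begins with TA on either strand;
  the truth junction is the T for + insertions and the A for − insertions.
- **Libraries** sample clones from the abundance vector and fragment
  lengths uniformly on 150–600 bp *without replacement within a clone*, so
  each unique molecule has unique outer coordinates and the positional
  duplicate definition is exact against truth. PCR duplicates re-emit an
  existing molecule (same tags, fresh errors) with probability `dup_rate`
  per emitted pair, giving ≈ n/(1−dup_rate) total pairs. Errors are
  uniform substitutions; qualities are constant 'I'.
- **Variant cohorts** put an identical shared pool in every sample (hence
  every shared variant occurs in ≥ 2 samples) plus per-sample unique
  private variants, so the designed GII is exactly
  n_private/(n_private+n_shared) per sample.

What the generator does **not** emulate: tagmentation insertion bias and
fragment-size distributions, chimeric reads, quality-score decay, indel
sequencing errors, alignment ambiguity from repeats (toy genomes are
repeat-free by construction), and copy-number or coverage structure in the
variant cohorts. Passing tests therefore demonstrate the correctness of
the implemented rules and exact recovery under clean conditions, not
robustness to every artifact of real libraries — real data enter through
the same SAM/VCF interfaces after external alignment and variant calling.

## Problem sizes and determinism

Default validation scales: 100 clones × 3 replicates × 5 000 fragments
(20 % duplicates) for end-to-end recovery; 1 000 clones for the motif
matrix; 1 000 random tables for the merge oracle; 50 random genome/model
pairs for the annotation oracle; 1 000 null replicates for rank-sum
calibration. All randomness flows from explicit integer seeds
(`numpy.random.default_rng`); identical seeds give byte-identical FASTA,
FASTQ and VCF outputs.

## Known limitations

- The built-in aligner is exact-match only; any sequencing error makes a
  synthetic read unmapped rather than mismatched. This is intentional — it
  is a test harness, not an aligner — and error-bearing libraries should
  be aligned externally.
- The artifact filter needs ≥ 2 biological samples and degrades to a
  warning no-op on one.
- Cross-strand site collapsing is not performed anywhere; a head-to-head
  insertion pair 1 bp apart would count as two sites.
- `information_content` applies no small-sample correction.
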