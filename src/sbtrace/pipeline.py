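"""Pipeline configuration and stage orchestration.

`run_pipeline` wires the stages together for a set of technical replicates
per sample: trim -> align (toy) or SAM ingest -> flag/quality filter ->
duplicate removal -> junction calling -> 5-bp merge -> cross-sample
artifact filter -> replicate consensus -> clonality report + logo (and
optional annotation). Every stage logs record counts in/out so conservation
can be audited, and the resolved configuration is serialized with the run.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import alignment, clonality, sites, trimming
from .simulate import ToyGenome


@dataclasses.dataclass
class PipelineConfig:
    """Stage parameters; defaults are the published analysis settings."""

    merge_window: int = 5
    artifact_min_count: int = 2
    artifact_min_samples: int = 2
    consensus_min_replicates: int = 2
    consensus_window: int = 0
    min_mapq: int = 30
    max_r1_5p_softclip: int = 5
    require_ir: bool = True
    logo_flank: int = 20
    tss_upstream: int = 2000
    tss_downstream: int = 200
    gene_downstream: int = 3000
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def process_replicate_fastq(
    r1_path: str | Path,
    r2_path: str | Path,
    genome: ToyGenome,
    config: PipelineConfig,
    out_dir: Path | None = None,
    tag: str = "rep",
) -> tuple:
    """One replicate from FASTQ to a merged site table. Returns (table, log)."""
    pairs = trimming.iter_read_pairs(r1_path, r2_path)
    trimmed, trim_log = trimming.trim_pairs(
        pairs, trimming.default_stages(require_ir=config.require_ir)
    )
    aligned = alignment.align_toy(trimmed, genome)
    filtered, filter_log = alignment.filter_alignments(
        aligned,
        min_mapq=config.min_mapq,
        max_r1_5p_softclip=config.max_r1_5p_softclip,
    )
    deduped, n_dups = alignment.deduplicate_fragments(filtered)
    table = sites.sites_from_alignments(deduped)
    merged = sites.merge_sites(table, window=config.merge_window)
    log = {
        "trim": trim_log,
        "filter": filter_log,
        "n_duplicates_removed": n_dups,
        "n_raw_sites": len(table),
        "n_merged_sites": len(merged),
    }
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        alignment.write_sam(
            deduped, out_dir / f"{tag}.dedup.sam", alignment.make_header(genome)
        )
        sites.write_bed(merged, out_dir / f"{tag}.sites.bed", name=tag)
    return merged, log


def process_replicate_sam(
    sam_path: str | Path, config: PipelineConfig
) -> tuple:
    """One replicate from an externally aligned SAM to a merged site table."""
    records, _ = alignment.read_sam(sam_path)
    filtered, filter_log = alignment.filter_alignments(
        records,
        min_mapq=config.min_mapq,
        max_r1_5p_softclip=config.max_r1_5p_softclip,
    )
    deduped, n_dups = alignment.deduplicate_fragments(filtered)
    merged = sites.merge_sites(
        sites.sites_from_alignments(deduped), window=config.merge_window
    )
    return merged, {"filter": filter_log, "n_duplicates_removed": n_dups}


def run_pipeline(
    sample_replicates: Mapping[str, Sequence[tuple[str | Path, str | Path]]],
    genome: ToyGenome,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full insertion-site pipeline for several samples.

    ``sample_replicates`` maps sample_id -> list of (R1, R2) FASTQ paths,
    one pair per technical replicate. Returns per-sample consensus tables,
    clonality reports, logo matrices and the stage logs; writes stage
    outputs plus a JSON manifest when ``out_dir`` is given.
    """
    config = config or PipelineConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")

    replicate_tables: dict[str, list] = {}
    logs: dict[str, list] = {}
    for sample, reps in sample_replicates.items():
        replicate_tables[sample] = []
        logs[sample] = []
        for i, (r1, r2) in enumerate(reps):
            table, log = process_replicate_fastq(
                r1, r2, genome, config,
                out_dir=(out / sample if out is not None else None),
                tag=f"rep{i + 1}",
            )
            replicate_tables[sample].append(table)
            logs[sample].append(log)

    # artifact filter compares biological samples using their pooled replicates
    pooled = {
        sample: pd.concat(tables, ignore_index=True)
        .groupby(["chrom", "pos", "strand"], as_index=False)["count"]
        .sum()
        for sample, tables in replicate_tables.items()
    }
    if len(pooled) >= 2:
        _, removed = sites.filter_cross_sample_artifacts(
            pooled,
            min_count=config.artifact_min_count,
            min_samples=config.artifact_min_samples,
        )
        bad = set(zip(removed["chrom"], removed["pos"], removed["strand"]))
        for sample in replicate_tables:
            replicate_tables[sample] = [
                t[~t.apply(lambda r: (r["chrom"], r["pos"], r["strand"]) in bad, axis=1)]
                .reset_index(drop=True) if len(t) else t
                for t in replicate_tables[sample]
            ]
    else:
        removed = None

    results = {}
    for sample, tables in replicate_tables.items():
        consensus = sites.replicate_consensus(
            tables,
            min_replicates=config.consensus_min_replicates,
            window=config.consensus_window,
        )
        report = clonality.clonality_report(consensus, sample_id=sample)
        logo = clonality.logo_matrix(consensus, genome, flank=config.logo_flank)
        results[sample] = {
            "consensus": consensus,
            "report": report,
            "logo": logo,
            "logs": logs[sample],
        }
        if out is not None:
            sites.write_bed(consensus, out / sample / "consensus.bed", name=sample)
            report.to_tsv(out / sample / "clonality.tsv")
            logo.to_tsv(out / sample / "logo.tsv")
            clonality.karyotype_positions(consensus).to_csv(
                out / sample / "karyotype_positions.tsv", sep="\t", index=False
            )
    if out is not None:
        manifest = {
            sample: {
                "n_unique_sites": results[sample]["report"].n_unique_sites,
                "n_unique_fragments": results[sample]["report"].n_unique_fragments,
                "top_clone_pct": results[sample]["report"].top_clone_pct,
                "logs": logs[sample],
            }
            for sample in results
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return results
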