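"""Feature-category assignment and genome-wide background fractions."""

import numpy as np
import pandas as pd
import pytest

from sbtrace import annotation, simulate, sites


def write_gtf(path, rows):
    """rows: (chrom, feature, start0, end0, strand, gene, tx)."""
    with open(path, "w") as fh:
        for chrom, feat, s, e, strand, gene, tx in rows:
            fh.write(
                f"{chrom}\ttest\t{feat}\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                f'gene_id "{gene}"; transcript_id "{tx}";\n'
            )


@pytest.fixture()
def simple_model(tmp_path):
    # + strand transcript: span 5000-8000, exons 5000-5500 & 7000-8000,
    # 3' UTR 7800-8000, TSS 5000
    rows = [
        ("chr1", "transcript", 5000, 8000, "+", "g1", "t1"),
        ("chr1", "exon", 5000, 5500, "+", "g1", "t1"),
        ("chr1", "exon", 7000, 8000, "+", "g1", "t1"),
        ("chr1", "three_prime_utr", 7800, 8000, "+", "g1", "t1"),
    ]
    path = tmp_path / "toy.gtf"
    write_gtf(path, rows)
    return annotation.build_feature_model(path, {"chr1": 20000})


def brute_classify(models, chrom_lengths, chrom, pos,
                   tss_up=2000, tss_down=200, gene_down=3000):
    """Per-base oracle straight from the category definitions."""
    for m in models:
        if m["chrom"] != chrom:
            continue
        tss = m["start"] if m["strand"] == "+" else m["end"] - 1
        if m["strand"] == "+" and tss - tss_up <= pos < tss + tss_down:
            return "promoter"
        if m["strand"] == "-" and tss - tss_down + 1 <= pos < tss + tss_up + 1:
            return "promoter"
    for feat, cat in (("utr3", "3' UTR"), ("exons", "exon")):
        for m in models:
            if m["chrom"] == chrom and any(a <= pos < b for a, b in m[feat]):
                return cat
    for m in models:
        if m["chrom"] == chrom and m["start"] <= pos < m["end"]:
            return "intron"
    for m in models:
        if m["chrom"] != chrom:
            continue
        if m["strand"] == "+" and m["end"] <= pos < m["end"] + gene_down:
            return "downstream"
        if m["strand"] == "-" and m["start"] - gene_down <= pos < m["start"]:
            return "downstream"
    return "distal intergenic"


class TestFeatureModel:
    def test_plus_strand_promoter_window(self, simple_model):
        # TSS 5000 -> promoter covers 3000..5200
        assert simple_model.classify("chr1", 3000) == "promoter"
        assert simple_model.classify("chr1", 5199) == "promoter"
        assert simple_model.classify("chr1", 2999) == "distal intergenic"
        assert simple_model.classify("chr1", 4500) == "promoter"  # beats intron-ish

    def test_minus_strand_downstream_window(self, tmp_path):
        rows = [
            ("chr1", "transcript", 4000, 9000, "-", "g1", "t1"),
            ("chr1", "exon", 4000, 9000, "-", "g1", "t1"),
        ]
        path = tmp_path / "minus.gtf"
        write_gtf(path, rows)
        model = annotation.build_feature_model(path, {"chr1": 20000})
        # 3'-most end of a - gene is its genomic start: downstream 1000..4000
        assert model.classify("chr1", 1000) == "downstream"
        assert model.classify("chr1", 3999) == "downstream"
        assert model.classify("chr1", 999) == "distal intergenic"

    def test_precedence_order(self, simple_model):
        assert simple_model.classify("chr1", 5100) == "promoter"  # over exon
        assert simple_model.classify("chr1", 7900) == "3' UTR"  # over exon
        assert simple_model.classify("chr1", 7500) == "exon"
        assert simple_model.classify("chr1", 6000) == "intron"
        assert simple_model.classify("chr1", 8500) == "downstream"
        assert simple_model.classify("chr1", 15000) == "distal intergenic"

    def test_empty_gtf_rejected(self, tmp_path):
        path = tmp_path / "empty.gtf"
        path.write_text("")
        with pytest.raises(ValueError):
            annotation.build_feature_model(path, {"chr1": 1000})

    def test_gtf_without_transcripts_rejected(self, tmp_path):
        path = tmp_path / "exononly.gtf"
        write_gtf(path, [("chr1", "CDS", 10, 20, "+", "g", "t")])
        with pytest.raises(ValueError):
            annotation.build_feature_model(path, {"chr1": 1000})


class TestAnnotateSites:
    def test_category_and_nearest_gene(self, simple_model):
        df = pd.DataFrame(
            [("chr1", 4500, "+", 3), ("chr1", 6000, "-", 1), ("chr1", 15000, "+", 2)],
            columns=sites.SITE_COLUMNS,
        )
        ann = annotation.annotate_sites(df, simple_model)
        assert ann["category"].tolist() == ["promoter", "intron", "distal intergenic"]
        assert set(ann["nearest_gene"]) == {"g1"}
        assert ann["tss_distance"].tolist() == [-500, 1000, 10000]

    def test_unknown_chrom_warns_distal(self, simple_model):
        df = pd.DataFrame([("chrZ", 10, "+", 1)], columns=sites.SITE_COLUMNS)
        with pytest.warns(UserWarning):
            ann = annotation.annotate_sites(df, simple_model)
        assert ann["category"].tolist() == ["distal intergenic"]


class TestBackground:
    def test_empty_model_is_all_distal(self):
        model = annotation.FeatureModel(transcripts=[], chrom_lengths={"chr1": 5000})
        bg = annotation.genome_feature_background(model)
        assert bg["distal intergenic"] == 1.0

    def test_fractions_sum_to_one(self, simple_model):
        bg = annotation.genome_feature_background(simple_model)
        assert sum(bg.values()) == pytest.approx(1.0)

    def test_matches_perbase_oracle_on_random_models(self, tmp_path):
        rng_seeds = [101, 102, 103]
        for seed in rng_seeds:
            genome = simulate.generate_genome(1, [4000], seed=seed)
            models = simulate.simulate_transcript_models(
                genome, 3, seed=seed, gtf_path=tmp_path / f"m{seed}.gtf"
            )
            model = annotation.build_feature_model(
                tmp_path / f"m{seed}.gtf", genome.chrom_lengths
            )
            bg = annotation.genome_feature_background(model)
            L = genome.chrom_lengths["chr1"]
            brute_counts = {c: 0 for c in annotation.CATEGORIES}
            for pos in range(L):
                brute_counts[brute_classify(models, genome.chrom_lengths, "chr1", pos)] += 1
            for cat in annotation.CATEGORIES:
                assert bg[cat] == pytest.approx(brute_counts[cat] / L)

    def test_site_annotation_agrees_with_background_classifier(self, tmp_path):
        genome = simulate.generate_genome(1, [6000], seed=41)
        models = simulate.simulate_transcript_models(
            genome, 4, seed=42, gtf_path=tmp_path / "m.gtf"
        )
        model = annotation.build_feature_model(tmp_path / "m.gtf", genome.chrom_lengths)
        rng = np.random.default_rng(43)
        for pos in rng.integers(0, 6000, size=300):
            assert model.classify("chr1", int(pos)) == brute_classify(
                models, genome.chrom_lengths, "chr1", int(pos)
            )

    def test_invariant_under_transcript_order(self, tmp_path):
        rows = [
            ("chr1", "transcript", 1000, 2000, "+", "g1", "t1"),
            ("chr1", "exon", 1000, 2000, "+", "g1", "t1"),
            ("chr1", "transcript", 5000, 7000, "-", "g2", "t2"),
            ("chr1", "exon", 5000, 7000, "-", "g2", "t2"),
        ]
        p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
        write_gtf(p1, rows)
        write_gtf(p2, rows[2:] + rows[:2])
        m1 = annotation.build_feature_model(p1, {"chr1": 10000})
        m2 = annotation.build_feature_model(p2, {"chr1": 10000})
        assert annotation.genome_feature_background(m1) == annotation.genome_feature_background(m2)
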