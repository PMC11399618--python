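"""Junction calling, the 5-bp merge rule, artifact and consensus filters."""

import numpy as np
import pandas as pd
import pysam
import pytest
from hypothesis import given, settings, strategies as st

from sbtrace import alignment, sites


def _table(counts, chrom="chr1", strand="+"):
    return pd.DataFrame(
        [(chrom, p, strand, c) for p, c in sorted(counts.items())],
        columns=sites.SITE_COLUMNS,
    )


def _as_dict(df):
    return {int(r.pos): int(r.count) for r in df.itertuples(index=False)}


@pytest.fixture(scope="module")
def header():
    return pysam.AlignmentHeader.from_dict({"SQ": [{"SN": "chr1", "LN": 100000}]})


class TestCallReadInsertion:
    def _r1(self, header, pos0, cigar, reverse=False):
        a = pysam.AlignedSegment(header)
        a.query_name = "q"
        a.flag = (83 if reverse else 99)
        a.reference_id = 0
        a.reference_start = pos0
        a.mapping_quality = 60
        a.cigarstring = cigar
        a.query_sequence = "A" * sum(
            l for op, l in a.cigartuples if op in (0, 1, 4)
        )
        return a

    def test_forward_read_junction_is_alignment_start(self, header):
        rec = self._r1(header, 1000, "150M")
        assert sites.call_read_insertion(rec) == ("chr1", 1000, "+")

    def test_reverse_read_junction_is_last_reference_base(self, header):
        rec = self._r1(header, 1000, "150M", reverse=True)
        assert sites.call_read_insertion(rec) == ("chr1", 1149, "-")

    def test_leading_softclip_consumes_no_reference(self, header):
        rec = self._r1(header, 1000, "3S147M")
        assert sites.call_read_insertion(rec) == ("chr1", 1000, "+")

    def test_deletion_extends_reference_span(self, header):
        rec = self._r1(header, 1000, "100M10D50M", reverse=True)
        assert sites.call_read_insertion(rec) == ("chr1", 1159, "-")

    def test_r2_record_rejected(self, header):
        rec = self._r1(header, 1000, "150M")
        rec.flag = 147
        with pytest.raises(ValueError):
            sites.call_read_insertion(rec)


def brute_force_merge(counts, window=5):
    """Independent oracle: explicit chain construction then the merge rule."""
    positions = sorted(counts)
    clusters, current = [], [positions[0]]
    for p in positions[1:]:
        if p - current[-1] <= window:
            current.append(p)
        else:
            clusters.append(current)
            current = [p]
    clusters.append(current)
    out = {}
    for members in clusters:
        cs = [counts[p] for p in members]
        top = [p for p, c in zip(members, cs) if c == max(cs)]
        pos = top[0] if len(top) == 1 else int(np.floor(np.median(top)))
        out[pos] = sum(cs)
    return out


class TestMergeSites:
    def test_largest_count_member_wins(self):
        assert _as_dict(sites.merge_sites(_table({100: 10, 103: 3}))) == {100: 13}

    def test_tied_counts_resolve_to_median_position(self):
        assert _as_dict(sites.merge_sites(_table({100: 5, 104: 5}))) == {102: 10}

    def test_beyond_window_not_merged(self):
        assert _as_dict(sites.merge_sites(_table({100: 2, 110: 4}))) == {100: 2, 110: 4}

    def test_odd_tie_takes_member_median(self):
        assert _as_dict(sites.merge_sites(_table({100: 4, 103: 4, 105: 4}))) == {103: 12}

    def test_strands_and_chroms_merge_separately(self):
        df = pd.concat(
            [
                _table({100: 2, 103: 2}, strand="+"),
                _table({101: 7}, strand="-"),
                _table({102: 1}, chrom="chr2"),
            ],
            ignore_index=True,
        )
        merged = sites.merge_sites(df)
        assert len(merged) == 3
        assert int(merged["count"].sum()) == 12

    @given(
        st.dictionaries(
            st.integers(min_value=0, max_value=300),
            st.integers(min_value=1, max_value=20),
            min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_bruteforce_oracle_and_conserves_counts(self, counts):
        merged = sites.merge_sites(_table(counts))
        assert _as_dict(merged) == brute_force_merge(counts)
        assert int(merged["count"].sum()) == sum(counts.values())
        # idempotence and bounded positions
        again = sites.merge_sites(merged)
        assert _as_dict(again) == _as_dict(merged)
        assert merged["pos"].between(min(counts), max(counts)).all()


class TestArtifactFilter:
    def test_site_strong_in_two_samples_removed_everywhere(self):
        tables = {"A": _table({100: 3, 200: 1}), "B": _table({100: 2, 300: 4})}
        filtered, removed = sites.filter_cross_sample_artifacts(tables)
        assert _as_dict(filtered["A"]) == {200: 1}
        assert _as_dict(filtered["B"]) == {300: 4}
        assert removed["pos"].tolist() == [100]

    def test_single_supporting_sample_retained(self):
        tables = {"A": _table({100: 1}), "B": _table({100: 3})}
        filtered, removed = sites.filter_cross_sample_artifacts(tables)
        assert _as_dict(filtered["A"]) == {100: 1}
        assert _as_dict(filtered["B"]) == {100: 3}
        assert removed.empty

    def test_high_count_in_one_sample_retained(self):
        tables = {"A": _table({100: 9}), "B": _table({500: 2})}
        filtered, _ = sites.filter_cross_sample_artifacts(tables)
        assert _as_dict(filtered["A"]) == {100: 9}

    def test_single_sample_is_noop_with_warning(self):
        with pytest.warns(UserWarning):
            filtered, removed = sites.filter_cross_sample_artifacts(
                {"A": _table({100: 5})}
            )
        assert _as_dict(filtered["A"]) == {100: 5} and removed.empty

    def test_strand_is_part_of_site_identity(self):
        tables = {
            "A": _table({100: 3}, strand="+"),
            "B": _table({100: 3}, strand="-"),
        }
        filtered, removed = sites.filter_cross_sample_artifacts(tables)
        assert removed.empty and len(filtered["A"]) == 1


class TestReplicateConsensus:
    def test_two_of_three_retained_with_summed_count(self):
        reps = [_table({100: 4}), _table({100: 6}), _table({900: 1})]
        out = sites.replicate_consensus(reps, min_replicates=2)
        assert _as_dict(out) == {100: 10}

    def test_single_replicate_site_dropped(self):
        reps = [_table({}), _table({}), _table({500: 9})]
        reps = [r.astype({"pos": int, "count": int}) for r in reps]
        out = sites.replicate_consensus(reps, min_replicates=2)
        assert out.empty

    def test_windowed_matching_retains_nearby_sites(self):
        reps = [_table({100: 4}), _table({103: 6})]
        exact = sites.replicate_consensus(reps, min_replicates=2, window=0)
        windowed = sites.replicate_consensus(reps, min_replicates=2, window=5)
        assert exact.empty
        assert _as_dict(windowed) == {103: 10}  # higher-count member position

    def test_too_few_tables_rejected(self):
        with pytest.raises(ValueError):
            sites.replicate_consensus([_table({1: 1})], min_replicates=2)


class TestBedRoundtrip:
    def test_write_read_identity(self, tmp_path):
        df = pd.concat(
            [_table({10: 3, 50: 1}), _table({20: 2}, strand="-")], ignore_index=True
        )
        path = tmp_path / "sites.bed"
        sites.write_bed(df, path)
        back = sites.read_bed(path)
        merged_cols = ["chrom", "pos", "strand", "count"]
        assert back[merged_cols].sort_values(["pos", "strand"]).reset_index(
            drop=True
        ).equals(df[merged_cols].sort_values(["pos", "strand"]).reset_index(drop=True))
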