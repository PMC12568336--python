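"""Parsing, chimeric filtering, dedup, classification, accounting, complexity."""

import itertools

import numpy as np
import pandas as pd
import pytest

import loopscape as ls
from loopscape.genome import ConfigError
from loopscape.pairsio import PairRecord, SummaryValidationError, is_chimeric_frame
from .conftest import qc_chain

GENOME = ls.GenomeSpec(("chr1", "chr2"), {"chr1": 1_000_000, "chr2": 1_000_000})


def _frame(rows):
    return pd.DataFrame(rows, columns=["read_id", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"])


class TestParse:
    def test_sides_normalized_to_genome_order(self):
        df, _ = ls.parse_pairs(_frame([("r1", "chr2", 100, "chr1", 200, "+", "-")]), GENOME)
        row = df.iloc[0]
        assert (row.chrom1, row.pos1, row.strand1) == ("chr1", 200, "-")
        assert (row.chrom2, row.pos2, row.strand2) == ("chr2", 100, "+")

    def test_sentinel_chromosome_marks_unmapped(self):
        df, stats = ls.parse_pairs(_frame([("r1", "!", 0, "chr1", 200, "+", "-")]), GENOME)
        assert not df.iloc[0]["mapped"]
        assert stats.n_unmapped == 1

    def test_position_beyond_chromosome_rejected_and_counted(self):
        df, stats = ls.parse_pairs(_frame([("r1", "chr1", 100, "chr1", 2_000_000, "+", "-")]), GENOME)
        assert df.empty
        assert stats.n_rejected_out_of_bounds == 1

    def test_unknown_chromosome_rejected_and_counted(self):
        df, stats = ls.parse_pairs(_frame([("r1", "chr9", 100, "chr1", 200, "+", "-")]), GENOME)
        assert df.empty
        assert stats.n_rejected_unknown_chrom == 1

    def test_blacklisted_chromosome_dropped_with_count(self):
        g = ls.GenomeSpec(("chr1", "chrM"), {"chr1": 1_000_000, "chrM": 16_299}, frozenset({"chrM"}))
        df, stats = ls.parse_pairs(
            _frame([("r1", "chrM", 10, "chr1", 200, "+", "-"), ("r2", "chr1", 10, "chr1", 5000, "+", "-")]), g
        )
        assert stats.n_dropped_blacklist == 1
        assert len(df) == 1

    def test_malformed_lines_reported_with_line_numbers(self):
        lines = [
            "#columns: readID chrom1 pos1 chrom2 pos2 strand1 strand2\n",
            "r1\tchr1\t100\tchr1\t5000\t+\t-\n",
            "r2\tchr1\tnotanumber\tchr1\t5000\t+\t-\n",
            "r3\tchr1\t100\n",
        ]
        df, stats = ls.parse_pairs(lines, GENOME)
        assert len(df) == 1
        assert [ln for ln, _ in stats.malformed] == [3, 4]


class TestChimeric:
    def test_different_chromosomes_chimeric(self):
        assert ls.is_chimeric(PairRecord("r", "chr1", 100, "+", "chr2", 100, "-"))

    def test_inward_at_exactly_threshold_not_chimeric(self):
        # "more than 2,000 bp" is strict: 2,000 exactly stays typical
        assert not ls.is_chimeric(PairRecord("r", "chr1", 100, "+", "chr1", 2100, "-"))

    def test_same_strand_chimeric(self):
        assert ls.is_chimeric(PairRecord("r", "chr1", 100, "+", "chr1", 600, "+"))

    def test_unmapped_record_is_undefined_input(self):
        with pytest.raises(ValueError):
            ls.is_chimeric(PairRecord("r", "!", 0, "+", "chr1", 100, "-", mapped=False))

    def test_matches_enumeration_oracle(self):
        """Brute-force oracle over strands x distances x chromosome identity."""
        threshold = 2000
        for s1, s2, dist, same_chrom in itertools.product(
            "+-", "+-", (0, 1999, 2000, 2001), (True, False)
        ):
            c2 = "chr1" if same_chrom else "chr2"
            rec = PairRecord("r", "chr1", 5000, s1, c2, 5000 + dist, s2)
            # first principles: a pair is a candidate ligation junction unless it
            # is same-chromosome, inward-convergent, and within the threshold
            inward = s1 == "+" and s2 == "-"  # left side +, right side -
            expect = (not same_chrom) or (not inward) or (dist > threshold)
            assert ls.is_chimeric(rec, threshold) == expect, (s1, s2, dist, same_chrom)

    def test_frame_version_agrees_with_scalar(self, qc_fixture):
        pairs, _, genome = qc_fixture
        parsed, _ = ls.parse_pairs(pairs, genome)
        mapped = parsed[parsed["mapped"]].head(500)
        flags = is_chimeric_frame(mapped)
        for flag, row in zip(flags, mapped.itertuples()):
            rec = PairRecord(row.read_id, row.chrom1, row.pos1, row.strand1, row.chrom2, row.pos2, row.strand2)
            assert ls.is_chimeric(rec) == flag


class TestDeduplicate:
    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_k_identical_copies_give_k_minus_1_duplicates(self, k):
        rows = [(f"r{i}", "chr1", 100, "chr1", 5000, "+", "-") for i in range(k)]
        df, _ = ls.parse_pairs(_frame(rows), GENOME)
        _, n_dup = ls.deduplicate(ls.sort_pairs(df))
        assert n_dup == k - 1

    def test_strands_are_part_of_the_key(self):
        rows = [("r1", "chr1", 100, "chr1", 5000, "+", "-"), ("r2", "chr1", 100, "chr1", 5000, "+", "+")]
        df, _ = ls.parse_pairs(_frame(rows), GENOME)
        _, n_dup = ls.deduplicate(ls.sort_pairs(df))
        assert n_dup == 0

    def test_unsorted_input_rejected(self):
        rows = [("r1", "chr1", 9000, "chr1", 9500, "+", "-"), ("r2", "chr1", 100, "chr1", 5000, "+", "-")]
        df, _ = ls.parse_pairs(_frame(rows), GENOME)
        with pytest.raises(ValueError, match="sorted"):
            ls.deduplicate(df)


class TestClassify:
    @pytest.mark.parametrize(
        "pos2,category,valid",
        [(1099, "cis_lt_1kb", False), (1100, "cis_1kb_10kb", True), (10_100, "cis_ge_10kb", True)],
    )
    def test_distance_strata_boundaries(self, pos2, category, valid):
        df, _ = ls.parse_pairs(_frame([("r1", "chr1", 100, "chr1", pos2, "+", "-")]), GENOME)
        out = ls.classify(df)
        assert out.iloc[0]["category"] == category
        assert bool(out.iloc[0]["valid"]) is valid

    def test_trans_pair_valid(self):
        df, _ = ls.parse_pairs(_frame([("r1", "chr1", 100, "chr2", 200, "+", "-")]), GENOME)
        out = ls.classify(df)
        assert out.iloc[0]["category"] == "trans"
        assert out.iloc[0]["valid"]

    def test_categories_partition_all_records(self, qc_fixture):
        pairs, _, genome = qc_fixture
        classified, _ = qc_chain(pairs, genome, chimeric_filter=False)
        counts = classified["category"].value_counts()
        assert counts.sum() == len(classified)
        mapped_nodup = classified[(classified["category"] != "unmapped") & (classified["category"] != "duplicate")]
        strata = mapped_nodup["category"].isin(["trans", "cis_lt_1kb", "cis_1kb_10kb", "cis_ge_10kb"])
        assert strata.all()


class TestSummarize:
    def test_identity_violation_is_named(self):
        counts = dict(
            total=100, unmapped=10, mapped=90, duplicate=10, nodup=70,  # 10+70 != 90
            cis=50, trans=20, valid=60, cis_lt_1kb=10, cis_ge_1kb=40, cis_ge_10kb=20,
        )
        with pytest.raises(SummaryValidationError, match="duplicate \\+ nodup == mapped"):
            ls.summarize(counts)

    def test_all_zero_counts_warn_and_report_zero(self):
        counts = {k: 0 for k in ("total", "unmapped", "mapped", "duplicate", "nodup", "cis", "trans",
                                 "valid", "cis_lt_1kb", "cis_ge_1kb", "cis_ge_10kb")}
        with pytest.warns(UserWarning, match="degenerate"):
            rep = ls.summarize(counts)
        assert (rep.table["Percent"] == 0).all()

    def test_percentages_recompute_from_counts(self, qc_fixture):
        pairs, _, genome = qc_fixture
        classified, _ = qc_chain(pairs, genome, chimeric_filter=False)
        rep = ls.summarize(classified)
        c = rep.counts
        by_cat = dict(zip(rep.table["Category"], rep.table["Percent"]))
        assert by_cat["Mapped Read Pairs"] == round(100 * c["mapped"] / c["total"], 2)
        assert by_cat["No-Dup Valid Read Pairs (cis >= 1 kb + trans)"] == round(100 * c["valid"] / c["nodup"], 2)


class TestComplexityCurve:
    def test_zero_depth_gives_zero(self):
        cc = ls.complexity_curve(1e6, 5e5, [0, 1e6, 2e6])
        assert cc.expected_distinct[0] == 0.0

    def test_root_finder_self_consistency(self):
        cc = ls.complexity_curve(1e6, 5e5, [1e6])
        assert abs(cc.at(1e6) - 5e5) / 5e5 < 1e-6

    def test_curve_nondecreasing_and_concave(self):
        grid = np.linspace(0, 5e6, 60)
        cc = ls.complexity_curve(1e6, 7e5, grid)
        d = np.diff(cc.expected_distinct)
        assert (d >= 0).all()
        assert (np.diff(d) <= 1e-6).all()

    def test_no_saturation_case_reported(self):
        cc = ls.complexity_curve(1e6, 1e6, [0, 1e6])
        assert np.isinf(cc.library_size)
        assert "no saturation" in cc.message

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ConfigError):
            ls.complexity_curve(1e6, 2e6, [0])
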