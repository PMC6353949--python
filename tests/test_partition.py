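"""Read classification rules, partition reports, and gene counting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from xenonet import (
    ReadClass,
    SimulationConfig,
    classify_read,
    gene_counts,
    partition_reads,
    simulate_alignment_table,
)
from xenonet.partition import (
    read_alignment_table,
    read_alignments_sam,
    write_alignment_table,
)


def make_table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "read_id", "mapped_human", "score_human", "mapped_mouse",
            "score_mouse", "gene_human", "gene_mouse",
        ],
    )


class TestClassifyRead:
    @pytest.mark.parametrize(
        "mh,sh,mm,sm,margin,expected",
        [
            (1, 90.0, 0, None, 0, ReadClass.HUMAN_UNIQUE),
            (0, None, 1, 90.0, 0, ReadClass.MOUSE_UNIQUE),
            (0, None, 0, None, 0, ReadClass.UNMAPPED),
            (1, 100.0, 1, 100.0, 0, ReadClass.AMBIGUOUS),  # equal similarity
            (1, 90.0, 1, 80.0, 0, ReadClass.HUMAN_UNIQUE),
            (1, 80.0, 1, 90.0, 0, ReadClass.MOUSE_UNIQUE),
            (1, 100.0, 1, 96.0, 5, ReadClass.AMBIGUOUS),   # within margin
            (1, 100.0, 1, 94.0, 5, ReadClass.HUMAN_UNIQUE),
        ],
    )
    def test_rule(self, mh, sh, mm, sm, margin, expected):
        assert classify_read(mh, sh, mm, sm, margin) == expected

    def test_mapped_without_score_raises(self):
        with pytest.raises(ValueError, match="no human score"):
            classify_read(1, None, 0, None)

    def test_negative_margin_raises(self):
        with pytest.raises(ValueError, match="margin"):
            classify_read(1, 1.0, 0, None, margin=-1)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        sh=st.floats(0, 100, allow_nan=False),
        sm=st.floats(0, 100, allow_nan=False),
        margin=st.floats(0, 10, allow_nan=False),
    )
    def test_antisymmetry(self, sh, sm, margin):
        """Swapping the genomes swaps the species labels exactly."""
        fwd = classify_read(1, sh, 1, sm, margin)
        rev = classify_read(1, sm, 1, sh, margin)
        swap = {
            ReadClass.HUMAN_UNIQUE: ReadClass.MOUSE_UNIQUE,
            ReadClass.MOUSE_UNIQUE: ReadClass.HUMAN_UNIQUE,
            ReadClass.AMBIGUOUS: ReadClass.AMBIGUOUS,
            ReadClass.UNMAPPED: ReadClass.UNMAPPED,
        }
        assert rev == swap[fwd]


class TestPartitionReads:
    def test_planted_fractions_reproduced(self):
        table, _ = simulate_alignment_table(SimulationConfig(seed=0, n_reads=10000))
        _, report = partition_reads(table)
        pct = report.percentages
        assert pct["HUMAN_UNIQUE"] == pytest.approx(57.24, abs=1e-9)
        assert pct["MOUSE_UNIQUE"] == pytest.approx(29.66, abs=1e-9)
        assert pct["AMBIGUOUS"] == pytest.approx(11.00, abs=1e-9)

    def test_conservation_and_percent_sum(self):
        table, _ = simulate_alignment_table(SimulationConfig(seed=3, n_reads=3000))
        _, report = partition_reads(table)
        assert sum(report.counts.values()) == report.total == 3000
        assert sum(report.percentages.values()) == pytest.approx(100.0, abs=0.01)

    def test_empty_table_raises(self):
        with pytest.raises(ValueError, match="no reads"):
            partition_reads(make_table([]))

    def test_margin_monotone_ambiguous(self):
        table, _ = simulate_alignment_table(SimulationConfig(seed=1, n_reads=2000))
        previous = -1
        for margin in (0, 1, 5, 10, 100):
            _, report = partition_reads(table, margin=margin)
            assert report.counts["AMBIGUOUS"] >= previous
            previous = report.counts["AMBIGUOUS"]

    def test_genome_swap_antisymmetry(self):
        table, _ = simulate_alignment_table(SimulationConfig(seed=2, n_reads=2000))
        swapped = table.rename(
            columns={
                "mapped_human": "mapped_mouse", "mapped_mouse": "mapped_human",
                "score_human": "score_mouse", "score_mouse": "score_human",
                "gene_human": "gene_mouse", "gene_mouse": "gene_human",
            }
        )
        _, rep = partition_reads(table)
        _, rep_sw = partition_reads(swapped)
        assert rep.counts["HUMAN_UNIQUE"] == rep_sw.counts["MOUSE_UNIQUE"]
        assert rep.counts["MOUSE_UNIQUE"] == rep_sw.counts["HUMAN_UNIQUE"]
        assert rep.counts["AMBIGUOUS"] == rep_sw.counts["AMBIGUOUS"]

    def test_strict_dual_discard_dominates(self):
        table = make_table(
            [["r1", 1, 90.0, 1, 50.0, "gH", "gM"], ["r2", 1, 90.0, 0, np.nan, "gH", ""]]
        )
        assignments, report = partition_reads(table, strict_dual_discard=True)
        assert assignments["r1"] == "AMBIGUOUS"
        assert assignments["r2"] == "HUMAN_UNIQUE"


class TestGeneCounts:
    def test_unique_reads_counted(self):
        table = make_table(
            [
                ["r1", 1, 90.0, 0, np.nan, "gA", ""],
                ["r2", 1, 91.0, 0, np.nan, "gA", ""],
                ["r3", 1, 92.0, 0, np.nan, "gA", ""],
                ["r4", 0, np.nan, 1, 80.0, "", "gB"],
                ["r5", 1, 70.0, 1, 70.0, "gA", "gB"],  # ambiguous: no count
            ]
        )
        assignments, _ = partition_reads(table)
        dual, features = gene_counts(assignments, table)
        assert dual.human.loc["gA", "sample"] == 3
        assert dual.mouse.loc["gB", "sample"] == 1
        assert features["counted"] == 4

    def test_no_feature_and_multigene(self):
        table = make_table(
            [
                ["r1", 1, 90.0, 0, np.nan, "", ""],          # no annotation
                ["r2", 1, 90.0, 0, np.nan, "gA,gB", ""],     # multi-gene
                ["r3", 1, 90.0, 0, np.nan, "gA", ""],
            ]
        )
        assignments, _ = partition_reads(table)
        dual, features = gene_counts(assignments, table)
        assert features == {"counted": 1, "no_feature": 1, "ambiguous_feature": 1}
        assert dual.human["sample"].sum() == 1

    def test_unknown_read_raises(self):
        table = make_table([["r1", 1, 90.0, 0, np.nan, "gA", ""]])
        bad = pd.Series({"rX": "HUMAN_UNIQUE"})
        with pytest.raises(ValueError, match="unknown reads"):
            gene_counts(bad, table)


class TestIO:
    def test_tsv_round_trip(self, tmp_path):
        table, _ = simulate_alignment_table(SimulationConfig(seed=9, n_reads=50))
        path = tmp_path / "aln.tsv"
        write_alignment_table(table, path)
        back = read_alignment_table(path)
        assert list(back.columns) == list(table.columns)
        assert len(back) == 50

    def test_missing_columns_raise(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("read_id\tmapped_human\nr1\t1\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_alignment_table(path)

    def test_sam_reader_uses_alignment_scores(self, tmp_path):
        header = "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"
        hum = header + (
            "r1\t0\tchr1\t1\t60\t10M\t*\t0\t0\tACGTACGTAC\t*\tAS:i:50\n"
            "r2\t0\tchr1\t1\t60\t10M\t*\t0\t0\tACGTACGTAC\t*\tAS:i:40\n"
        )
        mus = header + (
            "r2\t0\tchr1\t1\t60\t10M\t*\t0\t0\tACGTACGTAC\t*\tAS:i:45\n"
            "r3\t0\tchr1\t1\t60\t10M\t*\t0\t0\tACGTACGTAC\t*\tAS:i:30\n"
        )
        hpath, mpath = tmp_path / "h.sam", tmp_path / "m.sam"
        hpath.write_text(hum)
        mpath.write_text(mus)
        table = read_alignments_sam(hpath, mpath)
        assignments, _ = partition_reads(table)
        assert assignments["r1"] == "HUMAN_UNIQUE"
        assert assignments["r2"] == "MOUSE_UNIQUE"  # 45 > 40
        assert assignments["r3"] == "MOUSE_UNIQUE"
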