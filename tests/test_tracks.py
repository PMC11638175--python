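"""Pseudobulk collapse and barChart BED generation, sorting and dialects."""

import numpy as np
import pandas as pd
import pytest

from scbroker import tracks
from scbroker.tracks import (BarChartRecord, collapse_by_celltype,
                             make_barchart_bed, read_annotation,
                             read_barchart_bed, sort_records,
                             write_barchart_bed)


def brute_force_collapse(matrix: pd.DataFrame, labels: pd.Series,
                         stat: str = "mean") -> pd.DataFrame:
    """Independent per-type loop oracle for the collapse operation."""
    types = sorted(set(labels[c] for c in matrix.columns))
    out = pd.DataFrame(index=matrix.index, columns=types, dtype=float)
    for t in types:
        members = [c for c in matrix.columns if labels[c] == t]
        for g in matrix.index:
            values = [matrix.loc[g, c] for c in members]
            out.loc[g, t] = (np.mean(values) if stat == "mean"
                             else np.median(values))
    return out


def toy_record(chrom="chr1", start=0, end=10, name="g", score=0, strand="+",
               scores=(1.0, 2.0)):
    return BarChartRecord(chrom, start, end, name, score, strand,
                          f"{name}_sym", len(scores), tuple(scores))


class TestCollapse:
    def test_hand_computed_means(self):
        matrix = pd.DataFrame(
            [[1.0, 3.0, 10.0, 20.0],
             [0.0, 0.0, 0.0, 0.0],
             [2.0, 2.0, 5.0, 7.0]],
            index=["g1", "g2", "g3"], columns=["c1", "c2", "c3", "c4"])
        labels = pd.Series(["A", "A", "B", "B"],
                           index=["c1", "c2", "c3", "c4"])
        collapsed = collapse_by_celltype(matrix, labels, "mean")
        assert list(collapsed.columns) == ["A", "B"]
        assert collapsed.loc["g1"].tolist() == [2.0, 15.0]
        assert collapsed.loc["g2"].tolist() == [0.0, 0.0]  # all-zero gene
        assert collapsed.loc["g3"].tolist() == [2.0, 6.0]

    def test_single_type_equals_row_means(self, expression):
        matrix, _, _ = expression
        labels = pd.Series("only", index=matrix.columns)
        collapsed = collapse_by_celltype(matrix, labels)
        np.testing.assert_allclose(collapsed["only"], matrix.mean(axis=1))

    @pytest.mark.parametrize("stat", ["mean", "median"])
    def test_matches_brute_force_oracle(self, stat):
        rng = np.random.default_rng(11)
        for _ in range(5):
            n_genes = int(rng.integers(2, 20))
            n_cells = int(rng.integers(4, 60))
            matrix = pd.DataFrame(
                rng.gamma(2.0, 1.0, size=(n_genes, n_cells)),
                index=[f"g{i}" for i in range(n_genes)],
                columns=[f"c{i}" for i in range(n_cells)])
            labels = pd.Series(
                rng.choice(["A", "B", "C"], size=n_cells), index=matrix.columns)
            fast = collapse_by_celltype(matrix, labels, stat)
            slow = brute_force_collapse(matrix, labels, stat)
            assert (fast - slow).abs().values.max() <= 1e-12

    def test_conservation_of_totals(self, expression):
        """Mean per type times member count sums back to per-gene totals."""
        matrix, labels, _ = expression
        collapsed = collapse_by_celltype(matrix, labels, "mean")
        counts = labels.value_counts()
        reconstructed = (collapsed * counts[collapsed.columns]).sum(axis=1)
        totals = matrix.sum(axis=1)
        rel = ((reconstructed - totals).abs() / totals.abs().clip(lower=1e-300))
        assert rel.max() <= 1e-9

    def test_unlabelled_cell_rejected(self):
        matrix = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["c1", "c2"])
        labels = pd.Series(["A"], index=["c1"])
        with pytest.raises(ValueError, match="absent from metadata"):
            collapse_by_celltype(matrix, labels)


class TestBarChartRecords:
    def test_records_carry_celltype_vector(self, expression, annotation):
        matrix, labels, _ = expression
        collapsed = collapse_by_celltype(matrix, labels)
        records = make_barchart_bed(collapsed, annotation)
        assert len(records) == len(matrix)
        for r in records:
            assert r.exp_count == 4 == len(r.exp_scores)
            assert 0 <= r.score <= 1000

    def test_global_max_gene_scores_exactly_1000(self, expression, annotation):
        matrix, labels, _ = expression
        collapsed = collapse_by_celltype(matrix, labels)
        records = make_barchart_bed(collapsed, annotation)
        peak = max(max(r.exp_scores) for r in records)
        top = [r for r in records if max(r.exp_scores) == peak]
        assert all(r.score == 1000 for r in top)

    def test_minus_strand_preserved(self, expression, annotation):
        matrix, labels, _ = expression
        collapsed = collapse_by_celltype(matrix, labels)
        records = {r.name: r for r in make_barchart_bed(collapsed, annotation)}
        for _, row in annotation.iterrows():
            assert records[row["gene_id"]].strand == row["strand"]

    def test_all_zero_matrix_scores_zero(self, annotation):
        collapsed = pd.DataFrame(0.0, index=annotation["gene_id"],
                                 columns=["A", "B"])
        records = make_barchart_bed(collapsed, annotation)
        assert all(r.score == 0 for r in records)

    def test_unannotated_genes_skipped(self, expression, annotation):
        matrix, labels, _ = expression
        collapsed = collapse_by_celltype(matrix, labels)
        partial = annotation.iloc[:10]
        records = make_barchart_bed(collapsed, partial)
        assert len(records) == 10

    def test_empty_intersection_rejected(self, annotation):
        collapsed = pd.DataFrame([[1.0]], index=["nope"], columns=["A"])
        with pytest.raises(ValueError, match="no overlap"):
            make_barchart_bed(collapsed, annotation)


class TestSorting:
    def test_chromosomes_sort_lexicographically(self):
        records = [toy_record("chr2", 5, 10), toy_record("chr10", 0, 5),
                   toy_record("chr1", 50, 60)]
        assert [r.chrom for r in sort_records(records)] == \
            ["chr1", "chr10", "chr2"]

    def test_sorted_input_unchanged(self):
        records = [toy_record("chr1", 0, 5), toy_record("chr1", 5, 9)]
        assert sort_records(records) == records

    def test_ties_broken_by_end(self):
        records = [toy_record("chr1", 0, 9, "b"), toy_record("chr1", 0, 5, "a")]
        assert [r.name for r in sort_records(records)] == ["a", "b"]


class TestDialects:
    @pytest.mark.parametrize("dialect,n_fields",
                             [("plus3", 9), ("plus4", 10), ("plus5", 11)])
    def test_field_counts_and_round_trip(self, tmp_path, dialect, n_fields):
        records = sort_records([toy_record("chr1", 0, 5, "a", scores=(1.5, 0, 2)),
                                toy_record("chr2", 3, 9, "b", score=1000,
                                           scores=(0.25, 3.5, 1))])
        path = tmp_path / "track.bed"
        write_barchart_bed(records, path, dialect)
        lines = path.read_text().splitlines()
        assert all(len(l.split("\t")) == n_fields for l in lines)
        assert read_barchart_bed(path, dialect) == records

    def test_exp_scores_formatting(self, tmp_path):
        path = tmp_path / "track.bed"
        write_barchart_bed([toy_record(scores=(1.5, 0, 2))], path, "plus3")
        assert path.read_text().split("\t")[8].strip() == "1.5,0,2"

    def test_unsorted_input_rejected(self, tmp_path):
        records = [toy_record("chr2", 0, 5), toy_record("chr1", 0, 5)]
        with pytest.raises(ValueError, match="not sorted"):
            write_barchart_bed(records, tmp_path / "track.bed")

    def test_placeholder_columns_are_literal_zero(self, tmp_path):
        path = tmp_path / "track.bed"
        write_barchart_bed([toy_record()], path, "plus5")
        fields = path.read_text().strip().split("\t")
        assert fields[9] == "0" and fields[10] == "0"


class TestAnnotationIO:
    def test_gff3_coordinates_shifted_to_bed(self, tmp_path):
        path = tmp_path / "genes.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tID=g1;Name=G1\n"
            "chr1\tsrc\tmRNA\t1001\t2000\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr2\tsrc\tgene\t501\t700\t.\t-\t.\tID=g2\n")
        ann = read_annotation(path)
        assert len(ann) == 2  # only gene features
        assert ann.iloc[0]["start"] == 1000 and ann.iloc[0]["end"] == 2000
        assert ann.iloc[0]["gene_name"] == "G1"
        assert ann.iloc[1]["gene_name"] == "g2"  # falls back to the id
        assert ann.iloc[1]["strand"] == "-"

    def test_bed_and_gff_agree_on_intervals(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("chr1\t1000\t2000\tg1\t0\t+\n")
        gff = tmp_path / "genes.gff3"
        gff.write_text("chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tID=g1\n")
        a, b = read_annotation(bed), read_annotation(gff)
        assert a[["chrom", "start", "end", "gene_id", "strand"]].equals(
            b[["chrom", "start", "end", "gene_id", "strand"]])

    def test_fixture_annotation_round_trip(self, annotation, tmp_path):
        path = tracks.write_annotation_bed(annotation, tmp_path / "ann.bed")
        back = read_annotation(path)
        assert back.equals(annotation.reset_index(drop=True))
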