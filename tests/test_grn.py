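"""Tree-ensemble network inference: importances, ranking, hubs, HTML export."""

import json
import re

import numpy as np
import pandas as pd
import pytest

from scbroker.grn import (GRNConfig, export_html, hub_scores, infer_network,
                          match_tfs, rank_edges, read_edges, read_tf_list,
                          select_cells, write_edges)


def matrix_from_rows(rows: dict) -> pd.DataFrame:
    n = len(next(iter(rows.values())))
    return pd.DataFrame(rows, index=[f"c{i:03d}" for i in range(n)]).T


def exhaustive_variance_reduction(x: np.ndarray, y: np.ndarray) -> float:
    """Brute-force depth-1 oracle: best weighted variance reduction over all
    axis-aligned splits of x."""
    n = len(y)
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    base = np.var(ys)
    best = 0.0
    for i in range(1, n):
        if xs[i] == xs[i - 1]:
            continue
        left, right = ys[:i], ys[i:]
        reduction = base - (i / n) * np.var(left) - ((n - i) / n) * np.var(right)
        best = max(best, reduction)
    return best


@pytest.fixture(scope="module")
def planted_pair():
    """y driven by TF1 (slope 2, noise sd 0.1); TF2 independent noise; n=200."""
    rng = np.random.default_rng(5)
    tf1 = rng.normal(size=200)
    tf2 = rng.normal(size=200)
    y = 2.0 * tf1 + rng.normal(0, 0.1, size=200)
    return matrix_from_rows({"TF1": tf1, "TF2": tf2, "y": y})


class TestSelectCells:
    def test_fixture_label_counts(self, expression):
        matrix, labels, _ = expression
        sub = select_cells(matrix, labels, "CD4_T")
        assert sub.shape == (40, 50)  # round-robin over 4 labels
        assert list(sub.index) == list(matrix.index)

    def test_unknown_label_lists_available(self, expression):
        matrix, labels, _ = expression
        with pytest.raises(ValueError, match="CD4_T"):
            select_cells(matrix, labels, "CD8_T")

    def test_label_covering_no_matrix_cells(self, expression):
        matrix, labels, _ = expression
        labels = labels.copy()
        labels["ghost_cell"] = "Treg"
        with pytest.raises(ValueError, match="covers no matrix cells"):
            select_cells(matrix, labels, "Treg")

    def test_no_filter_is_identity(self, expression):
        matrix, labels, _ = expression
        assert select_cells(matrix, labels, None) is matrix


class TestInference:
    def test_true_regulator_outranks_decoy(self, planted_pair):
        table = infer_network(planted_pair, ["TF1", "TF2"],
                              GRNConfig(seed=3))
        by_edge = table.set_index(["tf", "target"])["importance"]
        assert by_edge[("TF1", "y")] > by_edge[("TF2", "y")]

    def test_zero_variance_target_gets_exact_zero(self, planted_pair):
        matrix = planted_pair.copy()
        matrix.loc["flat"] = 3.14
        table = infer_network(matrix, ["TF1", "TF2"], GRNConfig(seed=3))
        incoming = table[table["target"] == "flat"]["importance"]
        assert (incoming == 0.0).all()

    def test_no_self_edges(self, planted_pair):
        table = infer_network(planted_pair, ["TF1", "TF2"], GRNConfig(seed=3))
        assert not (table["tf"] == table["target"]).any()
        # every other TF→gene pair is emitted
        assert len(table) == 2 * 2  # 2 TFs × (1 other TF + 1 gene)

    def test_importances_are_non_negative(self, planted_pair):
        table = infer_network(planted_pair, ["TF1", "TF2"], GRNConfig(seed=3))
        assert (table["importance"] >= 0).all()

    def test_deterministic_and_cell_order_invariant(self, planted_pair):
        cfg = GRNConfig(n_trees=20, seed=9)
        first = infer_network(planted_pair, ["TF1", "TF2"], cfg)
        second = infer_network(planted_pair, ["TF1", "TF2"], cfg)
        shuffled = planted_pair[list(planted_pair.columns[::-1])]
        third = infer_network(shuffled, ["TF1", "TF2"], cfg)
        pd.testing.assert_frame_equal(first, second)
        pd.testing.assert_frame_equal(first, third)

    def test_single_tree_matches_exhaustive_split_oracle(self, planted_pair):
        """One depth-1 tree, one informative TF: the importance equals the
        brute-force best-split variance reduction."""
        matrix = planted_pair.copy()
        matrix.loc["TF2"] = 1.0  # constant decoy: never splittable
        cfg = GRNConfig(n_trees=1, max_depth=1, bootstrap=False,
                        max_features=1.0, seed=0)
        table = infer_network(matrix, ["TF1", "TF2"], cfg)
        by_edge = table.set_index(["tf", "target"])["importance"]
        x = matrix.loc["TF1"].to_numpy()
        y = matrix.loc["y"].to_numpy()
        oracle = exhaustive_variance_reduction(x, y)
        assert by_edge[("TF1", "y")] == pytest.approx(oracle, rel=1e-10)
        assert by_edge[("TF2", "y")] == 0.0

    def test_extra_trees_variant_runs(self, planted_pair):
        cfg = GRNConfig(n_trees=10, seed=2, method="extra", bootstrap=False)
        table = infer_network(planted_pair, ["TF1", "TF2"], cfg)
        by_edge = table.set_index(["tf", "target"])["importance"]
        assert by_edge[("TF1", "y")] > by_edge[("TF2", "y")]

    def test_normalized_importances_sum_to_one_per_target(self, planted_pair):
        cfg = GRNConfig(n_trees=10, seed=2, normalize=True)
        table = infer_network(planted_pair, ["TF1", "TF2"], cfg)
        sums = table.groupby("target")["importance"].sum()
        assert np.allclose(sums, 1.0)

    def test_too_few_tfs_rejected(self, planted_pair):
        with pytest.raises(ValueError, match="at least 2 transcription factors"):
            infer_network(planted_pair, ["TF1"], GRNConfig())

    def test_too_few_cells_rejected(self):
        tiny = matrix_from_rows({"TF1": [1, 2, 3], "TF2": [3, 2, 1],
                                 "y": [1, 1, 2]})
        with pytest.raises(ValueError, match="at least 5 cells"):
            infer_network(tiny, ["TF1", "TF2"], GRNConfig())


class TestRankingAndHubs:
    def test_higher_importance_ranks_first(self):
        table = pd.DataFrame({"tf": ["a", "b"], "target": ["x", "x"],
                              "importance": [0.5, 0.9]})
        ranked = rank_edges(table)
        assert ranked.iloc[0][["tf", "rank"]].tolist() == ["b", 1]
        assert ranked["rank"].tolist() == [1, 2]

    def test_ties_break_lexicographically(self):
        table = pd.DataFrame({"tf": ["b", "a", "a"],
                              "target": ["x", "y", "x"],
                              "importance": [0.5, 0.5, 0.5]})
        ranked = rank_edges(table)
        assert list(zip(ranked["tf"], ranked["target"])) == \
            [("a", "x"), ("a", "y"), ("b", "x")]

    def test_top_n_truncation(self):
        table = pd.DataFrame({"tf": ["t"] * 100,
                              "target": [f"g{i:03d}" for i in range(100)],
                              "importance": np.linspace(1, 0, 100)})
        ranked = rank_edges(table, top_n=8)
        assert len(ranked) == 8
        assert ranked["rank"].tolist() == list(range(1, 9))

    def test_star_hub_score(self):
        table = pd.DataFrame({"tf": ["A"] * 5,
                              "target": [f"g{i}" for i in range(5)],
                              "importance": [1.0] * 5})
        assert hub_scores(table) == {"A": 5.0}

    def test_hubs_sorted_descending(self):
        table = pd.DataFrame({"tf": ["A", "B", "B"],
                              "target": ["x", "y", "z"],
                              "importance": [1.0, 2.0, 3.0]})
        assert list(hub_scores(table)) == ["B", "A"]

    def test_empty_table_gives_empty_hub_map(self):
        assert hub_scores(pd.DataFrame(columns=["tf", "target",
                                                "importance"])) == {}

    def test_edge_table_tsv_round_trip(self, tmp_path):
        table = rank_edges(pd.DataFrame({"tf": ["a", "b"],
                                         "target": ["x", "y"],
                                         "importance": [0.25, 0.75]}))
        path = write_edges(table, tmp_path / "edges.tsv")
        pd.testing.assert_frame_equal(read_edges(path), table)


class TestTFList:
    def test_comments_and_duplicates_handled(self, tmp_path):
        path = tmp_path / "tfs.txt"
        path.write_text("# regulators\nHMGB2\nTCF7  # T-cell factor\nhmgb2\n\n")
        assert read_tf_list(path) == ["HMGB2", "TCF7"]

    def test_matching_is_case_insensitive(self):
        matched, unmatched = match_tfs(["hmgb2", "NOPE"], ["HMGB2", "CD4"])
        assert matched == ["HMGB2"]
        assert unmatched == ["NOPE"]


class TestHtmlExport:
    def payload(self, path):
        html = path.read_text()
        blob = re.search(r'id="graph-data">(.*?)</script>', html,
                         re.S).group(1)
        return json.loads(blob)

    def test_embedded_json_matches_edge_list(self, tmp_path):
        table = rank_edges(pd.DataFrame({
            "tf": ["a", "a", "b"], "target": ["x", "y", "x"],
            "importance": [0.9, 0.5, 0.1]}))
        path = export_html(table, tmp_path / "net.html")
        payload = self.payload(path)
        assert len(payload["edges"]) == 3
        assert len(payload["nodes"]) <= 6
        back = [(e["source"], e["target"], e["importance"])
                for e in payload["edges"]]
        assert back == list(zip(table["tf"], table["target"],
                                table["importance"]))

    def test_empty_table_yields_valid_page(self, tmp_path):
        table = pd.DataFrame(columns=["tf", "target", "importance"])
        path = export_html(table, tmp_path / "net.html")
        assert "no edges" in path.read_text()
        assert self.payload(path) == {"nodes": [], "edges": []}

    def test_page_is_self_contained(self, tmp_path):
        table = rank_edges(pd.DataFrame({"tf": ["a"], "target": ["x"],
                                         "importance": [1.0]}))
        html = export_html(table, tmp_path / "net.html").read_text()
        assert "http" not in html.replace("http://www.w3.org/2000/svg", "")
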