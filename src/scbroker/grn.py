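"""Tree-ensemble gene regulatory network inference (GENIE3-style).

For every gene g in the expression matrix, an ensemble of regression trees is
fitted to predict g's expression across cells from the expression of the
transcription factors (excluding g itself when g is a TF). The importance of
the edge TF → g is the TF's total variance-reduction (impurity-decrease)
importance averaged across the trees of g's ensemble — unnormalized, so
per-target importance sums may differ; a per-target normalization flag is
available. Edges are ranked by importance across all targets, and a
regulator's hub score is the sum of its outgoing edge importances.

The default ensemble is random-forest-like (bootstrap resampling, "sqrt"
feature subsampling), matching the GENIE3 default; an extremely-randomized
variant is available via ``method="extra"``. Cells are canonicalized to
lexicographic order before fitting, so results are invariant to the column
order of the input matrix and fully determined by the configuration seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesRegressor, RandomForestRegressor

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["tf", "target", "importance", "rank"]


@dataclass
class GRNConfig:
    """Ensemble hyperparameters and run controls.

    n_trees: trees per target-gene ensemble (default 100).
    max_features: feature subsample per split — "sqrt" or a fraction.
    seed: master seed; per-target tree seeds are derived from it.
    cell_type_filter: optional label to restrict cells before inference.
    method: "rf" (bootstrap random forest) or "extra" (extremely randomized).
    max_depth / bootstrap: tree controls, mainly for oracle comparisons.
    normalize: divide each target's importances by their sum when positive.
    """

    n_trees: int = 100
    max_features: float | str = "sqrt"
    seed: int = 0
    cell_type_filter: str | None = None
    method: str = "rf"
    max_depth: int | None = None
    bootstrap: bool = True
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.method not in ("rf", "extra"):
            raise ValueError(f"unknown method: {self.method!r}")


def read_tf_list(path: str | Path) -> list[str]:
    """Plain-text TF list: one symbol per line, '#' comments, duplicates dropped."""
    symbols: list[str] = []
    seen = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            symbol = line.split("#", 1)[0].strip()
            if symbol and symbol.lower() not in seen:
                seen.add(symbol.lower())
                symbols.append(symbol)
    if not symbols:
        raise ValueError(f"no transcription factors found in {path}")
    return symbols


def match_tfs(symbols: list[str], gene_ids) -> tuple[list[str], list[str]]:
    """Match TF symbols to matrix gene ids, exact but case-insensitive.

    Returns (matched matrix gene ids, unmatched symbols); matched ids keep the
    matrix's spelling and the TF list's order.
    """
    lookup = {str(g).lower(): str(g) for g in gene_ids}
    matched, unmatched = [], []
    for symbol in symbols:
        hit = lookup.get(symbol.lower())
        (matched if hit is not None else unmatched).append(hit or symbol)
    return matched, unmatched


def select_cells(matrix: pd.DataFrame, celltypes: pd.Series,
                 label: str | None) -> pd.DataFrame:
    """Restrict the matrix to cells carrying ``label``; genes unchanged."""
    if label is None:
        return matrix
    available = sorted(celltypes.unique())
    if label not in available:
        raise ValueError(
            f"unknown cell-type label {label!r}; available: {available}")
    cells = [c for c in matrix.columns if celltypes.get(c) == label]
    if not cells:
        raise ValueError(
            f"label {label!r} exists in metadata but covers no matrix cells")
    return matrix[cells]


def _make_estimator(cfg: GRNConfig, n_features: int, seed: int):
    cls = RandomForestRegressor if cfg.method == "rf" else ExtraTreesRegressor
    max_features = cfg.max_features
    if isinstance(max_features, str) and max_features == "sqrt" and n_features == 1:
        max_features = 1.0
    return cls(n_estimators=cfg.n_trees, max_features=max_features,
               max_depth=cfg.max_depth, bootstrap=cfg.bootstrap,
               random_state=seed, n_jobs=1)


def _tree_importances(estimator) -> np.ndarray:
    """Mean over trees of the unnormalized impurity-decrease importances.

    Each tree contributes its per-feature total variance reduction (weighted
    by node sample fractions), without the per-tree sum-to-one normalization
    sklearn applies in ``feature_importances_``.
    """
    per_tree = [tree.tree_.compute_feature_importances(normalize=False)
                for tree in estimator.estimators_]
    return np.mean(per_tree, axis=0)


def infer_network(matrix: pd.DataFrame, tf_symbols: list[str],
                  cfg: GRNConfig | None = None) -> pd.DataFrame:
    """Fit one tree ensemble per gene; return the ranked TF→target edge table.

    Every TF→gene importance is emitted (self-edges excluded by construction).
    Zero-variance targets receive exactly 0 importance without fitting.
    Deterministic given the configuration seed.
    """
    cfg = cfg or GRNConfig()
    matrix = matrix[sorted(matrix.columns)]  # canonical cell order
    if matrix.shape[1] < 5:
        raise ValueError("need at least 5 cells for network inference")
    tf_ids, unmatched = match_tfs(tf_symbols, matrix.index)
    if unmatched:
        logger.warning("%d TF symbols not in matrix: %s",
                       len(unmatched), unmatched[:5])
    if len(tf_ids) < 2:
        raise ValueError(
            f"need at least 2 transcription factors present in the matrix, "
            f"found {len(tf_ids)}")

    tf_expr = {tf: matrix.loc[tf].to_numpy(dtype=float) for tf in tf_ids}
    seeds = np.random.RandomState(cfg.seed).randint(
        0, 2**31 - 1, size=matrix.shape[0])

    rows = []
    for gi, gene in enumerate(matrix.index):
        predictors = [tf for tf in tf_ids if tf != gene]
        if not predictors:
            continue
        y = matrix.loc[gene].to_numpy(dtype=float)
        if np.var(y) == 0.0:
            importances = np.zeros(len(predictors))
        else:
            X = np.column_stack([tf_expr[tf] for tf in predictors])
            est = _make_estimator(cfg, len(predictors), int(seeds[gi]))
            est.fit(X, y)
            importances = _tree_importances(est)
        if cfg.normalize:
            total = importances.sum()
            if total > 0:
                importances = importances / total
        for tf, imp in zip(predictors, importances):
            rows.append((tf, gene, float(imp)))

    table = pd.DataFrame(rows, columns=["tf", "target", "importance"])
    return rank_edges(table)


def rank_edges(table: pd.DataFrame, top_n: int | None = None) -> pd.DataFrame:
    """Sort by importance descending (ties broken by (tf, target) lexicographic),
    reassign ranks 1..N, and optionally truncate to the top ``top_n`` edges."""
    out = table.sort_values(
        by=["importance", "tf", "target"],
        ascending=[False, True, True], kind="mergesort").reset_index(drop=True)
    if top_n is not None:
        out = out.head(top_n).copy()
    out["rank"] = np.arange(1, len(out) + 1)
    return out[EDGE_COLUMNS]


def hub_scores(table: pd.DataFrame) -> dict[str, float]:
    """Total outgoing importance per regulator, sorted descending.

    The strongest hub (largest total) comes first; ties are broken by TF name.
    """
    if table.empty:
        return {}
    sums = table.groupby("tf")["importance"].sum()
    ordered = sorted(sums.items(), key=lambda kv: (-kv[1], kv[0]))
    return dict(ordered)


def write_edges(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table[EDGE_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_edges(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Self-contained interactive HTML export

_HTML_TEMPLATE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>Regulatory network</title>
<style>
  body {{ font-family: sans-serif; margin: 0; }}
  #info {{ position: absolute; top: 8px; left: 8px; background: #ffffffcc;
          padding: 6px 10px; border-radius: 4px; font-size: 13px; }}
  svg {{ width: 100vw; height: 100vh; display: block; }}
  .tf {{ fill: #d62728; }}
  .target {{ fill: #1f77b4; }}
  text {{ font-size: 10px; pointer-events: none; }}
  line {{ stroke: #999; }}
</style>
</head>
<body>
<div id="info">{message}</div>
<svg id="net"></svg>
<script type="application/json" id="graph-data">{payload}</script>
<script>
(function () {{
  var data = JSON.parse(document.getElementById("graph-data").textContent);
  if (!data.edges.length) return;
  var svg = document.getElementById("net");
  var W = window.innerWidth, H = window.innerHeight;
  var nodes = data.nodes.map(function (n, i) {{
    var a = 2 * Math.PI * i / data.nodes.length;
    return {{id: n.id, role: n.role, x: W / 2 + 200 * Math.cos(a),
             y: H / 2 + 200 * Math.sin(a), vx: 0, vy: 0}};
  }});
  var index = {{}};
  nodes.forEach(function (n) {{ index[n.id] = n; }});
  var edges = data.edges;
  var maxImp = Math.max.apply(null, edges.map(function (e) {{
    return e.importance; }})) || 1;
  // simple force relaxation: spring edges + pairwise repulsion
  for (var it = 0; it < 300; it++) {{
    edges.forEach(function (e) {{
      var a = index[e.source], b = index[e.target];
      var dx = b.x - a.x, dy = b.y - a.y;
      var d = Math.sqrt(dx * dx + dy * dy) || 1;
      var f = (d - 120) * 0.01;
      a.vx += f * dx / d; a.vy += f * dy / d;
      b.vx -= f * dx / d; b.vy -= f * dy / d;
    }});
    for (var i = 0; i < nodes.length; i++)
      for (var j = i + 1; j < nodes.length; j++) {{
        var dx = nodes[j].x - nodes[i].x, dy = nodes[j].y - nodes[i].y;
        var d2 = dx * dx + dy * dy + 0.01, f = 2000 / d2;
        var d = Math.sqrt(d2);
        nodes[i].vx -= f * dx / d; nodes[i].vy -= f * dy / d;
        nodes[j].vx += f * dx / d; nodes[j].vy += f * dy / d;
      }}
    nodes.forEach(function (n) {{
      n.x += n.vx * 0.5; n.y += n.vy * 0.5; n.vx *= 0.6; n.vy *= 0.6;
      n.x = Math.max(20, Math.min(W - 20, n.x));
      n.y = Math.max(20, Math.min(H - 20, n.y));
    }});
  }}
  var ns = "http://www.w3.org/2000/svg";
  edges.forEach(function (e) {{
    var a = index[e.source], b = index[e.target];
    var line = document.createElementNS(ns, "line");
    line.setAttribute("x1", a.x); line.setAttribute("y1", a.y);
    line.setAttribute("x2", b.x); line.setAttribute("y2", b.y);
    line.setAttribute("stroke-width", 0.5 + 3 * e.importance / maxImp);
    var t = document.createElementNS(ns, "title");
    t.textContent = e.source + " \\u2192 " + e.target +
      " (importance " + e.importance.toFixed(4) + ")";
    line.appendChild(t);
    svg.appendChild(line);
  }});
  nodes.forEach(function (n) {{
    var c = document.createElementNS(ns, "circle");
    c.setAttribute("cx", n.x); c.setAttribute("cy", n.y);
    c.setAttribute("r", n.role === "tf" ? 8 : 5);
    c.setAttribute("class", n.role);
    var t = document.createElementNS(ns, "title");
    t.textContent = n.id + " (" + n.role + ")";
    c.appendChild(t);
    svg.appendChild(c);
    var label = document.createElementNS(ns, "text");
    label.setAttribute("x", n.x + 9); label.setAttribute("y", n.y + 3);
    label.textContent = n.id;
    svg.appendChild(label);
  }});
}})();
</script>
</body>
</html>
"""


def export_html(table: pd.DataFrame, path: str | Path,
                top_n: int | None = None) -> Path:
    """Write a self-contained interactive network page (no network fetches).

    The node-link data is embedded as JSON in a ``graph-data`` script block;
    a small vanilla-JS force layout renders regulators (red) and targets
    (blue) with edge widths proportional to importance.
    """
    if top_n is not None:
        table = rank_edges(table, top_n)
    tfs = list(dict.fromkeys(table["tf"])) if not table.empty else []
    targets = [t for t in dict.fromkeys(table["target"])
               if t not in set(tfs)] if not table.empty else []
    payload = {
        "nodes": ([{"id": t, "role": "tf"} for t in tfs]
                  + [{"id": t, "role": "target"} for t in targets]),
        "edges": [{"source": r.tf, "target": r.target,
                   "importance": float(r.importance)}
                  for r in table.itertuples()],
    }
    message = (f"{len(payload['edges'])} edges, {len(payload['nodes'])} genes"
               if payload["edges"] else "no edges")
    path = Path(path)
    path.write_text(
        _HTML_TEMPLATE.format(payload=json.dumps(payload), message=message),
        encoding="utf-8")
    return path
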