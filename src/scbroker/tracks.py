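"""Pseudobulk collapse and barChart BED track generation.

Collapses a genes×cells expression matrix into genes×cell-types by a summary
statistic (mean by default, median for robustness), joins the collapsed
matrix to gene annotations, and writes sorted barChart BED records — the
per-gene, per-cell-type histogram tracks a genome browser renders.

Conventions: BED coordinates are 0-based half-open throughout (GFF3 input is
shifted on read); chromosome sort order is plain lexicographic, matching the
classic bedSort utility, so "chr10" precedes "chr2". The BED score column is
derived here as round(1000 · max(exp_scores) / global_max) — a display
scaling, not a statistical quantity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STATS = ("mean", "median")
DIALECTS = ("plus3", "plus4", "plus5")

ANNOTATION_COLUMNS = ["chrom", "start", "end", "gene_id", "gene_name", "strand"]


@dataclass(frozen=True)
class BarChartRecord:
    """One gene's location plus its per-cell-type expression vector.

    ``exp_scores`` is ordered by the fixed global cell-type ordering
    (lexicographic column order of the collapsed matrix); ``exp_count`` always
    equals its length, and ``score`` is an integer in [0, 1000].
    """

    chrom: str
    start: int
    end: int
    name: str
    score: int
    strand: str
    name2: str
    exp_count: int
    exp_scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.name}: start must be < end")
        if self.exp_count != len(self.exp_scores):
            raise ValueError(f"{self.name}: exp_count != len(exp_scores)")
        if not 0 <= self.score <= 1000:
            raise ValueError(f"{self.name}: score {self.score} outside [0, 1000]")

    @property
    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end)


# ---------------------------------------------------------------------------
# Readers


def read_expr_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes×cells TSV matrix (first column gene id, header = cells)."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    if matrix.index.has_duplicates:
        raise ValueError("duplicate gene ids in expression matrix")
    if matrix.columns.has_duplicates:
        raise ValueError("duplicate cell ids in expression matrix")
    return matrix


def read_cell_meta(path: str | Path, celltype_col: str = "celltype") -> pd.Series:
    """Read per-cell metadata; return the cell-type label Series."""
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if celltype_col not in meta.columns:
        raise ValueError(
            f"cell metadata has no column {celltype_col!r}; available: "
            f"{list(meta.columns)}")
    labels = meta[celltype_col]
    if labels.isna().any() or (labels == "").any():
        raise ValueError("empty cell-type labels in metadata")
    return labels


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read gene annotations from BED6(+1) or GFF3 (gene features only).

    Returns a DataFrame with columns chrom, start, end, gene_id, gene_name,
    strand in BED convention (0-based half-open). A 7th BED column, when
    present, supplies the gene symbol; otherwise gene_name = gene_id. GFF3
    coordinates are 1-based inclusive and are shifted by start−1 on read.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        rows = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9 or parts[2] != "gene":
                    continue
                attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
                gene_id = attrs.get("gene_id") or attrs.get("ID", "")
                rows.append({"chrom": parts[0], "start": int(parts[3]) - 1,
                             "end": int(parts[4]), "gene_id": gene_id,
                             "gene_name": attrs.get("Name", gene_id),
                             "strand": parts[6] if parts[6] in "+-" else "."})
        ann = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    else:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if raw.shape[1] < 6:
            raise ValueError("annotation BED must have at least 6 columns")
        ann = pd.DataFrame({
            "chrom": raw[0], "start": raw[1].astype(int),
            "end": raw[2].astype(int), "gene_id": raw[3],
            "gene_name": raw[6] if raw.shape[1] > 6 else raw[3],
            "strand": raw[5],
        })
    if (ann["start"] >= ann["end"]).any():
        raise ValueError("annotation contains intervals with start >= end")
    if (ann["chrom"] == "").any():
        raise ValueError("annotation contains empty chromosome names")
    return ann


def write_annotation_bed(ann: pd.DataFrame, path: str | Path) -> Path:
    """Write annotations as BED6+1 (7th column = gene symbol)."""
    path = Path(path)
    out = ann[["chrom", "start", "end", "gene_id"]].copy()
    out["score"] = 0
    out["strand"] = ann["strand"]
    out["gene_name"] = ann["gene_name"]
    out.to_csv(path, sep="\t", header=False, index=False)
    return path


# ---------------------------------------------------------------------------
# Collapse


def collapse_by_celltype(matrix: pd.DataFrame, celltypes: pd.Series,
                         stat: str = "mean") -> pd.DataFrame:
    """Aggregate a genes×cells matrix into genes×cell-types.

    Entry (g, t) is ``stat`` (mean or median) over the cells labelled t.
    Columns are ordered lexicographically by cell-type label. Every matrix
    cell must be present in the metadata.
    """
    if stat not in STATS:
        raise ValueError(f"unknown statistic: {stat!r} (choose from {STATS})")
    missing = matrix.columns.difference(celltypes.index)
    if len(missing) > 0:
        raise ValueError(
            f"{len(missing)} matrix cells absent from metadata, e.g. "
            f"{list(missing[:3])}")
    labels = celltypes.reindex(matrix.columns)
    if labels.empty:
        raise ValueError("matrix has no cells")
    collapsed = matrix.T.groupby(labels, sort=True).agg(stat).T
    collapsed.columns.name = None
    return collapsed


# ---------------------------------------------------------------------------
# barChart BED records


def make_barchart_bed(collapsed: pd.DataFrame,
                      ann: pd.DataFrame) -> list[BarChartRecord]:
    """Join the collapsed matrix to gene annotations.

    One record per annotated gene present in the matrix; genes without an
    annotation are skipped (a count is logged). The BED score scales each
    gene's maximum expression against the global maximum into [0, 1000]
    (0 everywhere when the global maximum is 0).
    """
    present = ann["gene_id"].isin(collapsed.index)
    if not present.any():
        raise ValueError("no overlap between matrix genes and annotation")
    skipped = collapsed.index.difference(ann["gene_id"])
    if len(skipped) > 0:
        logger.info("skipping %d matrix genes without annotation", len(skipped))
    included = ann.loc[present]
    sub = collapsed.loc[included["gene_id"]]
    global_max = float(sub.values.max())
    records = []
    for (_, row), (_, scores) in zip(included.iterrows(), sub.iterrows()):
        exp_scores = tuple(float(v) for v in scores)
        score = (int(round(1000 * max(exp_scores) / global_max))
                 if global_max > 0 else 0)
        records.append(BarChartRecord(
            chrom=row["chrom"], start=int(row["start"]), end=int(row["end"]),
            name=row["gene_id"], score=score, strand=row["strand"],
            name2=row["gene_name"], exp_count=len(exp_scores),
            exp_scores=exp_scores))
    return records


def sort_records(records: list[BarChartRecord]) -> list[BarChartRecord]:
    """Order by (chrom lexicographic, start, end); stable for ties."""
    return sorted(records, key=lambda r: r.sort_key)


def _is_sorted(records: list[BarChartRecord]) -> bool:
    return all(a.sort_key <= b.sort_key for a, b in zip(records, records[1:]))


def _fmt(value: float) -> str:
    """Compact decimal formatting: 1.5 → "1.5", 2.0 → "2", 0.0 → "0"."""
    return np.format_float_positional(float(value), trim="-")


def write_barchart_bed(records: list[BarChartRecord], path: str | Path,
                       dialect: str = "plus4") -> Path:
    """Write sorted records as a tab-separated barChart BED file.

    BED6 columns, then per dialect: plus3 = name2, expCount, expScores
    (comma-joined); plus4 adds a literal "0" offset placeholder; plus5 adds a
    second "0" length placeholder. The placeholders are non-functional in
    text output. Input must already be sorted.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect: {dialect!r} (choose from {DIALECTS})")
    if not _is_sorted(records):
        raise ValueError("records are not sorted; call sort_records first")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fields = [r.chrom, str(r.start), str(r.end), r.name, str(r.score),
                      r.strand, r.name2, str(r.exp_count),
                      ",".join(_fmt(v) for v in r.exp_scores)]
            if dialect in ("plus4", "plus5"):
                fields.append("0")
            if dialect == "plus5":
                fields.append("0")
            fh.write("\t".join(fields) + "\n")
    return path


def read_barchart_bed(path: str | Path,
                      dialect: str = "plus4") -> list[BarChartRecord]:
    """Inverse of :func:`write_barchart_bed`."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect: {dialect!r}")
    expected = {"plus3": 9, "plus4": 10, "plus5": 11}[dialect]
    records = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != expected:
                raise ValueError(
                    f"line {ln}: expected {expected} fields for {dialect}, "
                    f"got {len(parts)}")
            records.append(BarChartRecord(
                chrom=parts[0], start=int(parts[1]), end=int(parts[2]),
                name=parts[3], score=int(parts[4]), strand=parts[5],
                name2=parts[6], exp_count=int(parts[7]),
                exp_scores=tuple(float(v) for v in parts[8].split(","))))
    return records


def build_track(matrix: pd.DataFrame, celltypes: pd.Series, ann: pd.DataFrame,
                path: str | Path, stat: str = "mean",
                dialect: str = "plus4") -> list[BarChartRecord]:
    """Collapse → record construction → sort → write, in one call."""
    collapsed = collapse_by_celltype(matrix, celltypes, stat)
    records = sort_records(make_barchart_bed(collapsed, ann))
    write_barchart_bed(records, path, dialect)
    return records
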