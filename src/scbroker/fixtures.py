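"""Synthetic inputs for offline testing of every other module.

Three generators, all pure functions of a :class:`FixtureSpec` (seed
included):

* :func:`make_submission` — a PBMC-like submission at desk scale: a small
  cohort of healthy pig donors, one blood specimen each, one scRNA-seq
  library per specimen, and two fastq records per library, plus a project
  block citing the study accession.
* :func:`make_expression` — a planted linear regulatory network: TF
  expressions i.i.d. standard normal, each designated target a positive
  linear combination of its planted parent TFs plus Gaussian noise, the
  remaining genes independent background noise. Cells are assigned
  round-robin to four PBMC-like labels. The whole matrix is shifted by its
  global minimum so values are non-negative (count-like), which preserves
  tree splits and variances. The planted adjacency is returned as ground
  truth for recovery tests.
* :func:`make_annotation` — a toy gene annotation: non-overlapping 1 kb
  intervals on two chromosomes, alternating strands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .broker import ProjectBlock
from .faang import (FAANGSubmission, MetadataDocument, default_ruleset,
                    save_ruleset, write_submission)
from .tracks import ANNOTATION_COLUMNS, write_annotation_bed

CELL_TYPE_LABELS = ("CD4_T", "B", "NK", "Mono")

#: Study accession of the porcine PBMC dataset the fixtures emulate.
STUDY_ACCESSION = "PRJEB43826"


@dataclass(frozen=True)
class FixtureSpec:
    """Scale and noise parameters of the synthetic inputs."""

    n_donors: int = 7
    n_cells: int = 200
    n_genes: int = 40
    n_tfs: int = 5
    n_targets: int = 15
    parents_per_target: int = 2
    noise_sd: float = 0.1
    seed: int = 7

    def __post_init__(self) -> None:
        for name in ("n_donors", "n_cells", "n_genes", "n_tfs", "n_targets",
                     "parents_per_target"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_tfs >= self.n_genes:
            raise ValueError("n_tfs must be < n_genes")
        if self.n_tfs + self.n_targets > self.n_genes:
            raise ValueError("n_tfs + n_targets must be <= n_genes")
        if self.parents_per_target > self.n_tfs:
            raise ValueError("parents_per_target must be <= n_tfs")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_submission(spec: FixtureSpec = FixtureSpec()
                    ) -> tuple[FAANGSubmission, ProjectBlock]:
    """PBMC-like submission: per donor one organism record, one blood
    specimen, one scRNA-seq experiment, and two fastq analysis records."""
    rng = np.random.default_rng(spec.seed)
    sexes = ("male", "female")
    breeds = ("Duroc", "Landrace", "Yorkshire")
    sample_records, experiment_records, analysis_records = [], [], []
    for i in range(1, spec.n_donors + 1):
        donor = f"pig{i}"
        specimen = f"{donor}_pbmc"
        sample_records.append({
            "alias": donor,
            "material": "organism",
            "organism": "NCBITaxon:9823",
            "sex": sexes[(i - 1) % 2],
            "breed": breeds[(i - 1) % 3],
            "health_status": "normal",
        })
        sample_records.append({
            "alias": specimen,
            "material": "specimen from organism",
            "tissue": "UBERON:0000178",
            "derived_from": donor,
        })
        experiment = f"exp{i}"
        experiment_records.append({
            "alias": experiment,
            "assay_type": "scRNA-seq",
            "library_construction": "10x chromium 3prime",
            "sample_ref": specimen,
            "sequencing_platform": "Illumina NovaSeq 6000",
        })
        for read in (1, 2):
            analysis_records.append({
                "alias": f"run{i}_r{read}",
                "file_name": f"{experiment}_R{read}.fastq.gz",
                "file_type": "fastq",
                "checksum": rng.bytes(16).hex(),
                "experiment_ref": experiment,
            })
    sub = FAANGSubmission(
        sample=MetadataDocument("sample", sample_records, "json"),
        experiment=MetadataDocument("experiment", experiment_records, "json"),
        analysis=MetadataDocument("analysis", analysis_records, "json"),
    )
    project = ProjectBlock(
        title="Porcine PBMC single-cell ingestion pilot",
        description=(f"Single-cell RNA-seq of peripheral blood mononuclear "
                     f"cells from {spec.n_donors} healthy pigs."),
        contributors=[{"name": "Fixture Author",
                       "institution": "Synthetic Data Unit"}],
        accessions=[STUDY_ACCESSION],
    )
    return sub, project


def make_expression(spec: FixtureSpec = FixtureSpec()
                    ) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Planted-network expression matrix, cell metadata, and true adjacency.

    Returns (matrix genes×cells, cell-type label Series, edges DataFrame with
    columns tf/target/effect). Effect sizes are drawn from Uniform(1, 3).
    """
    rng = np.random.default_rng(spec.seed)
    n_background = spec.n_genes - spec.n_tfs - spec.n_targets
    tf_names = [f"TF{i + 1}" for i in range(spec.n_tfs)]
    target_names = [f"G{i + 1}" for i in range(spec.n_targets)]
    background_names = [f"BG{i + 1}" for i in range(n_background)]

    tf_values = rng.normal(0.0, 1.0, size=(spec.n_tfs, spec.n_cells))
    edges = []
    target_values = np.empty((spec.n_targets, spec.n_cells))
    for ti, target in enumerate(target_names):
        parents = rng.choice(spec.n_tfs, size=spec.parents_per_target,
                             replace=False)
        effects = rng.uniform(1.0, 3.0, size=spec.parents_per_target)
        signal = effects @ tf_values[parents]
        noise = rng.normal(0.0, spec.noise_sd, size=spec.n_cells)
        target_values[ti] = signal + noise
        for parent, effect in zip(parents, effects):
            edges.append({"tf": tf_names[parent], "target": target,
                          "effect": float(effect)})
    background_values = rng.normal(0.0, 1.0, size=(n_background, spec.n_cells))

    values = np.vstack([tf_values, target_values, background_values])
    values = values - values.min()  # shift to non-negative, count-like scale
    cell_ids = [f"cell{i + 1:04d}" for i in range(spec.n_cells)]
    matrix = pd.DataFrame(values,
                          index=tf_names + target_names + background_names,
                          columns=cell_ids)
    labels = pd.Series(
        [CELL_TYPE_LABELS[i % len(CELL_TYPE_LABELS)]
         for i in range(spec.n_cells)],
        index=cell_ids, name="celltype")
    adjacency = pd.DataFrame(edges, columns=["tf", "target", "effect"])
    return matrix, labels, adjacency


def make_annotation(spec: FixtureSpec = FixtureSpec()) -> pd.DataFrame:
    """Toy annotation: one 1 kb interval per gene, alternating between two
    chromosomes (equal split) and between strands; gene_name = gene_id + "_sym"."""
    matrix, _, _ = make_expression(spec)
    rows = []
    counters = {"chr1": 0, "chr2": 0}
    for i, gene in enumerate(matrix.index):
        chrom = "chr1" if i % 2 == 0 else "chr2"
        k = counters[chrom]
        counters[chrom] += 1
        start = 1000 + 2000 * k
        rows.append({"chrom": chrom, "start": start, "end": start + 1000,
                     "gene_id": gene, "gene_name": f"{gene}_sym",
                     "strand": "+" if i % 2 == 0 else "-"})
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_fixtures(out_dir: str | Path,
                   spec: FixtureSpec = FixtureSpec()) -> dict[str, Path]:
    """Write every fixture in the formats the CLI commands consume."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    sub, project = make_submission(spec)
    doc_paths = write_submission(sub, out_dir, fmt="tsv")
    paths.update(doc_paths)
    project_path = out_dir / "project.json"
    with open(project_path, "w", encoding="utf-8") as fh:
        json.dump({"title": project.title, "description": project.description,
                   "contributors": project.contributors,
                   "accessions": project.accessions}, fh, indent=2)
        fh.write("\n")
    paths["project"] = project_path

    ruleset_path = out_dir / "ruleset.json"
    save_ruleset(default_ruleset(), ruleset_path)
    paths["ruleset"] = ruleset_path

    matrix, labels, adjacency = make_expression(spec)
    matrix_path = out_dir / "exprMatrix.tsv"
    matrix.to_csv(matrix_path, sep="\t", index_label="gene")
    paths["matrix"] = matrix_path
    meta_path = out_dir / "meta.tsv"
    labels.to_frame().to_csv(meta_path, sep="\t", index_label="cell")
    paths["meta"] = meta_path
    adjacency_path = out_dir / "planted_edges.tsv"
    adjacency.to_csv(adjacency_path, sep="\t", index=False)
    paths["adjacency"] = adjacency_path

    tf_path = out_dir / "tfs.txt"
    tf_path.write_text(
        "".join(f"TF{i + 1}\n" for i in range(spec.n_tfs)), encoding="utf-8")
    paths["tfs"] = tf_path

    annotation_path = out_dir / "annotation.bed"
    write_annotation_bed(make_annotation(spec), annotation_path)
    paths["annotation"] = annotation_path
    return paths
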