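"""Transform a validated FAANG-style submission into an HCA-style entity graph.

The conversion runs five fixed stages: (1) validate the submission against
the ruleset, (2) clean it by dropping recommended-tier fields (the target
schema recognises only mandatory and optional requirement levels), (3) split
the three flat documents into typed entities with system metadata injected
(described_by URI, schema version, UUID), (4) realize the reference fields
(derived_from, sample_ref, experiment_ref) as process links, and (5) validate
the resulting graph.

Reference fields are deliberately retained inside entity content after link
construction so that flattening the graph reproduces the cleaned input
field-for-field; a stricter archive pipeline would strip them.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import pandas as pd

from .faang import (FAANGSubmission, MetadataDocument, Ruleset,
                    validate_submission)
from .hca import (DEFAULT_BASE_URI, Entity, EntityGraph, Link, assign_uuid,
                  describe, flatten_graph, validate_graph)
from .report import ValidationReport


@dataclass
class ProjectBlock:
    """Project-level information absent from the three flat documents.

    The source portal has no project tab, so this block is supplied by the
    submitter (title, description, contributors, study accessions) and
    synthesized into the single project entity of the graph.
    """

    title: str
    description: str = ""
    contributors: list[dict] = field(default_factory=list)
    accessions: list[str] = field(default_factory=list)


@dataclass
class ConversionOptions:
    drop_recommended: bool = True
    schema_version: str = "1.0.0"
    uuid_namespace: str = "scbroker"
    base_uri: str = DEFAULT_BASE_URI
    random_uuids: bool = False

    def __post_init__(self) -> None:
        if not self.schema_version:
            raise ValueError("schema_version must be non-empty")


class CleanResult(NamedTuple):
    submission: FAANGSubmission
    manifest: list[dict]


class ConversionResult(NamedTuple):
    graph: EntityGraph
    metadata_report: ValidationReport
    graph_report: ValidationReport


def clean_documents(sub: FAANGSubmission, rules: Ruleset,
                    opts: ConversionOptions | None = None) -> CleanResult:
    """Drop recommended-tier fields; return the cleaned submission + manifest.

    The submission must validate (status pass) first. Mandatory and optional
    fields are preserved verbatim. The manifest records every removed
    (document, record, field) triple for auditability. With
    ``drop_recommended`` off the submission is returned unchanged.
    """
    opts = opts or ConversionOptions()
    report = validate_submission(sub, rules)
    if report.status == "fail":
        raise ValueError(
            "submission failed validation: "
            + "; ".join(i.message for i in report.errors))
    manifest: list[dict] = []
    docs = {}
    for doc in sub.documents():
        recommended = {r.name: r for r in rules.sections[doc.doc_type]
                       if r.tier == "recommended"}
        records = []
        for rec in doc.records:
            out = {}
            for key, value in rec.items():
                rule = recommended.get(key)
                if (opts.drop_recommended and rule is not None
                        and rule.applies_to(rec)):
                    manifest.append({"doc_type": doc.doc_type,
                                     "record_alias": rec["alias"],
                                     "field": key})
                    continue
                out[key] = value
            records.append(out)
        docs[doc.doc_type] = MetadataDocument(doc.doc_type, records, doc.source)
    return CleanResult(FAANGSubmission(docs["sample"], docs["experiment"],
                                       docs["analysis"]), manifest)


def synthesize_project(meta: ProjectBlock) -> Entity:
    """Build the single project entity from the submitter's project block."""
    if not meta.title:
        raise ValueError("project title must be non-empty")
    entity_id = re.sub(r"[^a-z0-9]+", "_", meta.title.lower()).strip("_")
    return Entity(
        entity_id=entity_id or "project",
        category="project",
        subcategory="project",
        content={
            "title": meta.title,
            "description": meta.description,
            "contributors": list(meta.contributors),
            "accessions": list(meta.accessions),
        },
    )


def _stamp(entity: Entity, opts: ConversionOptions) -> Entity:
    entity = describe(entity, opts.base_uri, opts.schema_version)
    return assign_uuid(entity, opts.uuid_namespace, random=opts.random_uuids)


def split_into_entities(sub: FAANGSubmission, project: ProjectBlock,
                        opts: ConversionOptions | None = None) -> EntityGraph:
    """Split the three flat documents into typed entities (no links yet).

    Mapping: organism sample record → donor_organism biomaterial; specimen
    record → specimen_from_organism biomaterial; experiment record →
    library_preparation_protocol (carrying the full record) plus a paired
    sequencing_protocol; analysis record → sequence_file (fastq/bam) or
    analysis_file (mtx/h5ad); the project block → the project entity. One
    shared collection_protocol backs all sampling links. Every entity receives
    described_by, schema_version and a UUID.
    """
    opts = opts or ConversionOptions()
    g = EntityGraph()
    g.add_entity(_stamp(synthesize_project(project), opts))
    g.add_entity(_stamp(Entity("collection_protocol", "protocol",
                               "collection_protocol", {}), opts))

    sample_aliases = set(sub.sample.aliases)
    experiment_aliases = set(sub.experiment.aliases)

    for rec in sub.sample.records:
        material = rec.get("material", "organism")
        if material == "organism":
            subcat = "donor_organism"
        elif material == "specimen from organism":
            subcat = "specimen_from_organism"
        else:
            subcat = "cell_suspension"
        g.add_entity(_stamp(Entity(rec["alias"], "biomaterial", subcat,
                                   dict(rec)), opts))

    for rec in sub.experiment.records:
        ref = rec.get("sample_ref", "")
        if ref not in sample_aliases:
            raise ValueError(
                f"experiment {rec['alias']!r} references unknown sample "
                f"alias {ref!r}")
        g.add_entity(_stamp(Entity(rec["alias"], "protocol",
                                   "library_preparation_protocol",
                                   dict(rec)), opts))
        g.add_entity(_stamp(Entity(f"{rec['alias']}__sequencing", "protocol",
                                   "sequencing_protocol",
                                   {"alias": rec["alias"]}), opts))

    for rec in sub.analysis.records:
        ref = rec.get("experiment_ref", "")
        if ref not in experiment_aliases:
            raise ValueError(
                f"file {rec['alias']!r} references unknown experiment "
                f"alias {ref!r}")
        subcat = ("sequence_file" if rec.get("file_type") in ("fastq", "bam")
                  else "analysis_file")
        g.add_entity(_stamp(Entity(rec["alias"], "file", subcat,
                                   dict(rec)), opts))
    return g


def build_links(g: EntityGraph,
                opts: ConversionOptions | None = None) -> EntityGraph:
    """Realize the retained reference fields as process links.

    Each specimen's ``derived_from`` becomes a sampling link (donor →
    specimen under the shared collection protocol); each experiment's
    ``sample_ref`` plus the files carrying its alias in ``experiment_ref``
    become one sequencing link (specimen → files under the experiment's
    library-preparation and sequencing protocols). Files of one library share
    a single link. Reference fields stay in entity content for round-trips.
    """
    opts = opts or ConversionOptions()

    def add_process(pid: str) -> str:
        g.add_entity(_stamp(Entity(pid, "process", "process", {}), opts))
        return pid

    for specimen in g.by_subcategory("specimen_from_organism"):
        donor = specimen.content.get("derived_from", "")
        if donor not in g.entities:
            raise ValueError(
                f"specimen {specimen.entity_id!r} derived_from unresolvable "
                f"alias {donor!r}")
        pid = add_process(f"{specimen.entity_id}__sampling")
        g.links.append(Link(pid, (donor,), (specimen.entity_id,),
                            ("collection_protocol",)))

    files_by_experiment: dict[str, list[str]] = {}
    for entity in g.by_category("file"):
        ref = entity.content.get("experiment_ref", "")
        files_by_experiment.setdefault(ref, []).append(entity.entity_id)

    for lib in g.by_subcategory("library_preparation_protocol"):
        specimen = lib.content.get("sample_ref", "")
        if specimen not in g.entities:
            raise ValueError(
                f"experiment {lib.entity_id!r} sample_ref unresolvable "
                f"alias {specimen!r}")
        outputs = files_by_experiment.get(lib.entity_id, [])
        if not outputs:
            continue  # no files submitted for this library; no link to build
        pid = add_process(f"{lib.entity_id}__sequencing_run")
        g.links.append(Link(pid, (specimen,), tuple(outputs),
                            (lib.entity_id, f"{lib.entity_id}__sequencing")))
    return g


def convert(sub: FAANGSubmission, rules: Ruleset, project: ProjectBlock,
            opts: ConversionOptions | None = None) -> ConversionResult:
    """Full pipeline: validate → clean → split → link → validate graph.

    Fails fast (raises) if metadata validation fails; otherwise returns the
    graph together with both validation reports.
    """
    opts = opts or ConversionOptions()
    metadata_report = validate_submission(sub, rules)
    if metadata_report.status == "fail":
        raise ValueError(
            "conversion refused: submission failed metadata validation: "
            + "; ".join(i.message for i in metadata_report.errors))
    cleaned, _ = clean_documents(sub, rules, opts)
    g = split_into_entities(cleaned, project, opts)
    g = build_links(g, opts)
    graph_report = validate_graph(g)
    return ConversionResult(g, metadata_report, graph_report)


# ---------------------------------------------------------------------------
# Spreadsheet export

_SYSTEM_COLUMNS = ("entity_id", "uuid", "described_by", "schema_version")


def _encode_cell(value):
    if isinstance(value, str):
        return value
    return json.dumps(value)


def _decode_cell(value):
    if isinstance(value, str) and value[:1] in ("[", "{"):
        try:
            return json.loads(value)
        except json.JSONDecodeError:
            return value
    return value


def export_spreadsheet(g: EntityGraph, path: str | Path) -> Path:
    """Write the graph as an XLSX workbook, one sheet per entity subcategory.

    System fields occupy the leading columns; content follows. Subcategories
    with no entities are omitted. Non-string content values (e.g. contributor
    lists) are JSON-encoded in their cells.
    """
    report = validate_graph(g)
    if report.status == "fail":
        raise ValueError("cannot export an invalid graph: "
                         + "; ".join(i.message for i in report.errors))
    path = Path(path)
    by_subcat: dict[str, list[Entity]] = {}
    for entity in g.entities.values():
        by_subcat.setdefault(entity.subcategory, []).append(entity)
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        for subcat, entities in by_subcat.items():
            columns = list(_SYSTEM_COLUMNS)
            for entity in entities:
                for key in entity.content:
                    if key not in columns:
                        columns.append(key)
            rows = []
            for entity in entities:
                row = {"entity_id": entity.entity_id, "uuid": entity.uuid,
                       "described_by": entity.described_by,
                       "schema_version": entity.schema_version}
                row.update({k: _encode_cell(v)
                            for k, v in entity.content.items()})
                rows.append({c: row.get(c, "") for c in columns})
            frame = pd.DataFrame(rows, columns=columns)
            # sheet names are capped at 31 chars by the XLSX format
            writer_sheet = subcat[:31]
            frame.to_excel(writer, sheet_name=writer_sheet, index=False)
    return path


def read_spreadsheet(path: str | Path) -> dict[str, list[dict]]:
    """Inverse of :func:`export_spreadsheet`.

    Returns, per sheet (subcategory), a list of row dicts with system fields
    under their column names and content fields decoded back to their values.
    """
    sheets = pd.read_excel(path, sheet_name=None, dtype=str)
    out: dict[str, list[dict]] = {}
    for name, frame in sheets.items():
        rows = []
        for _, row in frame.iterrows():
            rec = {}
            for key, value in row.items():
                if pd.isna(value) or value == "":
                    continue
                rec[key] = _decode_cell(value)
            rows.append(rec)
        out[name] = rows
    return out
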