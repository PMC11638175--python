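"""HCA-style experimental entity graph: entities, links and graph validation.

The data model follows the Human Cell Atlas convention of five entity
categories — project, biomaterial, protocol, process and file — connected by
links in which a process consumes inputs (biomaterials or files) and produces
outputs under one or more protocols. Every entity carries three pieces of
system metadata: a ``described_by`` URI pointing at the schema that validates
it, the ``schema_version`` those rules belong to, and a UUID.

UUIDs are name-based (RFC 4122 version 5) by default so that converting the
same submission twice yields an identical, diffable graph; random version-4
UUIDs are available for production-like behaviour.
"""

from __future__ import annotations

import json
import re
import uuid as uuid_module
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx

from .faang import FAANGSubmission, MetadataDocument
from .report import ValidationReport

#: Fixed registry of category → allowed subcategories. A minimal set covering
#: a scRNA-seq assay path from donor to submitted files.
SUBCATEGORY_REGISTRY: dict[str, tuple[str, ...]] = {
    "project": ("project",),
    "biomaterial": ("donor_organism", "specimen_from_organism", "cell_suspension"),
    "protocol": ("collection_protocol", "dissociation_protocol",
                 "library_preparation_protocol", "sequencing_protocol"),
    "process": ("process",),
    "file": ("sequence_file", "analysis_file"),
}

#: Default base for described_by URIs; overridable via ConversionOptions.
DEFAULT_BASE_URI = "https://schemas.scbroker.dev/type"

UUID_RE = re.compile(
    r"^[0-9a-f]{8}-[0-9a-f]{4}-[0-9a-f]{4}-[0-9a-f]{4}-[0-9a-f]{12}$")

#: Subcategories whose content rows flatten back into each document.
_SAMPLE_SUBCATEGORIES = ("donor_organism", "specimen_from_organism",
                         "cell_suspension")
_FILE_SUBCATEGORIES = ("sequence_file", "analysis_file")


@dataclass(frozen=True)
class Entity:
    entity_id: str
    category: str
    subcategory: str
    content: dict = field(default_factory=dict)
    described_by: str = ""
    schema_version: str = ""
    uuid: str = ""

    def __post_init__(self) -> None:
        if not self.entity_id:
            raise ValueError("entity_id must be non-empty")
        allowed = SUBCATEGORY_REGISTRY.get(self.category)
        if allowed is None:
            raise ValueError(f"unknown entity category: {self.category!r}")
        if self.subcategory not in allowed:
            raise ValueError(
                f"subcategory {self.subcategory!r} not registered under "
                f"category {self.category!r}")


@dataclass(frozen=True)
class Link:
    """One process link: inputs are consumed, outputs produced, under protocols."""

    process_id: str
    input_ids: tuple[str, ...]
    output_ids: tuple[str, ...]
    protocol_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "input_ids", tuple(self.input_ids))
        object.__setattr__(self, "output_ids", tuple(self.output_ids))
        object.__setattr__(self, "protocol_ids", tuple(self.protocol_ids))


@dataclass
class EntityGraph:
    entities: dict[str, Entity] = field(default_factory=dict)
    links: list[Link] = field(default_factory=list)

    def add_entity(self, entity: Entity) -> Entity:
        if entity.entity_id in self.entities:
            raise ValueError(f"duplicate entity id: {entity.entity_id!r}")
        self.entities[entity.entity_id] = entity
        return entity

    def by_subcategory(self, subcategory: str) -> list[Entity]:
        return [e for e in self.entities.values() if e.subcategory == subcategory]

    def by_category(self, category: str) -> list[Entity]:
        return [e for e in self.entities.values() if e.category == category]


def assign_uuid(entity: Entity, namespace: str, random: bool = False) -> Entity:
    """Return the entity with its UUID set.

    The default scheme is deterministic: a version-5 UUID of
    ``category/entity_id`` under a namespace UUID derived from ``namespace``,
    so repeated conversions of the same submission are byte-identical.
    """
    if not entity.entity_id:
        raise ValueError("entity_id must be non-empty")
    if random:
        value = uuid_module.uuid4()
    else:
        ns = uuid_module.uuid5(uuid_module.NAMESPACE_URL, namespace)
        value = uuid_module.uuid5(ns, f"{entity.category}/{entity.entity_id}")
    return replace(entity, uuid=str(value))


def describe(entity: Entity, base_uri: str, schema_version: str) -> Entity:
    """Inject described_by and schema_version system metadata."""
    uri = f"{base_uri.rstrip('/')}/{schema_version}/{entity.subcategory}"
    return replace(entity, described_by=uri, schema_version=schema_version)


def _flow_graph(g: EntityGraph) -> nx.DiGraph:
    """Directed graph over biomaterial/file entities induced by the links."""
    flow = nx.DiGraph()
    for eid, entity in g.entities.items():
        if entity.category in ("biomaterial", "file"):
            flow.add_node(eid)
    for link in g.links:
        for src in link.input_ids:
            for dst in link.output_ids:
                flow.add_edge(src, dst)
    return flow


def validate_graph(g: EntityGraph) -> ValidationReport:
    """Structural validation of the entity graph.

    Errors: not exactly one project; malformed/duplicated UUIDs; described_by
    not ending in the subcategory; dangling link ids; empty or overlapping
    link inputs/outputs; links without protocols; cycles in the input→output
    flow; orphan files (never an output, or an output of several links);
    specimens with no donor-rooted path. A graph with no file entities passes
    with a warning.
    """
    report = ValidationReport()
    projects = g.by_category("project")
    if len(projects) != 1:
        report.add("graph", "project", "error",
                   f"graph must contain exactly one project entity, found "
                   f"{len(projects)}")

    seen_uuids: dict[str, str] = {}
    for eid, entity in g.entities.items():
        if not UUID_RE.match(entity.uuid):
            report.add(eid, "uuid", "error",
                       f"uuid missing or malformed: {entity.uuid!r}")
        elif entity.uuid in seen_uuids:
            report.add(eid, "uuid", "error",
                       f"uuid collision with entity {seen_uuids[entity.uuid]!r}")
        else:
            seen_uuids[entity.uuid] = eid
        if not entity.described_by:
            report.add(eid, "described_by", "error", "described_by is empty")
        elif not entity.described_by.endswith(entity.subcategory):
            report.add(eid, "described_by", "error",
                       f"described_by {entity.described_by!r} does not end with "
                       f"subcategory {entity.subcategory!r}")

    linkable = {"biomaterial", "file"}
    for link in g.links:
        proc = g.entities.get(link.process_id)
        if proc is None or proc.category != "process":
            report.add(link.process_id, "process_id", "error",
                       "link process id does not resolve to a process entity")
        if not link.input_ids or not link.output_ids:
            report.add(link.process_id, "inputs/outputs", "error",
                       "link inputs and outputs must be non-empty")
        if set(link.input_ids) & set(link.output_ids):
            report.add(link.process_id, "inputs/outputs", "error",
                       "link inputs and outputs must be disjoint")
        if not link.protocol_ids:
            report.add(link.process_id, "protocol_ids", "error",
                       "link has no protocols")
        for role, ids, allowed in (("input", link.input_ids, linkable),
                                   ("output", link.output_ids, linkable),
                                   ("protocol", link.protocol_ids, {"protocol"})):
            for eid in ids:
                entity = g.entities.get(eid)
                if entity is None:
                    report.add(link.process_id, role, "error",
                               f"dangling {role} id: {eid!r}")
                elif entity.category not in allowed:
                    report.add(link.process_id, role, "error",
                               f"{role} {eid!r} has category "
                               f"{entity.category!r}, expected one of "
                               f"{sorted(allowed)}")

    flow = _flow_graph(g)
    if not nx.is_directed_acyclic_graph(flow):
        cycle = nx.find_cycle(flow)
        report.add("graph", "links", "error",
                   f"cycle in input→output flow: {cycle}")
        return report  # reachability checks below assume a DAG

    files = g.by_category("file")
    if not files:
        report.add("graph", "files", "warning", "graph contains no file entities")
    for entity in files:
        n_producing = sum(entity.entity_id in link.output_ids for link in g.links)
        if n_producing == 0:
            report.add(entity.entity_id, "links", "error",
                       "orphan file: never an output of any link")
        elif n_producing > 1:
            report.add(entity.entity_id, "links", "error",
                       f"file is an output of {n_producing} links, expected 1")

    donors = {e.entity_id for e in g.by_subcategory("donor_organism")}
    for specimen in g.by_subcategory("specimen_from_organism"):
        sid = specimen.entity_id
        ancestors = nx.ancestors(flow, sid) if flow.has_node(sid) else set()
        if not ancestors & donors:
            report.add(sid, "links", "error",
                       "specimen has no donor-rooted path")
    return report


def flatten_graph(g: EntityGraph) -> FAANGSubmission:
    """Reconstruct the three flat documents from a valid entity graph.

    System metadata (uuid, described_by, schema_version) lives on the entity,
    not in its content, and is discarded. Link relations are already encoded
    in the retained reference fields (derived_from / sample_ref /
    experiment_ref), so the output round-trips against the cleaned input.
    Pure: repeated calls return equal submissions.
    """
    report = validate_graph(g)
    if report.status == "fail":
        raise ValueError(
            "cannot flatten an invalid graph: "
            + "; ".join(i.message for i in report.errors))
    sample_records, experiment_records, analysis_records = [], [], []
    for entity in g.entities.values():
        if entity.subcategory in _SAMPLE_SUBCATEGORIES:
            sample_records.append(dict(entity.content))
        elif entity.subcategory == "library_preparation_protocol":
            # carries the full experiment record (the paired sequencing
            # protocol holds only the alias)
            experiment_records.append(dict(entity.content))
        elif entity.subcategory in _FILE_SUBCATEGORIES:
            analysis_records.append(dict(entity.content))
    return FAANGSubmission(
        sample=MetadataDocument("sample", sample_records, "json"),
        experiment=MetadataDocument("experiment", experiment_records, "json"),
        analysis=MetadataDocument("analysis", analysis_records, "json"),
    )


# ---------------------------------------------------------------------------
# Serialization: one JSON document per entity plus a links document


def _entity_to_dict(entity: Entity) -> dict:
    return {
        "entity_id": entity.entity_id,
        "category": entity.category,
        "subcategory": entity.subcategory,
        "described_by": entity.described_by,
        "schema_version": entity.schema_version,
        "uuid": entity.uuid,
        "content": entity.content,
    }


def write_graph(g: EntityGraph, out_dir: str | Path) -> Path:
    """Write one JSON file per entity plus links.json into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for entity in g.entities.values():
        safe = re.sub(r"[^A-Za-z0-9_.-]", "_", entity.entity_id)
        path = out_dir / f"{entity.subcategory}__{safe}.json"
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(_entity_to_dict(entity), fh, indent=2)
            fh.write("\n")
    links = [{"process": link.process_id,
              "inputs": list(link.input_ids),
              "outputs": list(link.output_ids),
              "protocols": list(link.protocol_ids)} for link in g.links]
    with open(out_dir / "links.json", "w", encoding="utf-8") as fh:
        json.dump({"links": links}, fh, indent=2)
        fh.write("\n")
    return out_dir


def read_graph(in_dir: str | Path) -> EntityGraph:
    """Inverse of :func:`write_graph`."""
    in_dir = Path(in_dir)
    g = EntityGraph()
    entity_paths = sorted(p for p in in_dir.glob("*.json")
                          if p.name != "links.json")
    for path in entity_paths:
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        g.add_entity(Entity(
            entity_id=raw["entity_id"], category=raw["category"],
            subcategory=raw["subcategory"], content=raw["content"],
            described_by=raw["described_by"],
            schema_version=raw["schema_version"], uuid=raw["uuid"]))
    links_path = in_dir / "links.json"
    if links_path.exists():
        with open(links_path, encoding="utf-8") as fh:
            raw = json.load(fh)
        for entry in raw["links"]:
            g.links.append(Link(entry["process"], tuple(entry["inputs"]),
                                tuple(entry["outputs"]),
                                tuple(entry["protocols"])))
    return g
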