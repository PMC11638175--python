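"""FAANG-style submission model and three-part ruleset validation.

A submission consists of three flat metadata documents — sample, experiment
and analysis — each an ordered list of records keyed by a unique ``alias``.
Requirement levels follow the FAANG tier vocabulary: ``mandatory`` fields must
be present (error when absent), ``recommended`` fields warn when absent, and
``optional`` fields are free. The sample document mixes two record kinds
(donor organisms and specimens derived from them), so a field rule may be
scoped to records of one ``material``.

Ontology-term values are checked syntactically against the CURIE pattern
``PREFIX:digits`` only; no ontology service is consulted, so the validator
works fully offline.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .report import ValidationReport

TIERS = ("mandatory", "recommended", "optional")
VALUE_KINDS = ("text", "number", "ontology_term", "date", "file_ref", "entity_ref")
DOC_TYPES = ("sample", "experiment", "analysis")
SOURCES = ("spreadsheet", "json")

#: CURIE shape for ontology terms, e.g. "NCBITaxon:9823" or "UBERON:0000178".
CURIE_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*:[0-9]+$")
DATE_RE = re.compile(r"^\d{4}(-\d{2}(-\d{2})?)?$")


def normalize_field_name(name: str) -> str:
    """Lowercase snake-case normalization applied to headers and JSON keys."""
    return re.sub(r"[\s\-]+", "_", str(name).strip().lower())


@dataclass(frozen=True)
class FieldRule:
    """One field definition in a ruleset section.

    ``material`` scopes the rule to sample records whose ``material`` field
    equals it (None applies to every record). ``ref_section`` names the
    document an ``entity_ref`` value must resolve into.
    """

    name: str
    tier: str
    value_kind: str = "text"
    allowed_values: tuple[str, ...] | None = None
    ref_section: str | None = None
    material: str | None = None

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier: {self.tier!r}")
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value kind: {self.value_kind!r}")
        if self.value_kind == "entity_ref" and self.ref_section not in DOC_TYPES:
            raise ValueError(
                f"entity_ref rule {self.name!r} needs ref_section in {DOC_TYPES}"
            )

    def applies_to(self, record: dict) -> bool:
        return self.material is None or record.get("material") == self.material


@dataclass
class Ruleset:
    """Three ordered sections of field rules, one per document type."""

    version: str
    sections: dict[str, list[FieldRule]]

    def __post_init__(self) -> None:
        if not self.version:
            raise ValueError("ruleset version must be non-empty")
        for doc_type in DOC_TYPES:
            if doc_type not in self.sections:
                raise ValueError(f"missing section: {doc_type}")
        for doc_type, rules in self.sections.items():
            names = [r.name for r in rules]
            if len(names) != len(set(names)):
                raise ValueError(f"duplicate field names in section {doc_type!r}")


@dataclass
class MetadataDocument:
    """One flat document: an ordered list of records keyed by alias."""

    doc_type: str
    records: list[dict]
    source: str = "json"

    def __post_init__(self) -> None:
        if self.doc_type not in DOC_TYPES:
            raise ValueError(f"unknown document type: {self.doc_type!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source: {self.source!r}")
        seen: set[str] = set()
        for rec in self.records:
            alias = rec.get("alias", "")
            if not alias:
                raise ValueError(f"record without alias in {self.doc_type} document")
            if alias in seen:
                raise ValueError(
                    f"duplicate alias {alias!r} in {self.doc_type} document"
                )
            seen.add(alias)

    @property
    def aliases(self) -> list[str]:
        return [rec["alias"] for rec in self.records]


@dataclass
class FAANGSubmission:
    sample: MetadataDocument
    experiment: MetadataDocument
    analysis: MetadataDocument

    def document(self, doc_type: str) -> MetadataDocument:
        return {"sample": self.sample, "experiment": self.experiment,
                "analysis": self.analysis}[doc_type]

    def documents(self):
        return [self.sample, self.experiment, self.analysis]


# ---------------------------------------------------------------------------
# Default single-cell ruleset


def default_ruleset() -> Ruleset:
    """The packaged single-cell ruleset.

    Sample records are either donor organisms or specimens derived from them;
    experiments describe one sequencing library per specimen; analysis records
    describe submitted data files.
    """
    sample = [
        FieldRule("alias", "mandatory"),
        FieldRule("material", "mandatory",
                  allowed_values=("organism", "specimen from organism")),
        FieldRule("organism", "mandatory", "ontology_term", material="organism"),
        FieldRule("sex", "mandatory", allowed_values=("male", "female"),
                  material="organism"),
        FieldRule("breed", "mandatory", material="organism"),
        FieldRule("health_status", "recommended", material="organism"),
        FieldRule("birth_date", "optional", "date", material="organism"),
        FieldRule("tissue", "mandatory", "ontology_term",
                  material="specimen from organism"),
        FieldRule("derived_from", "mandatory", "entity_ref", ref_section="sample",
                  material="specimen from organism"),
        FieldRule("collection_date", "optional", "date",
                  material="specimen from organism"),
    ]
    experiment = [
        FieldRule("alias", "mandatory"),
        FieldRule("assay_type", "mandatory",
                  allowed_values=("scRNA-seq", "scATAC-seq")),
        FieldRule("library_construction", "mandatory"),
        FieldRule("sample_ref", "mandatory", "entity_ref", ref_section="sample"),
        FieldRule("sequencing_platform", "recommended"),
        FieldRule("cell_count", "optional", "number"),
    ]
    analysis = [
        FieldRule("alias", "mandatory"),
        FieldRule("file_name", "mandatory", "file_ref"),
        FieldRule("file_type", "mandatory",
                  allowed_values=("fastq", "bam", "mtx", "h5ad")),
        FieldRule("checksum", "mandatory"),
        FieldRule("experiment_ref", "mandatory", "entity_ref",
                  ref_section="experiment"),
        FieldRule("analysis_protocol", "optional"),
    ]
    return Ruleset(version="1.0",
                   sections={"sample": sample, "experiment": experiment,
                             "analysis": analysis})


def load_ruleset(path: str | Path) -> Ruleset:
    """Read a ruleset from its JSON serialization.

    Expected shape::

        {"version": "1.0",
         "sections": {"sample": [{"name": ..., "tier": ..., ...}, ...],
                      "experiment": [...], "analysis": [...]}}
    """
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    version = raw.get("version", "")
    sections_raw = raw.get("sections", {})
    for doc_type in DOC_TYPES:
        if doc_type not in sections_raw:
            raise ValueError(f"missing section: {doc_type}")
    sections: dict[str, list[FieldRule]] = {}
    for doc_type, rules_raw in sections_raw.items():
        rules = []
        for entry in rules_raw:
            rules.append(FieldRule(
                name=normalize_field_name(entry["name"]),
                tier=entry.get("tier", ""),
                value_kind=entry.get("value_kind", "text"),
                allowed_values=(tuple(entry["allowed_values"])
                                if entry.get("allowed_values") else None),
                ref_section=entry.get("ref_section"),
                material=entry.get("material"),
            ))
        sections[doc_type] = rules
    return Ruleset(version=version, sections=sections)


def save_ruleset(rules: Ruleset, path: str | Path) -> None:
    sections = {}
    for doc_type, rule_list in rules.sections.items():
        sections[doc_type] = [
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in {
                 "name": r.name, "tier": r.tier, "value_kind": r.value_kind,
                 "allowed_values": r.allowed_values,
                 "ref_section": r.ref_section, "material": r.material,
             }.items() if v is not None}
            for r in rule_list
        ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"version": rules.version, "sections": sections}, fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Reading and writing the three documents


def _records_from_frame(frame: pd.DataFrame) -> list[dict]:
    frame = frame.rename(columns=normalize_field_name)
    records = []
    for _, row in frame.iterrows():
        rec = {}
        for key, value in row.items():
            if pd.isna(value):
                continue
            rec[key] = str(value)
        records.append(rec)
    return records


def read_document(path: str | Path, doc_type: str) -> MetadataDocument:
    """Read one document from TSV, XLSX (first sheet) or JSON.

    Field names are normalized to lowercase snake case; cell values are kept
    verbatim (as strings).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tsv", ".txt"):
        frame = pd.read_csv(path, sep="\t", dtype=str)
        return MetadataDocument(doc_type, _records_from_frame(frame), "spreadsheet")
    if suffix == ".xlsx":
        frame = pd.read_excel(path, sheet_name=0, dtype=str)
        return MetadataDocument(doc_type, _records_from_frame(frame), "spreadsheet")
    if suffix == ".json":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        if not isinstance(raw, list):
            raise ValueError(f"{path}: expected a JSON list of records")
        records = [{normalize_field_name(k): str(v) for k, v in rec.items()}
                   for rec in raw]
        return MetadataDocument(doc_type, records, "json")
    raise ValueError(f"unsupported document format: {path}")


def write_document(doc: MetadataDocument, path: str | Path) -> None:
    """Write a document as TSV, XLSX or JSON (chosen by extension)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc.records, fh, indent=2)
            fh.write("\n")
        return
    columns: list[str] = []
    for rec in doc.records:
        for key in rec:
            if key not in columns:
                columns.append(key)
    frame = pd.DataFrame(
        [{c: rec.get(c, "") for c in columns} for rec in doc.records],
        columns=columns, dtype=str)
    if suffix in (".tsv", ".txt"):
        frame.to_csv(path, sep="\t", index=False)
    elif suffix == ".xlsx":
        frame.to_excel(path, index=False)
    else:
        raise ValueError(f"unsupported document format: {path}")


def read_submission(sample_path: str | Path, experiment_path: str | Path,
                    analysis_path: str | Path) -> FAANGSubmission:
    return FAANGSubmission(
        sample=read_document(sample_path, "sample"),
        experiment=read_document(experiment_path, "experiment"),
        analysis=read_document(analysis_path, "analysis"),
    )


def write_submission(sub: FAANGSubmission, out_dir: str | Path,
                     fmt: str = "tsv") -> dict[str, Path]:
    """Write all three documents into ``out_dir``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for doc in sub.documents():
        path = out_dir / f"{doc.doc_type}.{fmt}"
        write_document(doc, path)
        paths[doc.doc_type] = path
    return paths


# ---------------------------------------------------------------------------
# Validation


def _check_value(rule: FieldRule, value: str, aliases: dict[str, set[str]],
                 report: ValidationReport, alias: str) -> None:
    if rule.allowed_values is not None and value not in rule.allowed_values:
        report.add(alias, rule.name, "error",
                   f"value {value!r} not in allowed values "
                   f"{sorted(rule.allowed_values)}")
        return
    if rule.value_kind == "ontology_term" and not CURIE_RE.match(value):
        report.add(alias, rule.name, "error",
                   f"value {value!r} is not a CURIE (expected PREFIX:digits)")
    elif rule.value_kind == "number":
        try:
            float(value)
        except ValueError:
            report.add(alias, rule.name, "error",
                       f"value {value!r} is not numeric")
    elif rule.value_kind == "date" and not DATE_RE.match(value):
        report.add(alias, rule.name, "error",
                   f"value {value!r} is not an ISO date")
    elif rule.value_kind == "entity_ref":
        if value not in aliases[rule.ref_section]:
            report.add(alias, rule.name, "error",
                       f"unresolved reference: {value!r} is not an alias in the "
                       f"{rule.ref_section} document")


def validate_submission(sub: FAANGSubmission, rules: Ruleset) -> ValidationReport:
    """Validate all three documents against the ruleset.

    Missing mandatory fields are errors; missing recommended fields are
    warnings; values outside a rule's closed vocabulary, malformed ontology
    terms/numbers/dates, and unresolved entity references are errors.
    Problems are reported, never raised.
    """
    report = ValidationReport()
    aliases = {doc.doc_type: {a for a in
                              (rec.get("alias") for rec in doc.records) if a}
               for doc in sub.documents()}
    for doc in sub.documents():
        for i, rec in enumerate(doc.records):
            label = rec.get("alias") or f"{doc.doc_type}[{i}]"
            for rule in rules.sections[doc.doc_type]:
                if not rule.applies_to(rec):
                    continue
                value = rec.get(rule.name)
                if value is None or value == "":
                    if rule.tier == "mandatory":
                        report.add(label, rule.name, "error",
                                   f"missing mandatory field: {rule.name}")
                    elif rule.tier == "recommended":
                        report.add(label, rule.name, "warning",
                                   f"missing recommended field: {rule.name}")
                    continue
                _check_value(rule, value, aliases, report, label)
    return report
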