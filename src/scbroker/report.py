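"""Validation reports shared by the metadata validator and the graph validator.

A report never raises: problems are collected as issues, each tied to the
record (or entity) and field it concerns. The overall status is ``fail``
exactly when at least one issue has severity ``error``; warnings alone never
fail a submission.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

SEVERITIES = ("error", "warning")


@dataclass(frozen=True)
class Issue:
    """One validation finding, attached to a record/entity and a field."""

    record: str
    field: str
    severity: str
    message: str

    def __post_init__(self) -> None:
        if self.severity not in SEVERITIES:
            raise ValueError(f"unknown severity: {self.severity!r}")


@dataclass
class ValidationReport:
    issues: list[Issue] = field(default_factory=list)

    @property
    def status(self) -> str:
        return "fail" if any(i.severity == "error" for i in self.issues) else "pass"

    @property
    def errors(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "warning"]

    def add(self, record: str, field_name: str, severity: str, message: str) -> None:
        self.issues.append(Issue(record, field_name, severity, message))

    def extend(self, other: "ValidationReport") -> None:
        self.issues.extend(other.issues)

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "issues": [
                {
                    "record_alias": i.record,
                    "field": i.field,
                    "severity": i.severity,
                    "message": i.message,
                }
                for i in self.issues
            ],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)
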