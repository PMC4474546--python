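"""Rule-based, version-aware validation of RDML documents.

The three version dialects are encoded as explicit rules over the in-memory
model rather than delegated to an XML schema engine, so the same checks
apply whether a document came from a file or was built programmatically.
An optional hook accepts an external XSD for cross-checking when one is
available locally.

Severity policy: breaches of structure or referential integrity (duplicate
identifiers, dangling references, positions off the plate, non-monotone
curves, elements outside their version) are errors; vocabulary deviations
and missing recommended metadata are warnings — such files are valid but
hard to use downstream.

Issue codes are stable strings:

=======================  =========  =============================================
code                     severity   meaning
=======================  =========  =============================================
duplicate-id             error      identifier repeated within a top-level list
empty-id                 error      identifier empty
dangling-reference       error      sampleRef/targetRef/dyeRef does not resolve
dye-unregistered         error      target used in reaction data lacks a
                                    registered dye (versions >= 1.1)
position-out-of-bounds   error      reaction position outside the plate format
position-duplicate       error      two reactions share one position
missing-data             error      reaction carries no data entry
non-monotone-cycles      error      amplification cycles not strictly increasing
non-monotone-melt        error      melt temperatures not strictly increasing
element-wrong-version    error      annotation / efficiency-SE / legacy quality
                                    present in a version that lacks the element
negative-quantity        error      sample quantity below zero
unknown-token            warning    sample/target type outside the vocabulary
missing-recommended      warning    recommended metadata absent (e.g. email)
=======================  =========  =============================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import (
    RdmlDocument,
    Run,
    SAMPLE_TYPE_NAMES,
    TARGET_TYPE_NAMES,
)

SEVERITY_ERROR = "error"
SEVERITY_WARNING = "warning"


@dataclass
class ValidationIssue:
    severity: str
    path: str
    code: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not any(i.severity == SEVERITY_ERROR for i in self.issues)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == SEVERITY_ERROR]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == SEVERITY_WARNING]

    def to_dict(self) -> dict:
        return {
            "valid": self.valid,
            "issues": [
                {
                    "severity": i.severity,
                    "code": i.code,
                    "path": i.path,
                    "message": i.message,
                }
                for i in self.issues
            ],
        }


def format_report(report: ValidationReport) -> str:
    """Render a report; a clean report is exactly "validation successful"."""
    if not report.issues:
        return "validation successful"
    return "\n".join(
        f"{i.severity}: {i.code} at {i.path}: {i.message}" for i in report.issues
    )


def _check_unique_ids(issues, elements, list_name):
    seen: set[str] = set()
    for el in elements:
        path = f"{list_name}[{el.id}]"
        if not el.id:
            issues.append(ValidationIssue(
                SEVERITY_ERROR, path, "empty-id",
                f"{list_name} element with empty identifier"))
            continue
        if el.id in seen:
            issues.append(ValidationIssue(
                SEVERITY_ERROR, path, "duplicate-id",
                f"identifier {el.id!r} occurs more than once in {list_name}"))
        seen.add(el.id)


def _strictly_increasing(xs) -> bool:
    return all(b > a for a, b in zip(xs, xs[1:]))


def _run_format(run: Run):
    return run.pcrFormat


def validate(doc: RdmlDocument, schema_path: str | None = None) -> ValidationReport:
    """Validate *doc* against the rules of its declared version.

    Problems are reported, never raised; report order is document order.
    *schema_path* optionally points to an XSD used for an additional
    cross-check of the serialized form (requires the document to be
    serializable).
    """
    issues: list[ValidationIssue] = []
    v12 = doc.version == "1.2"

    for list_name, elements in (
        ("experimenter", doc.experimenters),
        ("documentation", doc.documentations),
        ("dye", doc.dyes),
        ("sample", doc.samples),
        ("target", doc.targets),
        ("thermalCyclingConditions", doc.thermalCyclingConditions),
        ("experiment", doc.experiments),
    ):
        _check_unique_ids(issues, elements, list_name)

    sample_ids = {s.id for s in doc.samples}
    target_ids = {t.id for t in doc.targets}
    dye_ids = {d.id for d in doc.dyes}
    targets_by_id = {t.id: t for t in doc.targets}

    for exp in doc.experimenters:
        if not exp.email:
            issues.append(ValidationIssue(
                SEVERITY_WARNING, f"experimenter[{exp.id}]",
                "missing-recommended", "experimenter has no email address"))

    for s in doc.samples:
        path = f"sample[{s.id}]"
        if s.sampleType not in SAMPLE_TYPE_NAMES:
            issues.append(ValidationIssue(
                SEVERITY_WARNING, f"{path}/type", "unknown-token",
                f"sample type {s.sampleType!r} outside the known vocabulary"))
        if s.annotations and not v12:
            issues.append(ValidationIssue(
                SEVERITY_ERROR, f"{path}/annotation", "element-wrong-version",
                "sample annotations require version 1.2"))
        if s.legacyQuality is not None and v12:
            issues.append(ValidationIssue(
                SEVERITY_ERROR, f"{path}/templateQuality",
                "element-wrong-version",
                "legacy quality records were replaced by annotations in 1.2"))
        if s.quantity is not None and s.quantity.value < 0:
            issues.append(ValidationIssue(
                SEVERITY_ERROR, f"{path}/quantity", "negative-quantity",
                f"quantity value {s.quantity.value} is negative"))

    for t in doc.targets:
        path = f"target[{t.id}]"
        if t.targetType not in TARGET_TYPE_NAMES:
            issues.append(ValidationIssue(
                SEVERITY_WARNING, f"{path}/type", "unknown-token",
                f"target type {t.targetType!r} outside the known vocabulary"))
        if t.dyeRef is not None and t.dyeRef not in dye_ids:
            issues.append(ValidationIssue(
                SEVERITY_ERROR, f"{path}/dyeId", "dangling-reference",
                f"dye {t.dyeRef!r} is not registered at top level"))
        if t.amplificationEfficiencySE is not None:
            if t.amplificationEfficiency is None:
                issues.append(ValidationIssue(
                    SEVERITY_ERROR, f"{path}/amplificationEfficiencySE",
                    "dangling-reference",
                    "efficiency SE given without an efficiency value"))
            if not v12:
                issues.append(ValidationIssue(
                    SEVERITY_ERROR, f"{path}/amplificationEfficiencySE",
                    "element-wrong-version",
                    "amplificationEfficiencySE requires version 1.2"))

    for prog in doc.thermalCyclingConditions:
        for i, step in enumerate(prog.steps, start=1):
            if step.duration <= 0:
                issues.append(ValidationIssue(
                    SEVERITY_ERROR,
                    f"thermalCyclingConditions[{prog.id}]/step[{i}]",
                    "invalid-value", f"step duration {step.duration} not > 0"))

    dye_checked: set[str] = set()
    for exp in doc.experiments:
        run_ids: set[str] = set()
        for run in exp.runs:
            rpath = f"experiment[{exp.id}]/run[{run.id}]"
            if run.id in run_ids:
                issues.append(ValidationIssue(
                    SEVERITY_ERROR, rpath, "duplicate-id",
                    f"run id {run.id!r} occurs more than once in the experiment"))
            run_ids.add(run.id)
            fmt = _run_format(run)
            positions: set[int] = set()
            for react in run.reactions:
                path = f"{rpath}/react[{react.position}]"
                if fmt is not None and not (1 <= react.position <= fmt.size):
                    issues.append(ValidationIssue(
                        SEVERITY_ERROR, path, "position-out-of-bounds",
                        f"position {react.position} outside 1..{fmt.size} "
                        f"({fmt.rows}x{fmt.columns} plate)"))
                if react.position in positions:
                    issues.append(ValidationIssue(
                        SEVERITY_ERROR, path, "position-duplicate",
                        f"position {react.position} used by more than one "
                        "reaction"))
                positions.add(react.position)
                if not react.sampleRef or react.sampleRef not in sample_ids:
                    issues.append(ValidationIssue(
                        SEVERITY_ERROR, f"{path}/sample", "dangling-reference",
                        f"sample {react.sampleRef!r} not defined in the "
                        "document"))
                if not react.data:
                    issues.append(ValidationIssue(
                        SEVERITY_ERROR, path, "missing-data",
                        "reaction carries no data entry"))
                for d in react.data:
                    dpath = f"{path}/data[{d.targetRef}]"
                    if d.targetRef not in target_ids:
                        issues.append(ValidationIssue(
                            SEVERITY_ERROR, f"{dpath}/tar",
                            "dangling-reference",
                            f"target {d.targetRef!r} not defined in the "
                            "document"))
                    elif doc.version >= "1.1" and d.targetRef not in dye_checked:
                        # from 1.1 on, every dye must be registered at top level
                        dye_checked.add(d.targetRef)
                        tgt = targets_by_id[d.targetRef]
                        if tgt.dyeRef is None or tgt.dyeRef not in dye_ids:
                            issues.append(ValidationIssue(
                                SEVERITY_ERROR, f"target[{tgt.id}]/dyeId",
                                "dye-unregistered",
                                f"target {tgt.id!r} is used in reaction data "
                                "but has no registered dye"))
                    if not _strictly_increasing(
                            [p[0] for p in d.amplificationPoints]):
                        issues.append(ValidationIssue(
                            SEVERITY_ERROR, f"{dpath}/adp",
                            "non-monotone-cycles",
                            "amplification cycles are not strictly increasing"))
                    if not _strictly_increasing(
                            [p[0] for p in d.meltingPoints]):
                        issues.append(ValidationIssue(
                            SEVERITY_ERROR, f"{dpath}/mdp",
                            "non-monotone-melt",
                            "melt temperatures are not strictly increasing"))

    report = ValidationReport(issues=issues)
    if schema_path is not None:
        report.issues.extend(_schema_cross_check(doc, schema_path))
    return report


def _schema_cross_check(doc: RdmlDocument, schema_path: str):
    """Optional cross-validation of the serialized form against an XSD."""
    from lxml import etree

    from .io import document_to_xml_bytes

    schema = etree.XMLSchema(etree.parse(schema_path))
    tree = etree.fromstring(document_to_xml_bytes(doc))
    out = []
    if not schema.validate(tree):
        for err in schema.error_log:
            out.append(ValidationIssue(
                SEVERITY_ERROR, f"line {err.line}", "schema-violation",
                err.message))
    return out
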