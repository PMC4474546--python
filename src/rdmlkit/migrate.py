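"""Version migration and plate-coordinate conversion.

Converts documents between RDML 1.0, 1.1 and 1.2 in either direction.  Each
call produces a new document plus a :class:`MigrationReport` listing every
transformation, every synthesized element and every element that had to be
dropped because the target version cannot represent it.  Multi-step requests
(1.0 <-> 1.2) chain adjacent-version migrations and concatenate the reports.

Well coordinates: version 1.0 identified reactions by well label (letter row
plus number column, "B7"); from 1.1 onward a reaction carries a 1-based
numeric position in the run's two-dimensional plate format.  This module
uses row-major numbering — position = (row-1)*columns + column — which
follows the conventional A1, A2, ... reading order of a plate.  Row letters
run A..Z, then AA, AB, ... for plates deeper than 26 rows.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .model import (
    Dye,
    Annotation,
    InvalidPositionError,
    InvalidWellError,
    LegacyQuality,
    PcrFormat,
    RdmlDocument,
    SUPPORTED_VERSIONS,
    UnknownPlateTypeError,
    UnsupportedVersionError,
)

#: geometry of the predefined version-1.0 plate types
PLATE_TYPE_MAP: dict[str, PcrFormat] = {
    "96-well": PcrFormat(rows=8, columns=12),
    "384-well": PcrFormat(rows=16, columns=24),
    "48-well": PcrFormat(rows=6, columns=8),
    "rotor-72": PcrFormat(rows=72, columns=1),
    "rotor-100": PcrFormat(rows=100, columns=1),
}

_LABEL_RE = re.compile(r"^([A-Za-z]+)(\d+)$")


def _row_letters_to_index(letters: str) -> int:
    """'A' -> 1, 'Z' -> 26, 'AA' -> 27 (bijective base-26)."""
    idx = 0
    for ch in letters.upper():
        idx = idx * 26 + (ord(ch) - ord("A") + 1)
    return idx


def _row_index_to_letters(row: int) -> str:
    letters = ""
    while row > 0:
        row, rem = divmod(row - 1, 26)
        letters = chr(ord("A") + rem) + letters
    return letters


def well_label_to_position(label: str, fmt: PcrFormat) -> int:
    """Convert a well label ("B7") to the 1-based row-major linear position."""
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise InvalidWellError(f"cannot parse well label {label!r}")
    row = _row_letters_to_index(m.group(1))
    column = int(m.group(2))
    if not (1 <= row <= fmt.rows and 1 <= column <= fmt.columns):
        raise InvalidWellError(
            f"well {label!r} outside {fmt.rows}x{fmt.columns} plate"
        )
    return (row - 1) * fmt.columns + column


def position_to_well_label(position: int, fmt: PcrFormat) -> str:
    """Inverse of :func:`well_label_to_position`."""
    if not (1 <= position <= fmt.size):
        raise InvalidPositionError(
            f"position {position} outside 1..{fmt.size} "
            f"({fmt.rows}x{fmt.columns} plate)"
        )
    row, column = divmod(position - 1, fmt.columns)
    return f"{_row_index_to_letters(row + 1)}{column + 1}"


def plate_type_to_format(
    token: str, custom_map: Optional[Mapping[str, PcrFormat]] = None
) -> PcrFormat:
    """Resolve a version-1.0 plate-type token to its two-dimensional format.

    *custom_map* entries take precedence over the shipped map; an unknown
    token raises :class:`UnknownPlateTypeError` rather than guessing a
    geometry, since a silently wrong geometry corrupts every position.
    """
    if custom_map and token in custom_map:
        fmt = custom_map[token]
        return PcrFormat(rows=fmt.rows, columns=fmt.columns)
    if token in PLATE_TYPE_MAP:
        fmt = PLATE_TYPE_MAP[token]
        return PcrFormat(rows=fmt.rows, columns=fmt.columns)
    raise UnknownPlateTypeError(token)


def format_to_plate_type(
    fmt: PcrFormat, custom_map: Optional[Mapping[str, PcrFormat]] = None
) -> str:
    """Reverse lookup of the plate-type token matching a format's geometry."""
    maps: list[Mapping[str, PcrFormat]] = [PLATE_TYPE_MAP]
    if custom_map:
        maps.insert(0, custom_map)
    for m in maps:
        for token, candidate in m.items():
            if candidate.rows == fmt.rows and candidate.columns == fmt.columns:
                return token
    raise UnknownPlateTypeError(
        f"{fmt.rows}x{fmt.columns}",
        f"no plate-type token matches a {fmt.rows}x{fmt.columns} format",
    )


# ---------------------------------------------------------------------------
# migration report

@dataclass
class MigrationAction:
    kind: str  # "transformed" | "synthesized" | "dropped"
    path: str
    detail: str


@dataclass
class MigrationReport:
    sourceVersion: str
    targetVersion: str
    #: adjacent version pairs actually applied, e.g. [("1.0","1.1"), ("1.1","1.2")]
    steps: list[tuple[str, str]] = field(default_factory=list)
    actions: list[MigrationAction] = field(default_factory=list)

    def dropped(self) -> list[MigrationAction]:
        return [a for a in self.actions if a.kind == "dropped"]

    def to_dict(self) -> dict:
        return {
            "sourceVersion": self.sourceVersion,
            "targetVersion": self.targetVersion,
            "steps": [list(s) for s in self.steps],
            "actions": [
                {"kind": a.kind, "path": a.path, "detail": a.detail}
                for a in self.actions
            ],
        }


_QUALITY_ANNOTATION_RE = re.compile(r"^(dna|rna) quality$")


def _sample_path(sample_id: str) -> str:
    return f"sample[{sample_id}]"


# ---------------------------------------------------------------------------
# adjacent-version steps (each mutates the working copy in place)

def _upgrade_10_to_11(doc: RdmlDocument, report: MigrationReport,
                      plate_map: Optional[Mapping[str, PcrFormat]]) -> None:
    for exp in doc.experiments:
        for run in exp.runs:
            path = f"experiment[{exp.id}]/run[{run.id}]"
            if run.plateType is not None:
                fmt = plate_type_to_format(run.plateType, plate_map)
                run.pcrFormat = fmt
                report.actions.append(MigrationAction(
                    "transformed", f"{path}/plateType",
                    f"plate type {run.plateType!r} expanded to "
                    f"{fmt.rows}x{fmt.columns} pcrFormat",
                ))
                run.plateType = None
            if run.reactions:
                report.actions.append(MigrationAction(
                    "transformed", f"{path}/react",
                    "reaction identifiers now serialized as numeric "
                    "positions instead of well labels",
                ))
    # dye registration becomes mandatory: synthesize what is missing
    registered = {d.id for d in doc.dyes}
    for target in doc.targets:
        if target.dyeRef is None:
            dye_id = f"dye_{target.id}"
            n = 1
            while dye_id in registered:
                n += 1
                dye_id = f"dye_{target.id}_{n}"
            doc.dyes.append(Dye(id=dye_id, description="synthesized during migration"))
            registered.add(dye_id)
            target.dyeRef = dye_id
            report.actions.append(MigrationAction(
                "synthesized", f"target[{target.id}]/dyeId",
                f"dye {dye_id!r} created; dyes are mandatory from version 1.1",
            ))
        elif target.dyeRef not in registered:
            doc.dyes.append(Dye(id=target.dyeRef))
            registered.add(target.dyeRef)
            report.actions.append(MigrationAction(
                "synthesized", f"dye[{target.dyeRef}]",
                "top-level registration added for a referenced dye",
            ))


def _downgrade_11_to_10(doc: RdmlDocument, report: MigrationReport,
                        plate_map: Optional[Mapping[str, PcrFormat]]) -> None:
    for exp in doc.experiments:
        for run in exp.runs:
            path = f"experiment[{exp.id}]/run[{run.id}]"
            if run.pcrFormat is not None and run.plateType is None:
                token = format_to_plate_type(run.pcrFormat, plate_map)
                run.plateType = token
                report.actions.append(MigrationAction(
                    "transformed", f"{path}/pcrFormat",
                    f"{run.pcrFormat.rows}x{run.pcrFormat.columns} format "
                    f"mapped to predefined plate type {token!r}",
                ))
            if run.reactions:
                report.actions.append(MigrationAction(
                    "transformed", f"{path}/react",
                    "reaction identifiers now serialized as well labels",
                ))


def _upgrade_11_to_12(doc: RdmlDocument, report: MigrationReport) -> None:
    for sample in doc.samples:
        path = _sample_path(sample.id)
        if sample.quantity is not None:
            report.actions.append(MigrationAction(
                "transformed", f"{path}/quantity",
                "material-specific quantity re-housed as unified quantity",
            ))
        if sample.legacyQuality is not None:
            q = sample.legacyQuality
            value = q.method if q.result is None else f"{q.method}: {q.result}"
            sample.annotations.append(
                Annotation(property=f"{q.material} quality", value=value)
            )
            sample.legacyQuality = None
            report.actions.append(MigrationAction(
                "transformed", f"{path}/templateQuality",
                f"{q.material.upper()} quality record converted to an "
                f"annotation with property {q.material + ' quality'!r}",
            ))


def _downgrade_12_to_11(doc: RdmlDocument, report: MigrationReport) -> None:
    for sample in doc.samples:
        path = _sample_path(sample.id)
        for ann in sample.annotations:
            m = _QUALITY_ANNOTATION_RE.match(ann.property)
            if m and sample.legacyQuality is None:
                method, _, result_str = ann.value.partition(": ")
                try:
                    result = float(result_str) if result_str else None
                except ValueError:
                    method, result = ann.value, None
                sample.legacyQuality = LegacyQuality(
                    material=m.group(1), method=method, result=result
                )
                report.actions.append(MigrationAction(
                    "transformed", f"{path}/annotation[{ann.property}]",
                    "quality annotation converted back to a legacy "
                    f"{m.group(1).upper()} quality record",
                ))
            else:
                report.actions.append(MigrationAction(
                    "dropped", f"{path}/annotation[{ann.property}]",
                    f"annotation {ann.property!r}={ann.value!r} not "
                    "representable before version 1.2",
                ))
        sample.annotations = []
        if sample.quantity is not None:
            if sample.material is None:
                sample.material = "dna"
                report.actions.append(MigrationAction(
                    "transformed", f"{path}/quantity",
                    "template material unknown; quantity housed in the DNA "
                    "slot (ambiguous)",
                ))
            else:
                report.actions.append(MigrationAction(
                    "transformed", f"{path}/quantity",
                    f"unified quantity re-housed as {sample.material.upper()} "
                    "quantity",
                ))
    for target in doc.targets:
        if target.amplificationEfficiencySE is not None:
            report.actions.append(MigrationAction(
                "dropped", f"target[{target.id}]/amplificationEfficiencySE",
                f"efficiency SE {target.amplificationEfficiencySE} not "
                "representable before version 1.2",
            ))
            target.amplificationEfficiencySE = None


def migrate(
    doc: RdmlDocument,
    target_version: str,
    plate_map: Optional[Mapping[str, PcrFormat]] = None,
) -> tuple[RdmlDocument, MigrationReport]:
    """Migrate *doc* to *target_version*; the source document is unchanged.

    Returns the new document and a report whose ``actions`` list one entry
    per transformed, synthesized or dropped element and whose ``steps``
    record the adjacent-version hops actually applied.
    """
    if target_version not in SUPPORTED_VERSIONS:
        raise UnsupportedVersionError(
            f"unsupported target version {target_version!r}")
    if doc.version not in SUPPORTED_VERSIONS:
        raise UnsupportedVersionError(f"unsupported source version {doc.version!r}")

    report = MigrationReport(sourceVersion=doc.version, targetVersion=target_version)
    out = copy.deepcopy(doc)
    src = SUPPORTED_VERSIONS.index(doc.version)
    dst = SUPPORTED_VERSIONS.index(target_version)
    step = 1 if dst >= src else -1
    for i in range(src, dst, step):
        frm, to = SUPPORTED_VERSIONS[i], SUPPORTED_VERSIONS[i + step]
        if (frm, to) == ("1.0", "1.1"):
            _upgrade_10_to_11(out, report, plate_map)
        elif (frm, to) == ("1.1", "1.2"):
            _upgrade_11_to_12(out, report)
        elif (frm, to) == ("1.2", "1.1"):
            _downgrade_12_to_11(out, report)
        elif (frm, to) == ("1.1", "1.0"):
            _downgrade_11_to_10(out, report, plate_map)
        out.version = to
        report.steps.append((frm, to))
    return out, report
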