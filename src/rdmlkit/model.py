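"""In-memory model of an RDML document.

RDML (Real-time PCR Data Markup Language) is the instrument-independent
interchange format for quantitative PCR experiments: a zip-compressed XML
document holding experimenters, documentations, dyes, samples, targets,
thermal cycling conditions and experiments at the top level.  Experiments
contain runs; runs contain reactions; each reaction refers to a sample and,
per data entry, to a target, and carries the raw fluorescence readings
(amplification and melt curves), the baseline, the quantification threshold
and the observed Cq value.

Three format versions exist.  Version 1.1 replaced the predefined plate
types of 1.0 with an explicit two-dimensional plate format and numeric
reaction positions, and made dye registration mandatory.  Version 1.2 added
free-form sample annotations (property/value pairs), unified the DNA/RNA
quantity elements into a single quantity, and introduced the
``amplificationEfficiencySE`` uncertainty on targets.

The classes below are plain dataclasses: construction never validates
cross-references (that is the validator's job), so partially built or
deliberately broken documents can be represented.  Reaction positions are
always held as 1-based row-major linear indices in memory; the
well-label housing of version 1.0 files is an I/O concern.

Amplification efficiency is stored as fold-change per cycle throughout
(perfect doubling = 2.0, derived from a standard curve as E = 10^(-1/slope)).
Values are never rescaled on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, is_dataclass
from typing import Optional

SUPPORTED_VERSIONS: tuple[str, ...] = ("1.0", "1.1", "1.2")

#: serialization tokens <-> in-memory sample type names
SAMPLE_TYPE_TOKENS: dict[str, str] = {
    "unkn": "unknown",
    "std": "standard",
    "ntc": "no-template-control",
    "nac": "no-amplification-control",
    "pos": "positive-control",
}
SAMPLE_TYPE_NAMES: dict[str, str] = {v: k for k, v in SAMPLE_TYPE_TOKENS.items()}

TARGET_TYPE_TOKENS: dict[str, str] = {"toi": "target-of-interest", "ref": "reference"}
TARGET_TYPE_NAMES: dict[str, str] = {v: k for k, v in TARGET_TYPE_TOKENS.items()}


# ---------------------------------------------------------------------------
# errors

class RdmlError(Exception):
    """Base class for all errors raised by rdmlkit."""


class UnsupportedVersionError(RdmlError):
    """A version designation outside {1.0, 1.1, 1.2}."""


class MalformedFileError(RdmlError):
    """The input is not a readable RDML container/XML document."""


class RefusedWriteError(RdmlError):
    """Writing was refused because the document fails validation."""


class InvalidWellError(RdmlError):
    """A well label does not parse or lies outside the plate format."""


class InvalidPositionError(RdmlError):
    """A linear reaction position lies outside the plate format."""


class UnknownPlateTypeError(RdmlError):
    """A version-1.0 plate-type token has no known geometry."""

    def __init__(self, token: str, message: Optional[str] = None):
        self.token = token
        super().__init__(message or f"unknown plate type: {token!r}")


class InsufficientDataError(RdmlError):
    """Too few (or degenerate) observations for the requested fit."""


class UnitMismatchError(RdmlError):
    """Standard samples carry quantities in different units."""


class ElementWrongVersionError(RdmlError):
    """An element is not representable in the document's version."""


class IncompatibleSeriesError(RdmlError):
    """Curve series of mixed kinds passed where one kind is required."""


class InvalidSpecError(RdmlError):
    """A synthetic-run specification violates its invariants."""


class UnknownIdError(RdmlError):
    """A requested identifier does not exist in the document."""


# ---------------------------------------------------------------------------
# element dataclasses

@dataclass
class Experimenter:
    id: str
    firstName: Optional[str] = None
    lastName: Optional[str] = None
    email: Optional[str] = None
    extra: list[str] = field(default_factory=list)


@dataclass
class Documentation:
    id: str
    text: str = ""
    extra: list[str] = field(default_factory=list)


@dataclass
class Dye:
    id: str
    description: Optional[str] = None
    extra: list[str] = field(default_factory=list)


@dataclass
class Annotation:
    """Free-form sample tag (version 1.2): a property name and a value."""

    property: str
    value: str


@dataclass
class Quantity:
    """Amount of template put into a reaction, e.g. 5000 copies or 2.5 ng."""

    value: float
    unit: str


@dataclass
class LegacyQuality:
    """Pre-1.2 DNA/RNA quality record, retained verbatim for migration.

    Version 1.2 represents template quality as an annotation instead.
    """

    material: str  # "dna" | "rna"
    method: str
    result: Optional[float] = None


@dataclass
class Sample:
    id: str
    description: Optional[str] = None
    sampleType: str = "unknown"
    annotations: list[Annotation] = field(default_factory=list)
    quantity: Optional[Quantity] = None
    #: template material ("dna" | "rna"); selects the legacy quantity slot
    #: when serializing to versions before 1.2
    material: Optional[str] = None
    legacyQuality: Optional[LegacyQuality] = None
    extra: list[str] = field(default_factory=list)


@dataclass
class TargetSequences:
    forwardPrimer: Optional[str] = None
    reversePrimer: Optional[str] = None
    probe: Optional[str] = None
    amplicon: Optional[str] = None


@dataclass
class Target:
    id: str
    description: Optional[str] = None
    targetType: str = "target-of-interest"
    dyeRef: Optional[str] = None
    sequences: TargetSequences = field(default_factory=TargetSequences)
    #: fold-change per cycle (1 < E <= ~2); E = 10^(-1/slope) convention
    amplificationEfficiency: Optional[float] = None
    #: standard error of the efficiency, same scale; version 1.2 only
    amplificationEfficiencySE: Optional[float] = None
    extra: list[str] = field(default_factory=list)


@dataclass
class CyclingStep:
    temperature: float  # degrees C
    duration: float  # seconds
    acquire: bool = False


@dataclass
class CyclingProgram:
    id: str
    description: Optional[str] = None
    steps: list[CyclingStep] = field(default_factory=list)
    extra: list[str] = field(default_factory=list)


@dataclass
class PcrFormat:
    """Two-dimensional reaction grid; replaces 1.0's predefined plate types."""

    rows: int
    columns: int
    rowLabelScheme: str = "letters"
    columnLabelScheme: str = "numbers"

    @property
    def size(self) -> int:
        return self.rows * self.columns


@dataclass
class ReactionData:
    targetRef: str
    cq: Optional[float] = None  # cycles
    baseline: Optional[float] = None  # fluorescence units
    quantificationThreshold: Optional[float] = None  # fluorescence units
    #: ordered (cycle, fluorescence); cycles strictly increasing
    amplificationPoints: list[tuple[float, float]] = field(default_factory=list)
    #: ordered (temperature degC, fluorescence); temperatures strictly increasing
    meltingPoints: list[tuple[float, float]] = field(default_factory=list)
    extra: list[str] = field(default_factory=list)


@dataclass
class Reaction:
    #: 1-based row-major linear position on the plate
    position: int
    sampleRef: str = ""
    data: list[ReactionData] = field(default_factory=list)
    extra: list[str] = field(default_factory=list)


@dataclass
class Run:
    id: str
    description: Optional[str] = None
    pcrFormat: Optional[PcrFormat] = None
    #: version-1.0 predefined plate-type token (e.g. "96-well")
    plateType: Optional[str] = None
    reactions: list[Reaction] = field(default_factory=list)
    extra: list[str] = field(default_factory=list)


@dataclass
class Experiment:
    id: str
    description: Optional[str] = None
    runs: list[Run] = field(default_factory=list)
    extra: list[str] = field(default_factory=list)


@dataclass
class RdmlDocument:
    version: str
    dateMade: Optional[str] = None  # ISO-8601; never auto-modified
    dateUpdated: Optional[str] = None
    experimenters: list[Experimenter] = field(default_factory=list)
    documentations: list[Documentation] = field(default_factory=list)
    dyes: list[Dye] = field(default_factory=list)
    samples: list[Sample] = field(default_factory=list)
    targets: list[Target] = field(default_factory=list)
    thermalCyclingConditions: list[CyclingProgram] = field(default_factory=list)
    experiments: list[Experiment] = field(default_factory=list)
    extra: list[str] = field(default_factory=list)

    # convenience lookups -------------------------------------------------
    def sample(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.id == sample_id:
                return s
        raise UnknownIdError(f"no sample with id {sample_id!r}")

    def target(self, target_id: str) -> Target:
        for t in self.targets:
            if t.id == target_id:
                return t
        raise UnknownIdError(f"no target with id {target_id!r}")

    def dye(self, dye_id: str) -> Dye:
        for d in self.dyes:
            if d.id == dye_id:
                return d
        raise UnknownIdError(f"no dye with id {dye_id!r}")


def new_minimal_document(version: str) -> RdmlDocument:
    """Return an empty, structurally valid document of the given version."""
    if version not in SUPPORTED_VERSIONS:
        raise UnsupportedVersionError(
            f"unsupported RDML version {version!r}; "
            f"supported: {', '.join(SUPPORTED_VERSIONS)}"
        )
    return RdmlDocument(version=version)


# ---------------------------------------------------------------------------
# semantic equality

def _norm_text(s: str) -> str:
    # whitespace-insensitive text comparison
    return " ".join(s.split())


def _canon(obj, sort_points: bool = False):
    """Canonical nested representation used by :func:`semantic_equal`.

    Unordered lists (top-level element lists, runs, reactions, per-reaction
    data, annotations, opaque extras) are sorted by their natural key so that
    element order does not affect equality; genuinely ordered sequences
    (cycling steps, curve points) keep their order.
    """
    if obj is None or isinstance(obj, (bool, int, float)):
        return obj
    if isinstance(obj, str):
        return _norm_text(obj)
    if isinstance(obj, tuple):
        return tuple(_canon(x) for x in obj)
    if isinstance(obj, list):
        return [_canon(x) for x in obj]
    if is_dataclass(obj):
        out = {"__type__": type(obj).__name__}
        for f in fields(obj):
            val = getattr(obj, f.name)
            if f.name == "extra":
                out[f.name] = sorted(_norm_text(x) for x in val)
            elif isinstance(val, list) and f.name in _UNORDERED_LIST_KEYS:
                key = _UNORDERED_LIST_KEYS[f.name]
                out[f.name] = sorted((_canon(x) for x in val), key=key)
            else:
                out[f.name] = _canon(val)
        return out
    raise TypeError(f"cannot canonicalize {type(obj)!r}")


def _key_id(c):
    return c["id"]


def _key_annotation(c):
    return (c["property"], c["value"])


def _key_reaction(c):
    return c["position"]


def _key_data(c):
    return c["targetRef"]


_UNORDERED_LIST_KEYS = {
    "experimenters": _key_id,
    "documentations": _key_id,
    "dyes": _key_id,
    "samples": _key_id,
    "targets": _key_id,
    "thermalCyclingConditions": _key_id,
    "experiments": _key_id,
    "runs": _key_id,
    "reactions": _key_reaction,
    "data": _key_data,
    "annotations": _key_annotation,
}


def _values_equal(a, b, rel_tol: float) -> bool:
    if isinstance(a, bool) or isinstance(b, bool):
        return a is b
    if isinstance(a, (int, float)) and isinstance(b, (int, float)):
        return math.isclose(a, b, rel_tol=rel_tol, abs_tol=1e-12)
    if type(a) is not type(b):
        return False
    if isinstance(a, dict):
        return a.keys() == b.keys() and all(
            _values_equal(a[k], b[k], rel_tol) for k in a
        )
    if isinstance(a, (list, tuple)):
        return len(a) == len(b) and all(
            _values_equal(x, y, rel_tol) for x, y in zip(a, b)
        )
    return a == b


def semantic_equal(a: RdmlDocument, b: RdmlDocument, rel_tol: float = 1e-9) -> bool:
    """Content equality, ignoring element order within unordered lists and
    whitespace in text; numbers compared to *rel_tol* relative tolerance."""
    return _values_equal(_canon(a), _canon(b), rel_tol)
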