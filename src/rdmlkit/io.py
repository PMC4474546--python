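"""Reading and writing RDML files.

An RDML file is a zip archive whose single data member is one XML document;
the root element carries the format version as an attribute.  Some
third-party tools emit the bare XML without the zip wrapper, so bare XML is
accepted on input (and available on output behind an explicit flag).

Version differences handled here:

* 1.0 runs name a predefined plate type and identify reactions by well
  label ("B7"); on read both are converted — the plate type to an explicit
  row/column format, the label to the 1-based row-major linear position the
  in-memory model always uses.  Writing a 1.0 document reverses both.
* Sample quantities are housed in material-specific elements
  (``templateDnaQuantity``/``templateRnaQuantity``) before 1.2 and in the
  unified ``quantity`` element from 1.2 on.
* Annotations and ``amplificationEfficiencySE`` are serialized only for 1.2.

Unknown elements encountered anywhere in the tree are preserved verbatim as
opaque XML strings on their parent and re-emitted on write, so foreign
extensions survive a round trip.  Output is deterministic: stable element
ordering, shortest round-trip decimal numbers, fixed zip metadata — writing
the same document twice yields byte-identical archives.
"""

from __future__ import annotations

import copy
import io as _io
import warnings
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import BinaryIO, Mapping, Optional, Union

from lxml import etree

from . import model as m
from .migrate import (
    format_to_plate_type,
    plate_type_to_format,
    position_to_well_label,
    well_label_to_position,
)

CANONICAL_ENTRY_NAME = "rdml_data.xml"

Source = Union[str, Path, bytes, BinaryIO]


@dataclass
class ContainerInfo:
    entryName: str
    wasBareXml: bool = False


# ---------------------------------------------------------------------------
# low-level helpers

def _as_bytes(source: Source) -> bytes:
    if isinstance(source, bytes):
        return source
    if isinstance(source, (str, Path)):
        try:
            return Path(source).read_bytes()
        except OSError as e:
            raise m.MalformedFileError(f"cannot read {source}: {e}") from e
    return source.read()


def _extract_xml(data: bytes) -> tuple[bytes, ContainerInfo]:
    if zipfile.is_zipfile(_io.BytesIO(data)):
        try:
            with zipfile.ZipFile(_io.BytesIO(data)) as zf:
                members = [n for n in zf.namelist() if not n.endswith("/")]
                xml_members = [n for n in members if n.lower().endswith(".xml")]
                if not xml_members:
                    raise m.MalformedFileError(
                        "zip archive contains no XML member")
                if len(xml_members) > 1:
                    if CANONICAL_ENTRY_NAME in xml_members:
                        xml_members = [CANONICAL_ENTRY_NAME]
                    else:
                        raise m.MalformedFileError(
                            "zip archive contains several XML members and "
                            f"none is named {CANONICAL_ENTRY_NAME!r}")
                name = xml_members[0]
                if name != CANONICAL_ENTRY_NAME:
                    warnings.warn(
                        f"zip member {name!r} instead of the canonical "
                        f"{CANONICAL_ENTRY_NAME!r}", stacklevel=3)
                return zf.read(name), ContainerInfo(name, wasBareXml=False)
        except zipfile.BadZipFile as e:
            raise m.MalformedFileError(f"corrupt zip archive: {e}") from e
    stripped = data.lstrip()
    if stripped.startswith(b"PK"):
        raise m.MalformedFileError("truncated or corrupt zip archive")
    return data, ContainerInfo("", wasBareXml=True)


def _parse_xml(xml: bytes):
    try:
        return etree.fromstring(xml)
    except etree.XMLSyntaxError as e:
        raise m.MalformedFileError(f"not well-formed XML: {e}") from e


def _localname(el) -> str:
    return etree.QName(el).localname if el.tag is not etree.Comment else ""


def _opaque(el) -> str:
    el = copy.deepcopy(el)
    el.tail = None
    return etree.tostring(el, encoding="unicode")


def _num(text: str, where: str) -> float:
    try:
        return float(text)
    except (TypeError, ValueError) as e:
        raise m.MalformedFileError(f"bad number {text!r} in {where}") from e


def _fmt(x: float) -> str:
    """Shortest round-trip decimal; integral values without a fraction."""
    f = float(x)
    if f.is_integer() and abs(f) < 1e15:
        return str(int(f))
    return repr(f)


def _sub(parent, tag: str, text: Optional[str] = None, **attrib):
    el = etree.SubElement(parent, tag, **attrib)
    if text is not None:
        el.text = text
    return el


def _append_extras(parent, extras: list[str]) -> None:
    for blob in extras:
        parent.append(etree.fromstring(blob))


# ---------------------------------------------------------------------------
# version detection

def detect_version(source: Source) -> str:
    """Return the version attribute of the root element without full parsing."""
    xml, _ = _extract_xml(_as_bytes(source))
    try:
        for _event, el in etree.iterparse(_io.BytesIO(xml), events=("start",)):
            version = el.get("version")
            if version is None:
                raise m.MalformedFileError(
                    "root element carries no version attribute")
            return version
    except etree.XMLSyntaxError as e:
        raise m.MalformedFileError(f"not well-formed XML: {e}") from e
    raise m.MalformedFileError("empty XML document")


# ---------------------------------------------------------------------------
# reading

def read_rdml(
    source: Source,
    plate_map: Optional[Mapping[str, m.PcrFormat]] = None,
) -> tuple[m.RdmlDocument, ContainerInfo]:
    """Read an RDML file (zip container or bare XML) into the model.

    *plate_map* supplies geometries for non-standard version-1.0 plate-type
    tokens.  Unknown elements are preserved opaquely on their parent.
    """
    xml, info = _extract_xml(_as_bytes(source))
    root = _parse_xml(xml)
    if _localname(root) != "rdml":
        raise m.MalformedFileError(
            f"root element is {root.tag!r}, expected 'rdml'")
    version = root.get("version")
    if version is None:
        raise m.MalformedFileError("root element carries no version attribute")
    if version not in m.SUPPORTED_VERSIONS:
        raise m.UnsupportedVersionError(
            f"unsupported RDML version {version!r}")
    doc = m.RdmlDocument(version=version)
    for child in root:
        tag = _localname(child)
        if tag == "dateMade":
            doc.dateMade = child.text or ""
        elif tag == "dateUpdated":
            doc.dateUpdated = child.text or ""
        elif tag == "experimenter":
            doc.experimenters.append(_read_experimenter(child))
        elif tag == "documentation":
            doc.documentations.append(_read_documentation(child))
        elif tag == "dye":
            doc.dyes.append(_read_dye(child))
        elif tag == "sample":
            doc.samples.append(_read_sample(child))
        elif tag == "target":
            doc.targets.append(_read_target(child))
        elif tag == "thermalCyclingConditions":
            doc.thermalCyclingConditions.append(_read_cycling(child))
        elif tag == "experiment":
            doc.experiments.append(_read_experiment(child, version, plate_map))
        elif tag:
            doc.extra.append(_opaque(child))
    return doc, info


def _req_id(el) -> str:
    return el.get("id") or ""


def _read_experimenter(el) -> m.Experimenter:
    out = m.Experimenter(id=_req_id(el))
    for child in el:
        tag = _localname(child)
        if tag in ("firstName", "lastName", "email"):
            setattr(out, tag, child.text or "")
        elif tag:
            out.extra.append(_opaque(child))
    return out


def _read_documentation(el) -> m.Documentation:
    out = m.Documentation(id=_req_id(el))
    for child in el:
        tag = _localname(child)
        if tag == "text":
            out.text = child.text or ""
        elif tag:
            out.extra.append(_opaque(child))
    return out


def _read_dye(el) -> m.Dye:
    out = m.Dye(id=_req_id(el))
    for child in el:
        tag = _localname(child)
        if tag == "description":
            out.description = child.text or ""
        elif tag:
            out.extra.append(_opaque(child))
    return out


def _read_quantity(el) -> m.Quantity:
    value, unit = 0.0, ""
    for child in el:
        tag = _localname(child)
        if tag == "value":
            value = _num(child.text, "quantity/value")
        elif tag == "unit":
            unit = child.text or ""
    return m.Quantity(value=value, unit=unit)


def _read_quality(el, material: str) -> m.LegacyQuality:
    method, result = "", None
    for child in el:
        tag = _localname(child)
        if tag == "method":
            method = child.text or ""
        elif tag == "result":
            result = _num(child.text, "quality/result")
    return m.LegacyQuality(material=material, method=method, result=result)


def _read_sample(el) -> m.Sample:
    out = m.Sample(id=_req_id(el))
    for child in el:
        tag = _localname(child)
        if tag == "description":
            out.description = child.text or ""
        elif tag == "type":
            token = child.text or ""
            out.sampleType = m.SAMPLE_TYPE_TOKENS.get(token, token)
        elif tag == "annotation":
            prop = value = ""
            for sub in child:
                if _localname(sub) == "property":
                    prop = sub.text or ""
                elif _localname(sub) == "value":
                    value = sub.text or ""
            out.annotations.append(m.Annotation(property=prop, value=value))
        elif tag == "quantity":
            out.quantity = _read_quantity(child)
            out.material = child.get("material")
        elif tag == "templateDnaQuantity":
            out.quantity = _read_quantity(child)
            out.material = "dna"
        elif tag == "templateRnaQuantity":
            out.quantity = _read_quantity(child)
            out.material = "rna"
        elif tag == "templateDnaQuality":
            out.legacyQuality = _read_quality(child, "dna")
        elif tag == "templateRnaQuality":
            out.legacyQuality = _read_quality(child, "rna")
        elif tag:
            out.extra.append(_opaque(child))
    return out


def _read_target(el) -> m.Target:
    out = m.Target(id=_req_id(el))
    for child in el:
        tag = _localname(child)
        if tag == "description":
            out.description = child.text or ""
        elif tag == "type":
            token = child.text or ""
            out.targetType = m.TARGET_TYPE_TOKENS.get(token, token)
        elif tag == "dyeId":
            out.dyeRef = child.get("id") or (child.text or "")
        elif tag == "amplificationEfficiency":
            out.amplificationEfficiency = _num(
                child.text, f"target[{out.id}]/amplificationEfficiency")
        elif tag == "amplificationEfficiencySE":
            out.amplificationEfficiencySE = _num(
                child.text, f"target[{out.id}]/amplificationEfficiencySE")
        elif tag == "sequences":
            for sub in child:
                stag = _localname(sub)
                if stag in ("forwardPrimer", "reversePrimer", "probe",
                            "amplicon"):
                    setattr(out.sequences, stag, sub.text or "")
        elif tag:
            out.extra.append(_opaque(child))
    return out


def _read_cycling(el) -> m.CyclingProgram:
    out = m.CyclingProgram(id=_req_id(el))
    for child in el:
        tag = _localname(child)
        if tag == "description":
            out.description = child.text or ""
        elif tag == "step":
            temp = dur = 0.0
            acquire = False
            for sub in child:
                stag = _localname(sub)
                if stag == "temperature":
                    temp = _num(sub.text, "step/temperature")
                elif stag == "duration":
                    dur = _num(sub.text, "step/duration")
                elif stag == "acquire":
                    acquire = (sub.text or "").strip() in ("1", "true", "True")
            out.steps.append(m.CyclingStep(temperature=temp, duration=dur,
                                           acquire=acquire))
        elif tag:
            out.extra.append(_opaque(child))
    return out


def _read_experiment(el, version, plate_map) -> m.Experiment:
    out = m.Experiment(id=_req_id(el))
    for child in el:
        tag = _localname(child)
        if tag == "description":
            out.description = child.text or ""
        elif tag == "run":
            out.runs.append(_read_run(child, version, plate_map))
        elif tag:
            out.extra.append(_opaque(child))
    return out


def _read_run(el, version, plate_map) -> m.Run:
    out = m.Run(id=_req_id(el))
    react_elements = []
    for child in el:
        tag = _localname(child)
        if tag == "description":
            out.description = child.text or ""
        elif tag == "pcrFormat":
            rows = columns = 1
            row_scheme, col_scheme = "letters", "numbers"
            for sub in child:
                stag = _localname(sub)
                if stag == "rows":
                    rows = int(_num(sub.text, "pcrFormat/rows"))
                elif stag == "columns":
                    columns = int(_num(sub.text, "pcrFormat/columns"))
                elif stag == "rowLabel":
                    row_scheme = sub.text or "letters"
                elif stag == "columnLabel":
                    col_scheme = sub.text or "numbers"
            out.pcrFormat = m.PcrFormat(rows=rows, columns=columns,
                                        rowLabelScheme=row_scheme,
                                        columnLabelScheme=col_scheme)
        elif tag == "plateType":
            out.plateType = child.text or ""
        elif tag == "react":
            react_elements.append(child)
        elif tag:
            out.extra.append(_opaque(child))
    if version == "1.0" and out.plateType and out.pcrFormat is None:
        out.pcrFormat = plate_type_to_format(out.plateType, plate_map)
    for child in react_elements:
        out.reactions.append(_read_react(child, version, out))
    return out


def _read_react(el, version, run: m.Run) -> m.Reaction:
    if version == "1.0":
        label = el.get("well")
        if label is None:
            raise m.MalformedFileError(
                f"version-1.0 react in run {run.id!r} has no well attribute")
        if run.pcrFormat is None:
            raise m.MalformedFileError(
                f"run {run.id!r} has no plate geometry to resolve well "
                f"{label!r}")
        position = well_label_to_position(label, run.pcrFormat)
    else:
        raw = el.get("id")
        if raw is None:
            raise m.MalformedFileError(
                f"react in run {run.id!r} has no position id")
        position = int(raw)
    out = m.Reaction(position=position)
    for child in el:
        tag = _localname(child)
        if tag == "sample":
            out.sampleRef = child.get("id") or (child.text or "")
        elif tag == "data":
            out.data.append(_read_react_data(child))
        elif tag:
            out.extra.append(_opaque(child))
    return out


def _read_react_data(el) -> m.ReactionData:
    out = m.ReactionData(targetRef="")
    for child in el:
        tag = _localname(child)
        if tag == "tar":
            out.targetRef = child.get("id") or (child.text or "")
        elif tag == "cq":
            out.cq = _num(child.text, "data/cq")
        elif tag == "bgFluor":
            out.baseline = _num(child.text, "data/bgFluor")
        elif tag == "quantFluor":
            out.quantificationThreshold = _num(child.text, "data/quantFluor")
        elif tag == "adp":
            cyc = fluor = 0.0
            for sub in child:
                stag = _localname(sub)
                if stag == "cyc":
                    cyc = _num(sub.text, "adp/cyc")
                elif stag == "fluor":
                    fluor = _num(sub.text, "adp/fluor")
            out.amplificationPoints.append((cyc, fluor))
        elif tag == "mdp":
            tmp = fluor = 0.0
            for sub in child:
                stag = _localname(sub)
                if stag == "tmp":
                    tmp = _num(sub.text, "mdp/tmp")
                elif stag == "fluor":
                    fluor = _num(sub.text, "mdp/fluor")
            out.meltingPoints.append((tmp, fluor))
        elif tag:
            out.extra.append(_opaque(child))
    return out


# ---------------------------------------------------------------------------
# writing

def document_to_xml_bytes(doc: m.RdmlDocument) -> bytes:
    """Serialize *doc* to its version-appropriate XML (deterministic)."""
    root = etree.Element("rdml", version=doc.version)
    v12 = doc.version == "1.2"
    if doc.dateMade is not None:
        _sub(root, "dateMade", doc.dateMade)
    if doc.dateUpdated is not None:
        _sub(root, "dateUpdated", doc.dateUpdated)
    for e in doc.experimenters:
        el = _sub(root, "experimenter", id=e.id)
        for name in ("firstName", "lastName", "email"):
            val = getattr(e, name)
            if val is not None:
                _sub(el, name, val)
        _append_extras(el, e.extra)
    for d in doc.documentations:
        el = _sub(root, "documentation", id=d.id)
        _sub(el, "text", d.text)
        _append_extras(el, d.extra)
    for dye in doc.dyes:
        el = _sub(root, "dye", id=dye.id)
        if dye.description is not None:
            _sub(el, "description", dye.description)
        _append_extras(el, dye.extra)
    for s in doc.samples:
        _write_sample(root, s, v12)
    for t in doc.targets:
        _write_target(root, t, v12)
    for prog in doc.thermalCyclingConditions:
        el = _sub(root, "thermalCyclingConditions", id=prog.id)
        if prog.description is not None:
            _sub(el, "description", prog.description)
        for step in prog.steps:
            sel = _sub(el, "step")
            _sub(sel, "temperature", _fmt(step.temperature))
            _sub(sel, "duration", _fmt(step.duration))
            _sub(sel, "acquire", "1" if step.acquire else "0")
        _append_extras(el, prog.extra)
    for exp in doc.experiments:
        el = _sub(root, "experiment", id=exp.id)
        if exp.description is not None:
            _sub(el, "description", exp.description)
        for run in exp.runs:
            _write_run(el, run, doc.version)
        _append_extras(el, exp.extra)
    _append_extras(root, doc.extra)
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8")


def _write_sample(root, s: m.Sample, v12: bool) -> None:
    el = _sub(root, "sample", id=s.id)
    if s.description is not None:
        _sub(el, "description", s.description)
    _sub(el, "type", m.SAMPLE_TYPE_NAMES.get(s.sampleType, s.sampleType))
    if v12:
        for ann in s.annotations:
            ael = _sub(el, "annotation")
            _sub(ael, "property", ann.property)
            _sub(ael, "value", ann.value)
    if s.quantity is not None:
        if v12:
            attrib = {"material": s.material} if s.material else {}
            qel = _sub(el, "quantity", **attrib)
        else:
            tag = ("templateRnaQuantity" if s.material == "rna"
                   else "templateDnaQuantity")
            qel = _sub(el, tag)
        _sub(qel, "value", _fmt(s.quantity.value))
        _sub(qel, "unit", s.quantity.unit)
    if s.legacyQuality is not None and not v12:
        tag = ("templateRnaQuality" if s.legacyQuality.material == "rna"
               else "templateDnaQuality")
        qel = _sub(el, tag)
        _sub(qel, "method", s.legacyQuality.method)
        if s.legacyQuality.result is not None:
            _sub(qel, "result", _fmt(s.legacyQuality.result))
    _append_extras(el, s.extra)


def _write_target(root, t: m.Target, v12: bool) -> None:
    el = _sub(root, "target", id=t.id)
    if t.description is not None:
        _sub(el, "description", t.description)
    _sub(el, "type", m.TARGET_TYPE_NAMES.get(t.targetType, t.targetType))
    if t.amplificationEfficiency is not None:
        _sub(el, "amplificationEfficiency", _fmt(t.amplificationEfficiency))
    if t.amplificationEfficiencySE is not None and v12:
        _sub(el, "amplificationEfficiencySE", _fmt(t.amplificationEfficiencySE))
    if t.dyeRef is not None:
        _sub(el, "dyeId", id=t.dyeRef)
    seq = t.sequences
    if any(getattr(seq, f) is not None for f in
           ("forwardPrimer", "reversePrimer", "probe", "amplicon")):
        sel = _sub(el, "sequences")
        for f in ("forwardPrimer", "reversePrimer", "probe", "amplicon"):
            val = getattr(seq, f)
            if val is not None:
                _sub(sel, f, val)
    _append_extras(el, t.extra)


def _write_run(parent, run: m.Run, version: str) -> None:
    el = _sub(parent, "run", id=run.id)
    if run.description is not None:
        _sub(el, "description", run.description)
    if version == "1.0":
        token = run.plateType
        fmt = run.pcrFormat
        if token is None:
            if fmt is None:
                raise m.RefusedWriteError(
                    f"run {run.id!r} has neither plate type nor format")
            token = format_to_plate_type(fmt)
        if fmt is None:
            fmt = plate_type_to_format(token)
        _sub(el, "plateType", token)
    else:
        fmt = run.pcrFormat
        if fmt is not None:
            fel = _sub(el, "pcrFormat")
            _sub(fel, "rows", str(fmt.rows))
            _sub(fel, "columns", str(fmt.columns))
            _sub(fel, "rowLabel", fmt.rowLabelScheme)
            _sub(fel, "columnLabel", fmt.columnLabelScheme)
    for react in run.reactions:
        if version == "1.0":
            rel = _sub(el, "react",
                       well=position_to_well_label(react.position, fmt))
        else:
            rel = _sub(el, "react", id=str(react.position))
        _sub(rel, "sample", id=react.sampleRef)
        for d in react.data:
            del_ = _sub(rel, "data")
            _sub(del_, "tar", id=d.targetRef)
            if d.cq is not None:
                _sub(del_, "cq", _fmt(d.cq))
            if d.baseline is not None:
                _sub(del_, "bgFluor", _fmt(d.baseline))
            if d.quantificationThreshold is not None:
                _sub(del_, "quantFluor", _fmt(d.quantificationThreshold))
            for cyc, fluor in d.amplificationPoints:
                pel = _sub(del_, "adp")
                _sub(pel, "cyc", _fmt(cyc))
                _sub(pel, "fluor", _fmt(fluor))
            for tmp, fluor in d.meltingPoints:
                pel = _sub(del_, "mdp")
                _sub(pel, "tmp", _fmt(tmp))
                _sub(pel, "fluor", _fmt(fluor))
            _append_extras(del_, d.extra)
        _append_extras(rel, react.extra)
    _append_extras(el, run.extra)


def write_rdml_bytes(
    doc: m.RdmlDocument, bare_xml: bool = False, force: bool = False
) -> bytes:
    """Serialize *doc* to the bytes of an RDML file (or bare XML).

    Validation errors block writing unless *force* is set; warnings never do.
    """
    if not force:
        from .validate import validate

        report = validate(doc)
        if not report.valid:
            summary = "; ".join(
                f"{i.code} at {i.path}" for i in report.errors[:5])
            raise m.RefusedWriteError(
                f"document fails validation ({len(report.errors)} error(s)): "
                f"{summary}")
    xml = document_to_xml_bytes(doc)
    if bare_xml:
        return xml
    buf = _io.BytesIO()
    with zipfile.ZipFile(buf, "w", zipfile.ZIP_DEFLATED) as zf:
        info = zipfile.ZipInfo(CANONICAL_ENTRY_NAME,
                               date_time=(1980, 1, 1, 0, 0, 0))
        info.compress_type = zipfile.ZIP_DEFLATED
        info.external_attr = 0o644 << 16
        zf.writestr(info, xml)
    return buf.getvalue()


def write_rdml(
    doc: m.RdmlDocument,
    destination: Union[str, Path, BinaryIO],
    bare_xml: bool = False,
    force: bool = False,
) -> ContainerInfo:
    """Write *doc* as a zip-wrapped RDML file (bare XML behind a flag).

    Output is byte-deterministic for a fixed document.
    """
    payload = write_rdml_bytes(doc, bare_xml=bare_xml, force=force)
    if isinstance(destination, (str, Path)):
        Path(destination).write_bytes(payload)
    else:
        destination.write(payload)
    return ContainerInfo("" if bare_xml else CANONICAL_ENTRY_NAME,
                         wasBareXml=bare_xml)
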