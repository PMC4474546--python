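"""Read-only plate reconstruction, CSV export and curve plotting.

Raw instrument readings are the part of an RDML file that should never be
edited, so everything here is a view: a table reconstructing the plate
layout, CSV renderings of it, and amplification/melt curve series with a
deterministic SVG renderer.  No operation mutates the document.

CSV follows RFC 4180 (comma separator, CRLF line ends, double-quote
escaping) with "." as the decimal separator; missing values render as empty
fields.  SVG output is a standalone document — styling lives in element
attributes, coordinates are linearly scaled into a fixed viewBox with 5%
margins — and is byte-identical for identical input.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass, field
from typing import Optional, Sequence

from lxml import etree

from .migrate import position_to_well_label, plate_type_to_format
from .model import (
    IncompatibleSeriesError,
    RdmlDocument,
    Run,
)

KIND_AMPLIFICATION = "amplification"
KIND_MELT = "melt"


@dataclass
class PlateEntry:
    targetId: str
    dyeId: str = ""
    cq: Optional[float] = None
    baseline: Optional[float] = None
    threshold: Optional[float] = None


@dataclass
class PlateCell:
    position: int
    wellLabel: str
    sampleId: str
    sampleType: str = ""
    entries: list[PlateEntry] = field(default_factory=list)


@dataclass
class CurveSeries:
    reactionPosition: int
    targetId: str
    kind: str  # "amplification" | "melt"
    points: list[tuple[float, float]] = field(default_factory=list)


def _run_format(run: Run):
    if run.pcrFormat is not None:
        return run.pcrFormat
    if run.plateType is not None:
        return plate_type_to_format(run.plateType)
    return None


def plate_table(run: Run, doc: Optional[RdmlDocument] = None) -> list[PlateCell]:
    """One cell per occupied position, ordered by position; empty wells are
    omitted.  Passing the owning document resolves sample types and dyes."""
    fmt = _run_format(run)
    samples = {s.id: s for s in doc.samples} if doc else {}
    targets = {t.id: t for t in doc.targets} if doc else {}
    cells = []
    for react in sorted(run.reactions, key=lambda r: r.position):
        sample = samples.get(react.sampleRef)
        cell = PlateCell(
            position=react.position,
            wellLabel=(position_to_well_label(react.position, fmt)
                       if fmt else str(react.position)),
            sampleId=react.sampleRef,
            sampleType=sample.sampleType if sample else "",
        )
        for d in react.data:
            target = targets.get(d.targetRef)
            cell.entries.append(PlateEntry(
                targetId=d.targetRef,
                dyeId=(target.dyeRef or "") if target else "",
                cq=d.cq,
                baseline=d.baseline,
                threshold=d.quantificationThreshold,
            ))
        cells.append(cell)
    return cells


def _cell_num(x: Optional[float]) -> str:
    if x is None:
        return ""
    f = float(x)
    return str(int(f)) if f.is_integer() and abs(f) < 1e15 else repr(f)


def export_csv(run: Run, mode: str = "summary",
               doc: Optional[RdmlDocument] = None) -> str:
    """Render the run as CSV text.

    ``summary``: one row per (reaction, target) with Cq/baseline/threshold.
    ``long``: one row per fluorescence point, for re-import into other
    analysis software.  Rows are ordered by position, then target, then x.
    """
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\r\n")
    if mode == "summary":
        writer.writerow(["position", "well", "sample", "sampleType",
                         "target", "dye", "cq", "baseline", "threshold"])
        for cell in plate_table(run, doc):
            for entry in sorted(cell.entries, key=lambda e: e.targetId):
                writer.writerow([
                    cell.position, cell.wellLabel, cell.sampleId,
                    cell.sampleType, entry.targetId, entry.dyeId,
                    _cell_num(entry.cq), _cell_num(entry.baseline),
                    _cell_num(entry.threshold),
                ])
    elif mode == "long":
        writer.writerow(["position", "target", "kind", "x", "y"])
        for react in sorted(run.reactions, key=lambda r: r.position):
            for d in sorted(react.data, key=lambda d: d.targetRef):
                for x, y in d.amplificationPoints:
                    writer.writerow([react.position, d.targetRef,
                                     KIND_AMPLIFICATION,
                                     _cell_num(x), _cell_num(y)])
                for x, y in d.meltingPoints:
                    writer.writerow([react.position, d.targetRef, KIND_MELT,
                                     _cell_num(x), _cell_num(y)])
    else:
        raise ValueError(f"unknown CSV mode {mode!r}")
    return buf.getvalue()


def extract_curves(
    run: Run,
    kind: str = KIND_AMPLIFICATION,
    sample: Optional[str] = None,
    target: Optional[str] = None,
) -> list[CurveSeries]:
    """One series per (reaction, target) with nonempty points of *kind*,
    optionally filtered by sample id and/or target id."""
    if kind not in (KIND_AMPLIFICATION, KIND_MELT):
        raise ValueError(f"unknown curve kind {kind!r}")
    out = []
    for react in sorted(run.reactions, key=lambda r: r.position):
        if sample is not None and react.sampleRef != sample:
            continue
        for d in sorted(react.data, key=lambda d: d.targetRef):
            if target is not None and d.targetRef != target:
                continue
            points = (d.amplificationPoints if kind == KIND_AMPLIFICATION
                      else d.meltingPoints)
            if points:
                out.append(CurveSeries(
                    reactionPosition=react.position,
                    targetId=d.targetRef,
                    kind=kind,
                    points=list(points),
                ))
    return out


# ---------------------------------------------------------------------------
# SVG rendering

_PALETTE = ("#1f77b4", "#d62728", "#2ca02c", "#9467bd", "#ff7f0e",
            "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf")


@dataclass
class SvgOptions:
    width: int = 800
    height: int = 500
    margin: float = 0.05  # fraction of each dimension kept clear
    xLabel: Optional[str] = None
    yLabel: str = "fluorescence"
    ticks: int = 5
    title: Optional[str] = None


def _f(x: float) -> str:
    return f"{x:.2f}"


def _ticks(lo: float, hi: float, n: int) -> list[float]:
    if hi == lo:
        return [lo]
    return [lo + (hi - lo) * i / (n - 1) for i in range(n)]


def render_svg(series: Sequence[CurveSeries],
               options: Optional[SvgOptions] = None) -> str:
    """Render curve series as a standalone SVG chart (one polyline each).

    All series must share one kind; an empty list yields axes only.
    Identical input renders identical text.
    """
    opts = options or SvgOptions()
    kinds = {s.kind for s in series}
    if len(kinds) > 1:
        raise IncompatibleSeriesError(
            f"cannot mix curve kinds in one chart: {sorted(kinds)}")
    kind = next(iter(kinds)) if kinds else KIND_AMPLIFICATION
    x_label = opts.xLabel or ("cycle" if kind == KIND_AMPLIFICATION
                             else "temperature (degC)")

    xs = [p[0] for s in series for p in s.points]
    ys = [p[1] for s in series for p in s.points]
    x_lo, x_hi = (min(xs), max(xs)) if xs else (0.0, 1.0)
    y_lo, y_hi = (min(ys), max(ys)) if ys else (0.0, 1.0)
    if x_hi == x_lo:
        x_hi = x_lo + 1.0
    if y_hi == y_lo:
        y_hi = y_lo + 1.0

    w, h = float(opts.width), float(opts.height)
    mx, my = w * opts.margin, h * opts.margin
    # extra room on the left/bottom for tick labels
    left, right = mx + 45.0, w - mx
    top, bottom = my + (20.0 if opts.title else 0.0), h - my - 30.0

    def sx(x: float) -> float:
        return left + (x - x_lo) / (x_hi - x_lo) * (right - left)

    def sy(y: float) -> float:
        return bottom - (y - y_lo) / (y_hi - y_lo) * (bottom - top)

    svg = etree.Element(
        "svg", xmlns="http://www.w3.org/2000/svg",
        width=str(opts.width), height=str(opts.height),
        viewBox=f"0 0 {opts.width} {opts.height}")
    etree.SubElement(svg, "rect", x="0", y="0", width=str(opts.width),
                     height=str(opts.height), fill="white")
    if opts.title:
        t = etree.SubElement(svg, "text", x=_f(w / 2), y=_f(my + 5),
                             fill="black")
        t.set("font-size", "14")
        t.set("text-anchor", "middle")
        t.text = opts.title

    axes = etree.SubElement(svg, "g", stroke="black")
    axes.set("stroke-width", "1")
    etree.SubElement(axes, "line", x1=_f(left), y1=_f(bottom), x2=_f(right),
                     y2=_f(bottom))
    etree.SubElement(axes, "line", x1=_f(left), y1=_f(bottom), x2=_f(left),
                     y2=_f(top))

    labels = etree.SubElement(svg, "g", fill="black")
    labels.set("font-size", "10")
    labels.set("font-family", "sans-serif")
    for xv in _ticks(x_lo, x_hi, opts.ticks):
        px = sx(xv)
        etree.SubElement(axes, "line", x1=_f(px), y1=_f(bottom), x2=_f(px),
                         y2=_f(bottom + 4))
        t = etree.SubElement(labels, "text", x=_f(px), y=_f(bottom + 15))
        t.set("text-anchor", "middle")
        t.text = f"{xv:g}"
    for yv in _ticks(y_lo, y_hi, opts.ticks):
        py = sy(yv)
        etree.SubElement(axes, "line", x1=_f(left - 4), y1=_f(py), x2=_f(left),
                         y2=_f(py))
        t = etree.SubElement(labels, "text", x=_f(left - 6), y=_f(py + 3))
        t.set("text-anchor", "end")
        t.text = f"{yv:g}"
    tx = etree.SubElement(labels, "text", x=_f((left + right) / 2),
                          y=_f(bottom + 28))
    tx.set("text-anchor", "middle")
    tx.text = x_label
    ty = etree.SubElement(labels, "text", x=_f(12), y=_f((top + bottom) / 2))
    ty.set("text-anchor", "middle")
    ty.set("transform", f"rotate(-90 12 {_f((top + bottom) / 2)})")
    ty.text = opts.yLabel

    for i, s in enumerate(series):
        pts = " ".join(f"{_f(sx(x))},{_f(sy(y))}" for x, y in s.points)
        pl = etree.SubElement(svg, "polyline", points=pts, fill="none",
                              stroke=_PALETTE[i % len(_PALETTE)])
        pl.set("stroke-width", "1.5")
        pl.set("data-position", str(s.reactionPosition))
        pl.set("data-target", s.targetId)
    return etree.tostring(svg, encoding="unicode")


def parse_long_csv(text: str) -> dict[tuple[int, str, str], list[tuple[float, float]]]:
    """Parse long-mode CSV back into {(position, target, kind): points}."""
    reader = csv.reader(_io.StringIO(text))
    header = next(reader)
    assert header[:5] == ["position", "target", "kind", "x", "y"]
    out: dict[tuple[int, str, str], list[tuple[float, float]]] = {}
    for row in reader:
        if not row:
            continue
        pos, target, kind, x, y = row[:5]
        out.setdefault((int(pos), target, kind), []).append(
            (float(x), float(y)))
    return out
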