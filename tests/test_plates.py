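import copy

import pytest
from lxml import etree

from rdmlkit import semantic_equal
from rdmlkit.model import (
    IncompatibleSeriesError,
    PcrFormat,
    Reaction,
    ReactionData,
    Run,
)
from rdmlkit.plates import (
    CurveSeries,
    SvgOptions,
    export_csv,
    extract_curves,
    parse_long_csv,
    plate_table,
    render_svg,
)


def _tiny_run() -> Run:
    return Run(
        id="r1", pcrFormat=PcrFormat(rows=8, columns=12),
        reactions=[
            Reaction(position=1, sampleRef="s1", data=[
                ReactionData(targetRef="t1", cq=21.5,
                             amplificationPoints=[(float(c), 0.1 * c)
                                                  for c in range(1, 41)]),
            ]),
            Reaction(position=13, sampleRef="s2", data=[
                ReactionData(targetRef="t1", cq=None,
                             meltingPoints=[(60.0, 0.9), (60.5, 0.8)]),
            ]),
        ])


def test_plate_table_labels_and_order():
    cells = plate_table(_tiny_run())
    assert [c.position for c in cells] == [1, 13]
    assert [c.wellLabel for c in cells] == ["A1", "B1"]
    assert cells[0].entries[0].cq == 21.5


def test_plate_table_empty_run():
    assert plate_table(Run(id="r", pcrFormat=PcrFormat(8, 12))) == []


def test_plate_table_carries_all_cqs(doc12):
    run = doc12.experiments[0].runs[0]
    cells = plate_table(run, doc12)
    assert len(cells) == len(run.reactions)
    by_pos = {r.position: r for r in run.reactions}
    for cell in cells:
        assert cell.entries[0].cq == by_pos[cell.position].data[0].cq
        assert cell.sampleType  # resolved through the document
        assert cell.entries[0].dyeId == "SYBR"


def test_summary_csv_shape():
    lines = export_csv(_tiny_run(), "summary").splitlines()
    assert len(lines) == 3
    assert lines[0].split(",")[:4] == ["position", "well", "sample",
                                      "sampleType"]


def test_missing_cq_is_empty_field_not_nan():
    lines = export_csv(_tiny_run(), "summary").splitlines()
    row_b1 = next(l for l in lines if l.startswith("13,"))
    assert ",nan" not in row_b1.lower()
    assert row_b1.split(",")[6] == ""  # cq column


def test_long_csv_row_count():
    run = _tiny_run()
    run.reactions = run.reactions[:1]  # one reaction, 40 cycles
    lines = export_csv(run, "long").splitlines()
    assert len(lines) == 41 and lines[0] == "position,target,kind,x,y"


def test_long_csv_reimport_recovers_points(doc12):
    """Parsing the long CSV back yields exactly the stored point sets."""
    run = doc12.experiments[0].runs[0]
    recovered = parse_long_csv(export_csv(run, "long"))
    for react in run.reactions:
        for d in react.data:
            if d.amplificationPoints:
                got = recovered[(react.position, d.targetRef,
                                 "amplification")]
                assert got == [(float(x), float(y))
                               for x, y in d.amplificationPoints]
            if d.meltingPoints:
                got = recovered[(react.position, d.targetRef, "melt")]
                assert got == [(float(x), float(y))
                               for x, y in d.meltingPoints]


def test_extract_curves_counts_and_passthrough(doc12):
    run = doc12.experiments[0].runs[0]
    n_with_melt = sum(1 for r in run.reactions for d in r.data
                      if d.meltingPoints)
    melt = extract_curves(run, "melt")
    assert len(melt) == n_with_melt
    amp = extract_curves(run, "amplification")
    by_pos = {r.position: r for r in run.reactions}
    for series in amp:
        stored = by_pos[series.reactionPosition].data[0].amplificationPoints
        assert [p[0] for p in series.points] == [p[0] for p in stored]


def test_extract_curves_filters(doc12):
    run = doc12.experiments[0].runs[0]
    only = extract_curves(run, "amplification", target="tgt1")
    assert only and all(s.targetId == "tgt1" for s in only)
    assert extract_curves(run, "amplification", target="nope") == []
    one = extract_curves(run, "amplification", sample="ntc_1")
    assert len(one) == 1


def test_views_do_not_mutate_document(doc12):
    before = copy.deepcopy(doc12)
    run = doc12.experiments[0].runs[0]
    plate_table(run, doc12)
    export_csv(run, "summary", doc12)
    export_csv(run, "long")
    render_svg(extract_curves(run, "amplification"))
    assert semantic_equal(doc12, before)


# ---------------------------------------------------------------------------
# SVG

def _series(n=3, kind="amplification"):
    return [CurveSeries(reactionPosition=i + 1, targetId="t1", kind=kind,
                        points=[(float(c), 0.1 * c + i) for c in range(1, 11)])
            for i in range(n)]


def test_svg_one_polyline_per_series():
    svg = render_svg(_series(3))
    root = etree.fromstring(svg.encode())
    polylines = root.findall(".//{http://www.w3.org/2000/svg}polyline")
    assert len(polylines) == 3


def test_svg_empty_series_is_axes_only():
    svg = render_svg([])
    root = etree.fromstring(svg.encode())
    assert root.findall(".//{http://www.w3.org/2000/svg}polyline") == []
    assert root.findall(".//{http://www.w3.org/2000/svg}line")


def test_svg_deterministic():
    assert render_svg(_series(2)) == render_svg(_series(2))


def test_svg_mixed_kinds_rejected():
    mixed = _series(1) + _series(1, kind="melt")
    with pytest.raises(IncompatibleSeriesError):
        render_svg(mixed)


def test_svg_parses_as_xml_for_fixture(doc12):
    run = doc12.experiments[0].runs[0]
    for kind in ("amplification", "melt"):
        svg = render_svg(extract_curves(run, kind),
                         SvgOptions(title=f"{kind} curves"))
        root = etree.fromstring(svg.encode())
        assert root.tag.endswith("svg")
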