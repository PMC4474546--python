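import copy

import pytest

from rdmlkit import (
    generate_document,
    migrate,
    read_rdml,
    semantic_equal,
    validate,
)
from rdmlkit.migrate import (
    PLATE_TYPE_MAP,
    format_to_plate_type,
    plate_type_to_format,
    position_to_well_label,
    well_label_to_position,
)
from rdmlkit.model import (
    Annotation,
    InvalidPositionError,
    InvalidWellError,
    LegacyQuality,
    PcrFormat,
    UnknownPlateTypeError,
)
from rdmlkit.synth import SyntheticRunSpec

F96 = PcrFormat(rows=8, columns=12)


# ---------------------------------------------------------------------------
# coordinate conversion

@pytest.mark.parametrize("label,expected", [
    ("A1", 1), ("A12", 12), ("B1", 13), ("H12", 96), ("b7", 19),
])
def test_well_label_to_position_96(label, expected):
    assert well_label_to_position(label, F96) == expected


@pytest.mark.parametrize("position,expected", [
    (1, "A1"), (12, "A12"), (13, "B1"), (96, "H12"),
])
def test_position_to_well_label_96(position, expected):
    assert position_to_well_label(position, F96) == expected


@pytest.mark.parametrize("label", ["Z1", "A13", "1A", "", "A0", "QQ"])
def test_invalid_well_labels(label):
    with pytest.raises(InvalidWellError):
        well_label_to_position(label, F96)


@pytest.mark.parametrize("position", [0, 97, -1])
def test_out_of_range_positions(position):
    with pytest.raises(InvalidPositionError):
        position_to_well_label(position, F96)


def test_coordinate_bijection_exhaustive():
    """label -> position -> label is the identity on every cell of every
    shipped plate geometry (96 + 384 + 48 + 72 + 100 = 700 cells)."""
    cells = 0
    for fmt in PLATE_TYPE_MAP.values():
        for position in range(1, fmt.size + 1):
            label = position_to_well_label(position, fmt)
            assert well_label_to_position(label, fmt) == position
            cells += 1
    assert cells == sum(f.size for f in PLATE_TYPE_MAP.values()) == 700


def test_deep_plate_row_letters():
    """Rotor formats have more than 26 rows: letters roll over to AA, AB..."""
    rotor = PLATE_TYPE_MAP["rotor-100"]
    assert position_to_well_label(27, rotor) == "AA1"
    assert well_label_to_position("AA1", rotor) == 27


# ---------------------------------------------------------------------------
# plate-type map

@pytest.mark.parametrize("token,rows,cols", [
    ("96-well", 8, 12), ("384-well", 16, 24), ("48-well", 6, 8),
    ("rotor-72", 72, 1), ("rotor-100", 100, 1),
])
def test_plate_type_geometries(token, rows, cols):
    fmt = plate_type_to_format(token)
    assert (fmt.rows, fmt.columns) == (rows, cols)
    assert format_to_plate_type(fmt) == token


def test_unknown_plate_type_carries_token():
    with pytest.raises(UnknownPlateTypeError) as exc:
        plate_type_to_format("hexagonal-7")
    assert exc.value.token == "hexagonal-7"


def test_custom_plate_map_overrides():
    fmt = plate_type_to_format("hexagonal-7",
                               {"hexagonal-7": PcrFormat(rows=1, columns=7)})
    assert (fmt.rows, fmt.columns) == (1, 7)


# ---------------------------------------------------------------------------
# migration

def test_upgrade_1_0_to_1_2_takes_two_steps(doc10):
    out, report = migrate(doc10, "1.2")
    assert out.version == "1.2"
    assert report.steps == [("1.0", "1.1"), ("1.1", "1.2")]
    assert doc10.version == "1.0"  # source untouched


def test_chained_upgrade_intermediates_validate(doc10):
    mid, _ = migrate(doc10, "1.1")
    assert mid.version == "1.1" and not validate(mid).errors
    top, _ = migrate(mid, "1.2")
    assert top.version == "1.2" and not validate(top).errors


def test_noop_migration_is_empty(doc11):
    out, report = migrate(doc11, "1.1")
    assert semantic_equal(out, doc11)
    assert report.actions == [] and report.steps == []


def test_well_label_read_and_upgrade_composition():
    """A 1.0 file with a reaction in well B1 of a 96-well plate acquires
    numeric position 13 and an 8x12 format after upgrade."""
    xml = (b'<rdml version="1.0">'
           b'<sample id="s1"><type>unkn</type></sample>'
           b'<target id="t1"><type>toi</type></target>'
           b'<experiment id="e1"><run id="r1"><plateType>96-well</plateType>'
           b'<react well="B1"><sample id="s1"/>'
           b'<data><tar id="t1"/><cq>21.5</cq></data></react>'
           b'</run></experiment></rdml>')
    doc, _ = read_rdml(xml)
    assert doc.experiments[0].runs[0].reactions[0].position == 13
    out, report = migrate(doc, "1.1")
    run = out.experiments[0].runs[0]
    assert run.pcrFormat.rows == 8 and run.pcrFormat.columns == 12
    assert run.plateType is None
    assert run.reactions[0].position == 13
    # the dye-less target received a synthesized, registered dye
    assert out.targets[0].dyeRef is not None
    assert any(d.id == out.targets[0].dyeRef for d in out.dyes)
    assert any(a.kind == "synthesized" for a in report.actions)
    assert not validate(out).errors


def test_downgrade_drops_each_annotation(clean12):
    clean12.samples[0].annotations = [
        Annotation("tissue", "liver"),
        Annotation("treatment", "control"),
        Annotation("batch", "2"),
    ]
    for s in clean12.samples[1:]:
        s.annotations = []
    out, report = migrate(clean12, "1.1")
    dropped = report.dropped()
    assert len(dropped) == 3
    assert all("annotation" in a.path for a in dropped)
    assert all(not s.annotations for s in out.samples)


def test_representable_round_trip_1_1(doc11):
    up, _ = migrate(doc11, "1.2")
    down, report = migrate(up, "1.1")
    assert report.dropped() == []
    assert semantic_equal(down, doc11)


def test_representable_round_trip_1_0(doc10):
    up, _ = migrate(doc10, "1.1")
    down, report = migrate(up, "1.0")
    assert report.dropped() == []
    assert semantic_equal(down, doc10)


def test_quality_record_becomes_annotation_and_back(doc11):
    src = copy.deepcopy(doc11)
    src.samples[0].legacyQuality = LegacyQuality(
        material="rna", method="gel", result=1.8)
    up, report = migrate(src, "1.2")
    ann = up.samples[0].annotations
    assert any(a.property == "rna quality" and "gel" in a.value for a in ann)
    assert up.samples[0].legacyQuality is None
    assert not validate(up).errors
    down, down_report = migrate(up, "1.1")
    assert down_report.dropped() == []
    assert semantic_equal(down, src)


def test_efficiency_se_dropped_on_downgrade(clean12):
    clean12.targets[0].amplificationEfficiency = 1.92
    clean12.targets[0].amplificationEfficiencySE = 0.04
    out, report = migrate(clean12, "1.0")
    assert out.targets[0].amplificationEfficiencySE is None
    assert out.targets[0].amplificationEfficiency == 1.92
    assert any("amplificationEfficiencySE" in a.path
               for a in report.dropped())


def test_ambiguous_quantity_material_downgrade(clean12):
    clean12.samples[0].material = None
    out, report = migrate(clean12, "1.1")
    assert out.samples[0].material == "dna"
    assert any(a.kind == "transformed" and "ambiguous" in a.detail
               for a in report.actions)


def test_downgrade_to_1_0_restores_plate_type(doc11):
    out, _ = migrate(doc11, "1.0")
    run = out.experiments[0].runs[0]
    assert run.plateType == "96-well"
    assert not validate(out).errors


def test_migrated_fixture_round_trips_through_file(doc10):
    from rdmlkit import read_rdml, write_rdml_bytes

    out, _ = migrate(doc10, "1.2")
    back, _ = read_rdml(write_rdml_bytes(out))
    assert semantic_equal(out, back)
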