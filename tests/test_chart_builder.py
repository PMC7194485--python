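"""Pie/donut construction: angles, ring order, transposition, emission."""

from fractions import Fraction

import pytest
from hypothesis import given, strategies as st

from omicsviz import (
    ChartSpec,
    ContinuousMapping,
    Slice,
    VizConfig,
    apply_filter,
    build_charts,
    build_donut,
    build_pie,
    emit_chart_columns,
    emit_chart_string,
    parse_chart_string,
    parse_discrete_mapping,
    parse_filter,
)
from omicsviz.chart_builder import RING_IS_ROW, ChartParseError, viz_config_from_dict, viz_config_to_dict
from omicsviz.network_link import NAMESPACE
from omicsviz.table_io import SchemaError

CONT = ContinuousMapping(-8, 0, 8, "#2166AC", "#F7F7F7", "#B2182B")
DISC = parse_discrete_mapping("A:#1F78B4,B:#FF7F00,C:#E31A1C")


def _pie_config(**kw):
    base = dict(style="pie", value_columns=["Cluster"], mapping=DISC,
                label_column="AA position")
    base.update(kw)
    return VizConfig(**base)


def _donut_config(**kw):
    base = dict(style="donut", value_columns=["EOC vs FTE", "EOC vs OSE"],
                mapping=CONT, label_column="AA position")
    base.update(kw)
    return VizConfig(**base)


def test_pie_needs_exactly_one_value_column():
    with pytest.raises(ValueError):
        VizConfig(style="pie", value_columns=["a", "b"], mapping=DISC)
    with pytest.raises(ValueError):
        VizConfig(style="donut", value_columns=[], mapping=DISC)


def test_pie_partitions_the_circle_equally(demo_connection):
    chart = build_pie("9606.P20700", demo_connection, _pie_config())
    [ring] = chart.rings
    assert [(s.start_deg, s.end_deg) for s in ring] == [
        (Fraction(0), Fraction(180)), (Fraction(180), Fraction(360))
    ]
    assert [s.value for s in ring] == ["C", "C"]
    assert [s.label for s in ring] == ["393", "23"]
    assert [s.color for s in ring] == ["#E31A1C", "#E31A1C"]


def test_arcstart_offsets_the_first_slice_boundary(demo_connection):
    chart = build_pie("9606.P20700", demo_connection, _pie_config(arc_start_deg=90.0))
    assert chart.rings[0][0].start_deg == Fraction(90)
    assert chart.rings[0][-1].end_deg == Fraction(450)


def test_node_without_rows_gets_no_chart(demo_pair, demo_connection):
    table, network = demo_pair
    network.nodes.append(type(network.nodes[0])(id="orphan", attributes={}))
    demo_connection.rows_per_node["orphan"] = []
    assert build_pie("orphan", demo_connection, _pie_config()) is None


def test_missing_value_column_is_a_schema_error(demo_connection):
    with pytest.raises(SchemaError):
        build_pie("9606.P20700", demo_connection, _pie_config(value_columns=["nope"]))


def test_donut_ring_order_first_listed_innermost(demo_connection):
    chart = build_donut("9606.P20700", demo_connection, _donut_config())
    assert len(chart.rings) == 2
    inner, outer = chart.rings
    # inner ring carries the first listed column's values
    assert [s.value for s in inner] == [1.8, 0.9]   # EOC vs FTE
    assert [s.value for s in outer] == [2.4, 1.1]   # EOC vs OSE
    assert all(len(r) == 2 for r in chart.rings)


def test_ring_is_row_is_the_transpose(demo_connection):
    by_col = build_donut("9606.P20700", demo_connection, _donut_config())
    by_row = build_donut("9606.P20700", demo_connection,
                         _donut_config(ring_mode=RING_IS_ROW))
    cols = [[(s.value, s.color, s.label) for s in ring] for ring in by_col.rings]
    rows = [[(s.value, s.color, s.label) for s in ring] for ring in by_row.rings]
    assert rows == [list(t) for t in zip(*cols)]


def test_single_column_donut_matches_pie_slices(demo_connection):
    """Oracle: both builders must agree on the slice tuples."""
    donut = build_donut(
        "9606.P20700", demo_connection,
        _donut_config(value_columns=["EOC vs FTE"]),
    )
    pie = build_pie(
        "9606.P20700", demo_connection,
        _pie_config(value_columns=["EOC vs FTE"], mapping=CONT),
    )
    assert donut.rings == pie.rings


def test_filtered_only_controls_slice_count(demo_pair, demo_connection):
    table, _ = demo_pair
    apply_filter(table, parse_filter("(AA position,LOWER,100)"))
    full = build_pie("9606.P20700", demo_connection, _pie_config())
    vis = build_pie("9606.P20700", demo_connection, _pie_config(filtered_only=True))
    assert len(full.rings[0]) == 2
    assert len(vis.rings[0]) == 1
    assert vis.rings[0][0].label == "23"


def test_null_cell_keeps_its_angular_span(demo_pair):
    from omicsviz import Network, NodeRecord, OVTable, connect

    table = OVTable("t", [("k", "string"), ("v", "float")],
                    [("a", 1.0), ("a", None), ("a", -1.0)])
    net = Network("n", nodes=[NodeRecord("a", {"key": "a"})])
    conn = connect(table, net, "key", "k")
    chart = build_pie("a", conn, VizConfig(style="pie", value_columns=["v"],
                                           mapping=CONT))
    [ring] = chart.rings
    assert len(ring) == 3
    assert ring[1].color == CONT.missing_color
    assert ring[1].end_deg - ring[1].start_deg == Fraction(120)


# angle conservation --------------------------------------------------------


@given(st.integers(1, 60), st.floats(-360, 360))
def test_ring_angles_sum_to_exactly_360(k, arc_start):
    from omicsviz.chart_builder import _slice_angles

    angles = _slice_angles(k, arc_start)
    assert sum(a1 - a0 for a0, a1 in angles) == 360
    # contiguous partition starting at arc_start
    assert angles[0][0] == Fraction(arc_start)
    for (_, e), (s, _) in zip(angles, angles[1:]):
        assert e == s


# chart-string round trip ---------------------------------------------------


def test_chart_string_round_trip_demo(demo_connection):
    for config in (_pie_config(), _donut_config(label_size=15.0)):
        charts = build_charts(demo_connection, config)
        for chart in charts.values():
            text = emit_chart_string(chart)
            assert parse_chart_string(text) == chart
            # determinism: identical inputs, byte-identical strings
            assert emit_chart_string(chart) == text


_values = st.one_of(
    st.none(), st.integers(-100, 100), st.floats(-50, 50),
    st.booleans(), st.text(max_size=8),
)
_labels = st.one_of(st.none(), st.text(max_size=8))
_colors = st.integers(0, 0xFFFFFF).map(lambda v: f"#{v:06X}")


@st.composite
def chart_specs(draw):
    style = draw(st.sampled_from(["pie", "donut"]))
    arc_start = draw(st.floats(-180, 180))
    n_rings = 1 if style == "pie" else draw(st.integers(1, 3))
    k = draw(st.integers(1, 5))
    from omicsviz.chart_builder import _slice_angles

    angles = _slice_angles(k, arc_start)
    rings = [
        [Slice(a0, a1, draw(_colors), draw(_labels), draw(_values))
         for a0, a1 in angles]
        for _ in range(n_rings)
    ]
    return ChartSpec(draw(st.text(min_size=1, max_size=10)), style, rings,
                     arc_start, draw(st.one_of(st.none(), st.floats(5, 30))))


@given(chart_specs())
def test_chart_string_round_trip_property(chart):
    assert parse_chart_string(emit_chart_string(chart)) == chart


@pytest.mark.parametrize("text", ["", "nonsense", "ovchart:pie|node=a"])
def test_malformed_chart_strings_raise(text):
    with pytest.raises(ChartParseError):
        parse_chart_string(text)


# bookkeeping columns -------------------------------------------------------


def test_emit_creates_one_value_column_per_ring(demo_connection):
    network = demo_connection.network
    config = _donut_config()
    charts = build_charts(demo_connection, config)
    record = emit_chart_columns(demo_connection, config, charts)
    assert len(record["value_columns"]) == 2
    node = network.node("9606.P20700")
    assert record["chart_column"].startswith(f"{NAMESPACE}::donut")
    assert node.attributes[record["value_columns"][0]] == [1.8, 0.9]
    assert f"{NAMESPACE}::donut viz" in network.attributes


def test_emit_pie_creates_exactly_one_value_column(demo_connection):
    config = _pie_config()
    charts = build_charts(demo_connection, config)
    record = emit_chart_columns(demo_connection, config, charts)
    assert len(record["value_columns"]) == 1
    node = demo_connection.network.node("9606.P20700")
    assert node.attributes[record["value_columns"][0]] == ["C", "C"]


def test_emit_centers_continuous_values(demo_connection):
    shifted_mapping = ContinuousMapping(-6, 2, 10, "#2166AC", "#F7F7F7", "#B2182B")
    config = _donut_config(mapping=shifted_mapping)
    charts = build_charts(demo_connection, config)
    record = emit_chart_columns(demo_connection, config, charts)
    node = demo_connection.network.node("9606.P20700")
    # node columns hold centered values; the source table is untouched
    assert node.attributes[record["value_columns"][0]] == [1.8 - 2, 0.9 - 2]
    assert demo_connection.table.rows[0][2] == 1.8


def test_reapplying_overwrites_instead_of_duplicating(demo_connection):
    network = demo_connection.network
    cfg2 = _donut_config()
    charts = build_charts(demo_connection, cfg2)
    emit_chart_columns(demo_connection, cfg2, charts)
    cfg1 = _donut_config(value_columns=["EOC vs FTE"])
    charts1 = build_charts(demo_connection, cfg1)
    emit_chart_columns(demo_connection, cfg1, charts1)
    node = network.node("9606.P20700")
    donut_cols = [k for k in node.attributes if k.startswith(f"{NAMESPACE}::donut")]
    assert len(donut_cols) == 2  # 1 chart string + 1 ring, old ring 2 removed


def test_viz_config_dict_round_trip():
    for config in (_pie_config(), _donut_config(ring_mode=RING_IS_ROW,
                                                arc_start_deg=45.0, label_size=15.0)):
        data = viz_config_to_dict(config)
        again = viz_config_from_dict(data)
        assert viz_config_to_dict(again) == data
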