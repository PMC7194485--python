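"""Build per-node pie and donut glyphs from connected table rows.

A *pie* is drawn inside the node: one ring, one slice per connected row of
a single value column.  A *donut* is drawn around the node as concentric
rings.  In the default "ring is column" orientation there is one ring per
value column — the first listed column innermost — and one slice per
connected row; "ring is row" transposes this (one ring per row, one slice
per column).

Slices within a ring partition the full circle into equal angular spans
starting at ``arc_start_deg`` (0 = 3 o'clock) and increasing clockwise.
Angles are kept as exact rationals so each ring's spans always sum to 360
degrees.

Besides the in-memory :class:`ChartSpec`, the builder emits a declarative
chart string per node (a documented key:value microformat in the spirit of
the enhancedGraphics "Custom Chart" strings) plus bookkeeping attributes:
one value-list column for a pie, one per ring for a donut — with values
centered on the middle anchor for continuous mappings — and a
network-level record of the visualization settings.
"""

from __future__ import annotations

import json
import urllib.parse
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple

from .color_mapping import (
    ContinuousMapping,
    DiscreteMapping,
    center_transform,
    continuous_color,
)
from .network_link import NAMESPACE, Connection

__all__ = [
    "VizConfig",
    "Slice",
    "ChartSpec",
    "ChartParseError",
    "build_pie",
    "build_donut",
    "build_charts",
    "emit_chart_string",
    "parse_chart_string",
    "emit_chart_columns",
    "viz_config_to_dict",
    "viz_config_from_dict",
]

RING_IS_COLUMN = "ring_is_column"
RING_IS_ROW = "ring_is_row"


class ChartParseError(ValueError):
    pass


@dataclass
class VizConfig:
    """Settings of one visualization (pie or donut) on a connection."""

    style: str  # "pie" | "donut"
    value_columns: Sequence[str]
    mapping: object  # ContinuousMapping | DiscreteMapping
    label_column: Optional[str] = None
    filtered_only: bool = False
    ring_mode: str = RING_IS_COLUMN  # donut only
    arc_start_deg: float = 0.0
    label_size: Optional[float] = None

    def __post_init__(self):
        if self.style not in ("pie", "donut"):
            raise ValueError(f"unknown style {self.style!r}")
        self.value_columns = list(self.value_columns)
        if not self.value_columns:
            raise ValueError("at least one value column is required")
        if self.style == "pie" and len(self.value_columns) != 1:
            raise ValueError("a pie uses exactly one value column")
        if self.ring_mode not in (RING_IS_COLUMN, RING_IS_ROW):
            raise ValueError(f"unknown ring mode {self.ring_mode!r}")

    def validate_against(self, connection: Connection) -> None:
        for col in self.value_columns:
            connection.table.column_index(col)  # SchemaError when absent
        if self.label_column is not None:
            connection.table.column_index(self.label_column)


@dataclass(frozen=True)
class Slice:
    start_deg: Fraction
    end_deg: Fraction
    color: str
    label: Optional[str]
    value: object


@dataclass
class ChartSpec:
    """One node's glyph: ordered rings (innermost first) of slices."""

    node_id: str
    style: str
    rings: List[List[Slice]]
    arc_start_deg: float = 0.0
    label_size: Optional[float] = None


def _slice_angles(k: int, arc_start_deg: float) -> List[Tuple[Fraction, Fraction]]:
    start = Fraction(arc_start_deg)
    bounds = [start + Fraction(360 * i, k) for i in range(k + 1)]
    return list(zip(bounds[:-1], bounds[1:]))


def _color_of(value, mapping) -> str:
    if isinstance(mapping, ContinuousMapping):
        return continuous_color(value, mapping)
    if isinstance(mapping, DiscreteMapping):
        return mapping.color_for(value)
    raise TypeError(f"unsupported mapping type {type(mapping).__name__}")


def _label_text(value) -> Optional[str]:
    if value is None:
        return None
    if value is True:
        return "true"
    if value is False:
        return "false"
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value)


def build_pie(node_id: str, connection: Connection, config: VizConfig) -> Optional[ChartSpec]:
    """One ring inside the node, one slice per connected row, table order.

    Returns None (node left undecorated) when the node has no connected
    rows under the configured filtering.
    """
    if config.style != "pie":
        raise ValueError("build_pie requires a pie-style config")
    config.validate_against(connection)
    rows = connection.rows_for(node_id, filtered_only=config.filtered_only)
    if not rows:
        return None
    table = connection.table
    value_col = config.value_columns[0]
    angles = _slice_angles(len(rows), config.arc_start_deg)
    slices = []
    for (a0, a1), r in zip(angles, rows):
        value = table.cell(r, value_col)
        label = (
            _label_text(table.cell(r, config.label_column))
            if config.label_column
            else None
        )
        slices.append(Slice(a0, a1, _color_of(value, config.mapping), label, value))
    return ChartSpec(node_id, "pie", [slices], config.arc_start_deg, config.label_size)


def build_donut(node_id: str, connection: Connection, config: VizConfig) -> Optional[ChartSpec]:
    """Concentric rings around the node; see module docstring for orientation.

    ``ring_is_column``: ring r = value column r (first listed innermost),
    slice i = connected row i.  ``ring_is_row`` transposes: ring r = row r,
    slice i = value column i.  Slice labels come from the row's label cell
    either way.
    """
    if config.style != "donut":
        raise ValueError("build_donut requires a donut-style config")
    config.validate_against(connection)
    rows = connection.rows_for(node_id, filtered_only=config.filtered_only)
    if not rows:
        return None
    table = connection.table

    def label_of(row_index: int) -> Optional[str]:
        if config.label_column is None:
            return None
        return _label_text(table.cell(row_index, config.label_column))

    rings: List[List[Slice]] = []
    if config.ring_mode == RING_IS_COLUMN:
        angles = _slice_angles(len(rows), config.arc_start_deg)
        for col in config.value_columns:
            ring = []
            for (a0, a1), r in zip(angles, rows):
                value = table.cell(r, col)
                ring.append(
                    Slice(a0, a1, _color_of(value, config.mapping), label_of(r), value)
                )
            rings.append(ring)
    else:
        angles = _slice_angles(len(config.value_columns), config.arc_start_deg)
        for r in rows:
            ring = [
                Slice(a0, a1, _color_of(table.cell(r, col), config.mapping),
                      label_of(r), table.cell(r, col))
                for (a0, a1), col in zip(angles, config.value_columns)
            ]
            rings.append(ring)
    return ChartSpec(node_id, "donut", rings, config.arc_start_deg, config.label_size)


def build_charts(connection: Connection, config: VizConfig) -> Dict[str, ChartSpec]:
    """Build a chart for every node that has connected rows."""
    builder = build_pie if config.style == "pie" else build_donut
    charts = {}
    for node in connection.network.nodes:
        chart = builder(node.id, connection, config)
        if chart is not None:
            charts[node.id] = chart
    return charts


# ---------------------------------------------------------------------------
# chart-string microformat
# ---------------------------------------------------------------------------
# ovchart:<style>|node=<id>|arcstart=<float>|labelsize=<float or empty>|
#     ring=<slice>;<slice>;...|ring=...
# slice  := <color>,<label>,<value>
# label  := empty for no label, else "t" + percent-encoded text
# value  := n (null) | i<int> | f<float repr> | b0 | b1 | s<percent-encoded>
# Angles are not stored: they are fully determined by the slice count and
# arcstart, and are recomputed on parse.


def _encode_value(value) -> str:
    if value is None:
        return "n"
    if value is True:
        return "b1"
    if value is False:
        return "b0"
    if isinstance(value, int):
        return f"i{value}"
    if isinstance(value, float):
        return f"f{value!r}"
    return "s" + urllib.parse.quote(str(value), safe="")


def _decode_value(text: str):
    if text == "n":
        return None
    tag, rest = text[0], text[1:]
    if tag == "b":
        return rest == "1"
    if tag == "i":
        return int(rest)
    if tag == "f":
        return float(rest)
    if tag == "s":
        return urllib.parse.unquote(rest)
    raise ChartParseError(f"bad value token {text!r}")


def _encode_label(label: Optional[str]) -> str:
    return "" if label is None else "t" + urllib.parse.quote(label, safe="")


def emit_chart_string(chart: ChartSpec) -> str:
    """Serialize a chart to its declarative one-line description string."""
    parts = [
        f"ovchart:{chart.style}",
        "node=" + urllib.parse.quote(chart.node_id, safe=""),
        f"arcstart={chart.arc_start_deg!r}",
        "labelsize=" + ("" if chart.label_size is None else repr(chart.label_size)),
    ]
    for ring in chart.rings:
        slices = ";".join(
            f"{s.color},{_encode_label(s.label)},{_encode_value(s.value)}"
            for s in ring
        )
        parts.append("ring=" + slices)
    return "|".join(parts)


def parse_chart_string(text: str) -> ChartSpec:
    """Parse an emitted chart string back into an equal :class:`ChartSpec`."""
    if not text or not text.startswith("ovchart:"):
        raise ChartParseError("not a chart string (missing 'ovchart:' prefix)")
    fields = text.split("|")
    style = fields[0][len("ovchart:"):]
    if style not in ("pie", "donut"):
        raise ChartParseError(f"unknown chart style {style!r}")
    node_id = None
    arc_start = None
    label_size: Optional[float] = None
    raw_rings: List[str] = []
    for fld in fields[1:]:
        key, sep, val = fld.partition("=")
        if not sep:
            raise ChartParseError(f"malformed field {fld!r}")
        if key == "node":
            node_id = urllib.parse.unquote(val)
        elif key == "arcstart":
            arc_start = float(val)
        elif key == "labelsize":
            label_size = float(val) if val else None
        elif key == "ring":
            raw_rings.append(val)
        else:
            raise ChartParseError(f"unknown field {key!r}")
    if node_id is None or arc_start is None or not raw_rings:
        raise ChartParseError("chart string missing node, arcstart or rings")
    rings = []
    for raw in raw_rings:
        tokens = raw.split(";") if raw else []
        if not tokens:
            raise ChartParseError("empty ring")
        angles = _slice_angles(len(tokens), arc_start)
        ring = []
        for (a0, a1), token in zip(angles, tokens):
            try:
                color, label, value = token.split(",")
            except ValueError:
                raise ChartParseError(f"malformed slice {token!r}") from None
            ring.append(
                Slice(a0, a1, color, urllib.parse.unquote(label[1:]) if label else None,
                      _decode_value(value))
            )
        rings.append(ring)
    return ChartSpec(node_id, style, rings, arc_start, label_size)


# ---------------------------------------------------------------------------
# bookkeeping columns
# ---------------------------------------------------------------------------


def _style_prefix(style: str) -> str:
    return f"{NAMESPACE}::{style}"


def emit_chart_columns(
    connection: Connection, config: VizConfig, charts: Dict[str, ChartSpec]
) -> dict:
    """Write chart strings and value lists into the node attribute table.

    Creates, under the package namespace: one chart-string attribute per
    node; one value-list attribute for a pie or one per ring for a donut
    (continuous values centered on the middle anchor, as the downstream
    zero-anchored renderer expects); and a network-level record of the
    visualization settings.  Re-application overwrites the namespace
    columns rather than duplicating them.
    """
    network = connection.network
    prefix = _style_prefix(config.style)
    # overwrite semantics: clear every column of this style first
    for node in network.nodes:
        for key in [k for k in node.attributes if k.startswith(prefix)]:
            del node.attributes[key]
    for key in [k for k in network.attributes if k.startswith(prefix)]:
        del network.attributes[key]

    n_rings = max((len(c.rings) for c in charts.values()), default=0)
    chart_col = f"{prefix} chart"
    if config.style == "pie":
        value_cols = [f"{prefix} values"]
    else:
        value_cols = [f"{prefix} values ring {i + 1}" for i in range(n_rings)]

    continuous = isinstance(config.mapping, ContinuousMapping)
    for node in network.nodes:
        chart = charts.get(node.id)
        if chart is None:
            continue
        node.attributes[chart_col] = emit_chart_string(chart)
        for i, ring in enumerate(chart.rings):
            values = [s.value for s in ring]
            if continuous:
                values, _, _ = center_transform(values, config.mapping)
            node.attributes[value_cols[i]] = values

    network.attributes[f"{prefix} viz"] = json.dumps(
        viz_config_to_dict(config), sort_keys=True
    )
    return {"chart_column": chart_col, "value_columns": value_cols}


# ---------------------------------------------------------------------------
# config (de)serialization — shared by session persistence
# ---------------------------------------------------------------------------


def _mapping_to_dict(mapping) -> dict:
    if isinstance(mapping, ContinuousMapping):
        return {
            "kind": "continuous",
            "min_value": mapping.min_value,
            "mid_value": mapping.mid_value,
            "max_value": mapping.max_value,
            "min_color": mapping.min_color,
            "mid_color": mapping.mid_color,
            "max_color": mapping.max_color,
            "palette_name": mapping.palette_name,
            "missing_color": mapping.missing_color,
        }
    if isinstance(mapping, DiscreteMapping):
        return {
            "kind": "discrete",
            "assignments": list(mapping.assignments.items()),
            "palette_name": mapping.palette_name,
            "missing_color": mapping.missing_color,
        }
    raise TypeError(f"unsupported mapping type {type(mapping).__name__}")


def _mapping_from_dict(data: dict):
    if data["kind"] == "continuous":
        return ContinuousMapping(
            min_value=data["min_value"], mid_value=data["mid_value"],
            max_value=data["max_value"], min_color=data["min_color"],
            mid_color=data["mid_color"], max_color=data["max_color"],
            palette_name=data.get("palette_name"),
            missing_color=data.get("missing_color", "#CCCCCC"),
        )
    if data["kind"] == "discrete":
        return DiscreteMapping(
            assignments=dict(tuple(pair) for pair in data["assignments"]),
            palette_name=data.get("palette_name"),
            missing_color=data.get("missing_color", "#CCCCCC"),
        )
    raise ValueError(f"unknown mapping kind {data['kind']!r}")


def viz_config_to_dict(config: VizConfig) -> dict:
    return {
        "style": config.style,
        "value_columns": list(config.value_columns),
        "mapping": _mapping_to_dict(config.mapping),
        "label_column": config.label_column,
        "filtered_only": config.filtered_only,
        "ring_mode": config.ring_mode,
        "arc_start_deg": config.arc_start_deg,
        "label_size": config.label_size,
    }


def viz_config_from_dict(data: dict) -> VizConfig:
    return VizConfig(
        style=data["style"],
        value_columns=data["value_columns"],
        mapping=_mapping_from_dict(data["mapping"]),
        label_column=data.get("label_column"),
        filtered_only=data.get("filtered_only", False),
        ring_mode=data.get("ring_mode", RING_IS_COLUMN),
        arc_start_deg=data.get("arc_start_deg", 0.0),
        label_size=data.get("label_size"),
    )
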