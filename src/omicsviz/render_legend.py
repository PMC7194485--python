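"""Render decorated networks to SVG and build grouped legend annotations.

The legend is assembled from separate primitives — text lines, color
swatches, a gradient bar, a ring-order list — all carried under one
reserved group name so the whole legend can be moved or deleted as a unit.
A discrete mapping yields one swatch + label per value; a continuous
mapping yields a gradient bar ticked with the minimum, middle and maximum
anchor values verbatim (4-significant-digit formatting); a donut adds the
ordered list of its value columns, innermost first.

Rendering is deliberately plain SVG 1.1: edges as lines, nodes as circles,
pie wedges inside the node, donut annuli around it, one ``<path
class="slice">`` per chart slice.  Output is deterministic — fixed float
formatting and a seeded force-directed layout — so repeated renders of the
same state are byte-identical.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import networkx as nx

from .chart_builder import ChartSpec, VizConfig
from .color_mapping import ContinuousMapping, DiscreteMapping
from .network_link import Network

__all__ = [
    "LEGEND_GROUP_NAME",
    "LEGEND_POSITIONS",
    "LegendSpec",
    "LayoutError",
    "build_legend",
    "render_svg",
    "legend_to_svg",
]

#: Reserved annotation-group identifier distinguishing legend primitives
#: from any other annotation; renaming it orphans the legend.
LEGEND_GROUP_NAME = "OmicsVisualizerLegend"

LEGEND_POSITIONS = (
    "EAST_TOP", "EAST", "EAST_BOTTOM",
    "WEST_TOP", "WEST", "WEST_BOTTOM",
    "NORTH", "SOUTH",
)

# fixed legend geometry (swatch size, line leading, gradient bar size)
_SWATCH = 12.0
_LEADING = 18.0
_BAR_W = 140.0
_BAR_H = 12.0
_PAD = 10.0

_CANVAS_W = 800.0
_CANVAS_H = 600.0
_MARGIN = 80.0
_NODE_RADIUS = 18.0
_RING_GAP = 3.0
_RING_WIDTH = 8.0


class LayoutError(RuntimeError):
    """A node has no position and no automatic layout was requested."""


# legend primitives ---------------------------------------------------------


@dataclass(frozen=True)
class TextElement:
    text: str
    x: float
    y: float
    size: float
    bold: bool = False


@dataclass(frozen=True)
class ColorBoxElement:
    x: float
    y: float
    width: float
    height: float
    color: str


@dataclass(frozen=True)
class GradientBarElement:
    x: float
    y: float
    width: float
    height: float
    min_value: float
    mid_value: float
    max_value: float
    min_color: str
    mid_color: str
    max_color: str


@dataclass(frozen=True)
class RingOrderListElement:
    """Ordered donut column names, innermost first."""

    names: Tuple[str, ...]
    x: float
    y: float
    size: float


@dataclass
class LegendSpec:
    elements: list
    title: str
    font: str
    font_size: float
    position: str
    group_name: str = LEGEND_GROUP_NAME
    width: float = 0.0
    height: float = 0.0


def _fmt_value(v: float) -> str:
    return f"{v:.4g}"


def build_legend(
    configs: Sequence[VizConfig],
    title: str = "",
    font: str = "sans-serif",
    font_size: float = 12.0,
    position: str = "EAST_TOP",
) -> LegendSpec:
    """Assemble legend primitives for the active visualizations.

    Each visualization contributes a header naming its value column(s),
    then either swatches (discrete) or a min/mid/max-ticked gradient bar
    (continuous); donuts additionally contribute the ring-order column
    list.  All primitives share one reserved group.
    """
    if not configs:
        raise ValueError("no active visualization to build a legend from")
    if position not in LEGEND_POSITIONS:
        raise ValueError(f"unknown legend position {position!r}")

    elements: list = []
    y = 0.0
    width = _BAR_W + 2 * _PAD
    if title:
        y += font_size + 4
        elements.append(TextElement(title, _PAD, y, font_size * 1.2, bold=True))
        y += 8
    for config in configs:
        header = ", ".join(config.value_columns)
        y += _LEADING
        elements.append(TextElement(header, _PAD, y, font_size, bold=True))
        mapping = config.mapping
        if isinstance(mapping, DiscreteMapping):
            for value, color in mapping.assignments.items():
                y += _LEADING
                elements.append(
                    ColorBoxElement(_PAD, y - _SWATCH, _SWATCH, _SWATCH, color)
                )
                elements.append(
                    TextElement(str(value), _PAD + _SWATCH + 6, y - 1, font_size)
                )
        elif isinstance(mapping, ContinuousMapping):
            y += 8
            elements.append(
                GradientBarElement(
                    _PAD, y, _BAR_W, _BAR_H,
                    mapping.min_value, mapping.mid_value, mapping.max_value,
                    mapping.min_color, mapping.mid_color, mapping.max_color,
                )
            )
            y += _BAR_H + font_size + 2
            elements.append(TextElement(_fmt_value(mapping.min_value), _PAD, y, font_size * 0.9))
            span = mapping.max_value - mapping.min_value
            frac = 0.5 if span == 0 else (mapping.mid_value - mapping.min_value) / span
            elements.append(
                TextElement(_fmt_value(mapping.mid_value), _PAD + _BAR_W * frac, y, font_size * 0.9)
            )
            elements.append(
                TextElement(_fmt_value(mapping.max_value), _PAD + _BAR_W, y, font_size * 0.9)
            )
        else:
            raise TypeError(f"unsupported mapping type {type(mapping).__name__}")
        if config.style == "donut" and len(config.value_columns) > 1:
            y += _LEADING
            elements.append(TextElement("Ring order (innermost first):", _PAD, y, font_size * 0.9))
            elements.append(
                RingOrderListElement(tuple(config.value_columns), _PAD + 8, y, font_size * 0.9)
            )
            y += _LEADING * len(config.value_columns)
        y += 6
    return LegendSpec(
        elements=elements, title=title, font=font, font_size=font_size,
        position=position, width=width, height=y + _PAD,
    )


# SVG rendering -------------------------------------------------------------


def _f(v: float) -> str:
    return f"{v:.2f}"


def _node_positions(network: Network, layout, seed: int) -> Dict[str, Tuple[float, float]]:
    if layout is not None:
        missing = [n.id for n in network.nodes if n.id not in layout]
        if missing:
            raise LayoutError(f"no position for nodes: {missing}")
        raw = {n.id: layout[n.id] for n in network.nodes}
    elif all(n.position is not None for n in network.nodes) and network.nodes:
        raw = {n.id: n.position for n in network.nodes}
    else:
        g = network.to_networkx()
        raw = nx.spring_layout(g, seed=seed) if g.number_of_nodes() else {}
    if not raw:
        return {}
    xs = [p[0] for p in raw.values()]
    ys = [p[1] for p in raw.values()]
    span_x = (max(xs) - min(xs)) or 1.0
    span_y = (max(ys) - min(ys)) or 1.0
    scaled = {}
    for nid, (x, y) in raw.items():
        scaled[nid] = (
            _MARGIN + (x - min(xs)) / span_x * (_CANVAS_W - 2 * _MARGIN),
            _MARGIN + (y - min(ys)) / span_y * (_CANVAS_H - 2 * _MARGIN),
        )
    return scaled


def _polar(cx: float, cy: float, r: float, deg: float) -> Tuple[float, float]:
    # 0 deg = 3 o'clock; SVG's downward y-axis makes increasing angles clockwise
    rad = math.radians(deg)
    return cx + r * math.cos(rad), cy + r * math.sin(rad)


def _wedge_path(cx, cy, r, a0: float, a1: float) -> str:
    span = a1 - a0
    if span >= 360:
        # full disc as two half arcs
        p0 = _polar(cx, cy, r, a0)
        p1 = _polar(cx, cy, r, a0 + 180)
        return (
            f"M {_f(p0[0])} {_f(p0[1])} "
            f"A {_f(r)} {_f(r)} 0 1 1 {_f(p1[0])} {_f(p1[1])} "
            f"A {_f(r)} {_f(r)} 0 1 1 {_f(p0[0])} {_f(p0[1])} Z"
        )
    p0 = _polar(cx, cy, r, a0)
    p1 = _polar(cx, cy, r, a1)
    large = 1 if span > 180 else 0
    return (
        f"M {_f(cx)} {_f(cy)} L {_f(p0[0])} {_f(p0[1])} "
        f"A {_f(r)} {_f(r)} 0 {large} 1 {_f(p1[0])} {_f(p1[1])} Z"
    )


def _annulus_path(cx, cy, r_in, r_out, a0: float, a1: float) -> str:
    span = a1 - a0
    if span >= 360:
        def ring(r, sweep):
            p0 = _polar(cx, cy, r, a0)
            p1 = _polar(cx, cy, r, a0 + 180)
            return (
                f"M {_f(p0[0])} {_f(p0[1])} "
                f"A {_f(r)} {_f(r)} 0 1 {sweep} {_f(p1[0])} {_f(p1[1])} "
                f"A {_f(r)} {_f(r)} 0 1 {sweep} {_f(p0[0])} {_f(p0[1])} Z"
            )
        return ring(r_out, 1) + " " + ring(r_in, 0)
    o0 = _polar(cx, cy, r_out, a0)
    o1 = _polar(cx, cy, r_out, a1)
    i0 = _polar(cx, cy, r_in, a0)
    i1 = _polar(cx, cy, r_in, a1)
    large = 1 if span > 180 else 0
    return (
        f"M {_f(o0[0])} {_f(o0[1])} "
        f"A {_f(r_out)} {_f(r_out)} 0 {large} 1 {_f(o1[0])} {_f(o1[1])} "
        f"L {_f(i1[0])} {_f(i1[1])} "
        f"A {_f(r_in)} {_f(r_in)} 0 {large} 0 {_f(i0[0])} {_f(i0[1])} Z"
    )


def _render_chart(parent, chart: ChartSpec, cx: float, cy: float, font: str):
    label_size = chart.label_size or 10.0
    outer_r = _NODE_RADIUS
    if chart.style == "donut":
        outer_r = _NODE_RADIUS + _RING_GAP + len(chart.rings) * _RING_WIDTH
    for ring_i, ring in enumerate(chart.rings):
        for s in ring:
            a0, a1 = float(s.start_deg), float(s.end_deg)
            if chart.style == "pie":
                d = _wedge_path(cx, cy, _NODE_RADIUS - 1.5, a0, a1)
            else:
                r_in = _NODE_RADIUS + _RING_GAP + ring_i * _RING_WIDTH
                d = _annulus_path(cx, cy, r_in, r_in + _RING_WIDTH, a0, a1)
            ET.SubElement(
                parent, "path",
                {"class": "slice", "d": d, "fill": s.color,
                 "stroke": "#FFFFFF", "stroke-width": "0.5"},
            )
    # labels once per slice position, at the outermost ring's mid-angle
    outermost = chart.rings[-1]
    for s in outermost:
        if s.label is None:
            continue
        mid = float(s.start_deg + s.end_deg) / 2.0
        lx, ly = _polar(cx, cy, outer_r + 4 + label_size * 0.5, mid)
        text = ET.SubElement(
            parent, "text",
            {"x": _f(lx), "y": _f(ly), "font-size": _f(label_size),
             "font-family": font, "text-anchor": "middle",
             "dominant-baseline": "middle", "class": "slice-label"},
        )
        text.text = s.label


def _legend_origin(legend: LegendSpec) -> Tuple[float, float]:
    pos = legend.position
    if pos.startswith("EAST"):
        x = _CANVAS_W - legend.width - 4
    elif pos.startswith("WEST"):
        x = 4.0
    else:  # NORTH / SOUTH
        x = (_CANVAS_W - legend.width) / 2
    if pos.endswith("_TOP") or pos == "NORTH":
        y = 4.0
    elif pos.endswith("_BOTTOM") or pos == "SOUTH":
        y = _CANVAS_H - legend.height - 4
    else:
        y = (_CANVAS_H - legend.height) / 2
    return x, y


def _render_legend_group(parent, legend: LegendSpec, origin: Tuple[float, float]):
    group = ET.SubElement(
        parent, "g",
        {"id": legend.group_name, "class": "legend",
         "transform": f"translate({_f(origin[0])},{_f(origin[1])})"},
    )
    grad_count = 0
    for elem in legend.elements:
        if isinstance(elem, TextElement):
            attrs = {"x": _f(elem.x), "y": _f(elem.y), "font-size": _f(elem.size),
                     "font-family": legend.font, "class": "legend-text"}
            if elem.bold:
                attrs["font-weight"] = "bold"
            node = ET.SubElement(group, "text", attrs)
            node.text = elem.text
        elif isinstance(elem, ColorBoxElement):
            ET.SubElement(
                group, "rect",
                {"x": _f(elem.x), "y": _f(elem.y), "width": _f(elem.width),
                 "height": _f(elem.height), "fill": elem.color,
                 "stroke": "#000000", "stroke-width": "0.5",
                 "class": "legend-swatch"},
            )
        elif isinstance(elem, GradientBarElement):
            gid = f"ovlegend-grad-{grad_count}"
            grad_count += 1
            defs = ET.SubElement(group, "defs")
            grad = ET.SubElement(
                defs, "linearGradient",
                {"id": gid, "x1": "0", "y1": "0", "x2": "1", "y2": "0"},
            )
            span = elem.max_value - elem.min_value
            mid_frac = 0.5 if span == 0 else (elem.mid_value - elem.min_value) / span
            for off, color in (
                (0.0, elem.min_color), (mid_frac, elem.mid_color), (1.0, elem.max_color)
            ):
                ET.SubElement(
                    grad, "stop",
                    {"offset": f"{off * 100:.1f}%", "stop-color": color},
                )
            ET.SubElement(
                group, "rect",
                {"x": _f(elem.x), "y": _f(elem.y), "width": _f(elem.width),
                 "height": _f(elem.height), "fill": f"url(#{gid})",
                 "stroke": "#000000", "stroke-width": "0.5",
                 "class": "legend-gradient"},
            )
        elif isinstance(elem, RingOrderListElement):
            for i, name in enumerate(elem.names):
                line = ET.SubElement(
                    group, "text",
                    {"x": _f(elem.x), "y": _f(elem.y + (i + 1) * _LEADING),
                     "font-size": _f(elem.size), "font-family": legend.font,
                     "class": "legend-ring-order"},
                )
                line.text = f"{i + 1}. {name}"
        else:
            raise TypeError(f"unknown legend element {type(elem).__name__}")


def render_svg(
    network: Network,
    charts: Optional[Dict[str, ChartSpec]] = None,
    legend: Optional[LegendSpec] = None,
    layout: Optional[Dict[str, Tuple[float, float]]] = None,
    seed: int = 42,
    font: str = "sans-serif",
) -> str:
    """Render network, glyphs and legend to an SVG 1.1 document string.

    Node positions come from ``layout`` when given, else from stored node
    positions, else from a seeded deterministic force-directed layout.
    Repeated calls with identical inputs produce byte-identical output.
    """
    charts = charts or {}
    svg = ET.Element(
        "svg",
        {"xmlns": "http://www.w3.org/2000/svg", "version": "1.1",
         "width": _f(_CANVAS_W), "height": _f(_CANVAS_H),
         "viewBox": f"0 0 {_f(_CANVAS_W)} {_f(_CANVAS_H)}"},
    )
    positions = _node_positions(network, layout, seed)
    edges_g = ET.SubElement(svg, "g", {"class": "edges"})
    for src, tgt, *_ in network.edges:
        (x1, y1), (x2, y2) = positions[src], positions[tgt]
        ET.SubElement(
            edges_g, "line",
            {"x1": _f(x1), "y1": _f(y1), "x2": _f(x2), "y2": _f(y2),
             "stroke": "#999999", "stroke-width": "1"},
        )
    nodes_g = ET.SubElement(svg, "g", {"class": "nodes"})
    for node in network.nodes:
        cx, cy = positions[node.id]
        node_g = ET.SubElement(nodes_g, "g", {"class": "node", "data-id": node.id})
        ET.SubElement(
            node_g, "circle",
            {"cx": _f(cx), "cy": _f(cy), "r": _f(_NODE_RADIUS),
             "fill": "#E8E8E8", "stroke": "#666666", "stroke-width": "1"},
        )
        chart = charts.get(node.id)
        if chart is not None:
            _render_chart(node_g, chart, cx, cy, font)
    if legend is not None:
        _render_legend_group(svg, legend, _legend_origin(legend))
    return ET.tostring(svg, encoding="unicode")


def legend_to_svg(legend: LegendSpec, font: Optional[str] = None) -> str:
    """Export the legend alone as a standalone SVG document."""
    svg = ET.Element(
        "svg",
        {"xmlns": "http://www.w3.org/2000/svg", "version": "1.1",
         "width": _f(legend.width + 8), "height": _f(legend.height + 8),
         "viewBox": f"0 0 {_f(legend.width + 8)} {_f(legend.height + 8)}"},
    )
    _render_legend_group(svg, legend, (4.0, 4.0))
    return ET.tostring(svg, encoding="unicode")
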