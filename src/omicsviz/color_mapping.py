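"""Value-to-color mappings for chart slices.

Two kinds of mapping exist.  A *discrete* mapping assigns one color per
distinct value (categorical data such as cluster labels), typically from a
qualitative palette.  A *continuous* mapping is a diverging gradient
anchored at three values — minimum, middle, maximum — each with its own
color; values between anchors interpolate linearly per sRGB channel, and
values outside the bounds clamp to the boundary colors.

Default continuous bounds are symmetric about zero: the maximum bound is
``max(|data min|, |data max|)`` and the minimum bound is its opposite, so a
white middle lands on zero for log-ratio data.

The :func:`center_transform` helper exists for emitting chart strings to a
downstream renderer whose gradients are anchored at zero: data and bounds
are shifted by the middle value at emission time only; source tables are
never modified.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

__all__ = [
    "MISSING_COLOR",
    "PALETTES",
    "ContinuousMapping",
    "DiscreteMapping",
    "BoundsError",
    "default_continuous_bounds",
    "continuous_color",
    "center_transform",
    "parse_discrete_mapping",
    "format_discrete_mapping",
    "auto_discrete_mapping",
    "parse_color",
]

#: Slice color for null values; configurable where mappings are built.
MISSING_COLOR = "#CCCCCC"

_COLOR_RE = re.compile(r"#[0-9A-Fa-f]{6}\Z")

#: Bundled palettes as literal hex lists.  Qualitative sets follow the
#: familiar ColorBrewer designs; "viridis" is a sampled sequential ramp and
#: "RdBu" / "BuRd" are diverging three-plus-anchor scales.
PALETTES: Dict[str, dict] = {
    "Paired": {
        "kind": "qualitative",
        "colors": ["#A6CEE3", "#1F78B4", "#B2DF8A", "#33A02C", "#FB9A99",
                   "#E31A1C", "#FDBF6F", "#FF7F00", "#CAB2D6", "#6A3D9A",
                   "#FFFF99", "#B15928"],
    },
    "Set1": {
        "kind": "qualitative",
        "colors": ["#E41A1C", "#377EB8", "#4DAF4A", "#984EA3", "#FF7F00",
                   "#FFFF33", "#A65628", "#F781BF", "#999999"],
    },
    "Set2": {
        "kind": "qualitative",
        "colors": ["#66C2A5", "#FC8D62", "#8DA0CB", "#E78AC3", "#A6D854",
                   "#FFD92F", "#E5C494", "#B3B3B3"],
    },
    "RdBu": {  # diverging, red -> white -> blue
        "kind": "diverging",
        "colors": ["#B2182B", "#F7F7F7", "#2166AC"],
    },
    "BuRd": {  # diverging, blue -> white -> red (log-ratio default)
        "kind": "diverging",
        "colors": ["#2166AC", "#F7F7F7", "#B2182B"],
    },
    "viridis": {
        "kind": "sequential",
        "colors": ["#440154", "#46327E", "#365C8D", "#277F8E", "#1FA187",
                   "#4AC16D", "#A0DA39", "#FDE725"],
    },
}

DEFAULT_QUALITATIVE_PALETTE = "Paired"
DEFAULT_DIVERGING_PALETTE = "BuRd"


class BoundsError(ValueError):
    """Continuous bounds cannot be derived from the data."""


def parse_color(text: str) -> str:
    if not _COLOR_RE.match(text or ""):
        raise ValueError(f"invalid color {text!r}, expected #RRGGBB")
    return text.upper()


def _rgb(color: str) -> Tuple[int, int, int]:
    return int(color[1:3], 16), int(color[3:5], 16), int(color[5:7], 16)


def _hex(rgb: Tuple[int, int, int]) -> str:
    return "#{:02X}{:02X}{:02X}".format(*rgb)


@dataclass
class ContinuousMapping:
    """Three-anchor diverging gradient with clamping outside the bounds."""

    min_value: float
    mid_value: float
    max_value: float
    min_color: str
    mid_color: str
    max_color: str
    palette_name: Optional[str] = None
    missing_color: str = MISSING_COLOR

    def __post_init__(self):
        if not (self.min_value <= self.mid_value <= self.max_value):
            raise BoundsError(
                f"bounds must be ordered: {self.min_value} <= {self.mid_value} "
                f"<= {self.max_value} fails"
            )
        self.min_color = parse_color(self.min_color)
        self.mid_color = parse_color(self.mid_color)
        self.max_color = parse_color(self.max_color)
        self.missing_color = parse_color(self.missing_color)


@dataclass
class DiscreteMapping:
    """Ordered value -> color assignments (insertion order is legend order)."""

    assignments: dict  # value -> #RRGGBB
    palette_name: Optional[str] = None
    missing_color: str = MISSING_COLOR

    def __post_init__(self):
        self.assignments = {k: parse_color(v) for k, v in self.assignments.items()}
        self.missing_color = parse_color(self.missing_color)

    def color_for(self, value) -> str:
        if value is None:
            return self.missing_color
        if value in self.assignments:
            return self.assignments[value]
        # mappings parsed from text carry string keys; match typed cells on
        # their canonical text rendering
        if value is True:
            key = "true"
        elif value is False:
            key = "false"
        elif isinstance(value, float) and value.is_integer():
            key = str(int(value))
        else:
            key = str(value)
        return self.assignments.get(key, self.missing_color)


def default_continuous_bounds(values: Sequence[Optional[float]]):
    """Symmetric-about-zero default bounds from the data.

    ``M = max(|data min|, |data max|)`` over non-null finite values; the
    result is ``(-M, 0, M)``.  All-null input, or data that is identically
    zero, cannot define a gradient and raises :class:`BoundsError`.
    """
    finite = [v for v in values if v is not None and math.isfinite(v)]
    if not finite:
        raise BoundsError("no finite values to derive bounds from")
    m = max(abs(min(finite)), abs(max(finite)))
    if m == 0:
        raise BoundsError("all values are zero; specify bounds explicitly")
    return (-m, 0.0, m)


def continuous_color(value: Optional[float], mapping: ContinuousMapping) -> str:
    """Color for one value: clamp outside bounds, exact anchors, sRGB lerp between."""
    if value is None:
        return mapping.missing_color
    if value < mapping.min_value:
        return mapping.min_color
    if value > mapping.max_value:
        return mapping.max_color
    # anchors are exact; the mid check comes first so a degenerate segment
    # (min == mid or mid == max) maps its shared point to the mid anchor
    if value == mapping.mid_value:
        return mapping.mid_color
    if value == mapping.min_value:
        return mapping.min_color
    if value == mapping.max_value:
        return mapping.max_color
    if value < mapping.mid_value:
        lo, hi = mapping.min_value, mapping.mid_value
        c0, c1 = _rgb(mapping.min_color), _rgb(mapping.mid_color)
    else:
        lo, hi = mapping.mid_value, mapping.max_value
        c0, c1 = _rgb(mapping.mid_color), _rgb(mapping.max_color)
    # segment cannot be degenerate here: value strictly inside (lo, hi)
    t = (value - lo) / (hi - lo)
    return _hex(tuple(round(a + t * (b - a)) for a, b in zip(c0, c1)))


def center_transform(values: Sequence[Optional[float]], mapping: ContinuousMapping):
    """Shift values and bounds by the middle anchor for zero-anchored renderers.

    Returns ``(shifted values, adjusted_min, adjusted_max)`` with nulls
    passed through.  The shift happens only in what gets emitted to the
    renderer; the source table is untouched, and coloring the shifted value
    under the adjusted bounds reproduces :func:`continuous_color` exactly.
    """
    shifted = [None if v is None else v - mapping.mid_value for v in values]
    return (
        shifted,
        mapping.min_value - mapping.mid_value,
        mapping.max_value - mapping.mid_value,
    )


def parse_discrete_mapping(text: str) -> DiscreteMapping:
    """Parse ``value:#RRGGBB`` pairs, comma separated, order preserved."""
    if not text or not text.strip():
        raise ValueError("empty discrete mapping")
    assignments = {}
    for i, part in enumerate(text.split(",")):
        part = part.strip()
        key, sep, color = part.rpartition(":")
        if not sep:
            raise ValueError(f"malformed mapping entry {part!r} (expected value:#RRGGBB)")
        if key in assignments:
            raise ValueError(f"duplicate mapping key {key!r}")
        try:
            assignments[key] = parse_color(color)
        except ValueError as exc:
            raise ValueError(f"entry {i + 1} ({part!r}): {exc}") from None
    return DiscreteMapping(assignments=assignments)


def format_discrete_mapping(mapping: DiscreteMapping) -> str:
    return ",".join(f"{k}:{v}" for k, v in mapping.assignments.items())


def auto_discrete_mapping(
    values: Sequence, palette: str = DEFAULT_QUALITATIVE_PALETTE
) -> DiscreteMapping:
    """Assign palette colors to distinct values in first-appearance order.

    When the palette is smaller than the number of distinct values the
    colors cycle, with a warning.
    """
    colors = PALETTES[palette]["colors"]
    distinct: List = []
    for v in values:
        if v is not None and v not in distinct:
            distinct.append(v)
    if len(distinct) > len(colors):
        warnings.warn(
            f"palette {palette!r} has {len(colors)} colors for "
            f"{len(distinct)} values; colors will repeat",
            stacklevel=2,
        )
    assignments = {v: colors[i % len(colors)] for i, v in enumerate(distinct)}
    return DiscreteMapping(assignments=assignments, palette_name=palette)
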