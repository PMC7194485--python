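"""Import delimited text files into long-format, typed data tables.

A table here is deliberately *long*: several rows may share one node key
(one row per modification site, peptide, isoform or condition), which is
exactly what standard one-row-per-node attribute tables cannot hold.  The
import step mirrors a spreadsheet-style table import: the delimiter is
sniffed, every column's type is inferred from a leading sample of the file,
and the user may restrict the imported columns or override the inferred
types.
"""

from __future__ import annotations

import csv
import io
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "DTYPES",
    "ImportSpec",
    "OVTable",
    "SchemaError",
    "infer_column_type",
    "coerce_cell",
    "load_table",
    "loads_table",
    "import_from_node_table",
    "table_to_tsv",
]

#: Recognised column dtypes, narrowest first.  Type inference walks this
#: order and keeps the first dtype that parses every sampled cell.
DTYPES = ("integer", "float", "boolean", "string")

#: Raw cell spellings treated as null on input (configurable per ImportSpec).
DEFAULT_NULL_VALUES = ("", "NA")

_SNIFF_DELIMITERS = "\t,;"
_BOOL_TOKENS = {"true": True, "false": False}


class SchemaError(ValueError):
    """A referenced column does not exist, or a dtype constraint is broken."""


@dataclass
class ImportSpec:
    """Options controlling one file import.

    ``delimiter=None`` sniffs among tab, comma and semicolon.
    ``selected_columns=None`` imports every column.  ``dtype_overrides``
    wins over inference for the named columns.
    """

    path: str
    delimiter: Optional[str] = None
    selected_columns: Optional[Sequence[str]] = None
    dtype_overrides: dict = field(default_factory=dict)
    has_header: bool = True
    table_name: Optional[str] = None
    null_values: Sequence[str] = DEFAULT_NULL_VALUES
    sample_limit: int = 100


@dataclass
class OVTable:
    """A long-format typed table whose rows are hidden, never deleted, by filters.

    ``columns`` is an ordered list of ``(name, dtype)`` pairs; ``rows`` hold
    tuples of typed cells (``None`` for null).  ``visible_row_indices`` is
    the ordered subset of row positions that survive ``active_filter``;
    with no filter it is every row.
    """

    name: str
    columns: list  # list[tuple[str, str]]
    rows: list  # list[tuple]
    active_filter: object = None  # FilterExpr, set by filter_engine
    visible_row_indices: list = None

    def __post_init__(self):
        for i, row in enumerate(self.rows):
            if len(row) != len(self.columns):
                raise SchemaError(
                    f"row {i} has {len(row)} cells, expected {len(self.columns)}"
                )
        if self.visible_row_indices is None:
            self.visible_row_indices = list(range(len(self.rows)))

    # -- introspection helpers -------------------------------------------
    @property
    def column_names(self) -> list:
        return [name for name, _ in self.columns]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column_index(self, name: str) -> int:
        try:
            return self.column_names.index(name)
        except ValueError:
            raise SchemaError(f"no such column: {name!r}") from None

    def dtype_of(self, name: str) -> str:
        return self.columns[self.column_index(name)][1]

    def column_values(self, name: str, visible_only: bool = False) -> list:
        j = self.column_index(name)
        idx = self.visible_row_indices if visible_only else range(len(self.rows))
        return [self.rows[i][j] for i in idx]

    def cell(self, row_index: int, column: str):
        return self.rows[row_index][self.column_index(column)]

    def project(self, columns: Sequence[str]) -> "OVTable":
        """A new table holding only ``columns``, in the given order."""
        idx = [self.column_index(c) for c in columns]
        return OVTable(
            name=self.name,
            columns=[self.columns[j] for j in idx],
            rows=[tuple(row[j] for j in idx) for row in self.rows],
        )


# ---------------------------------------------------------------------------
# cell parsing and type inference
# ---------------------------------------------------------------------------

_INT_RE = re.compile(r"[+-]?\d+\Z")


def _parses_as(raw: str, dtype: str) -> bool:
    if dtype == "integer":
        return bool(_INT_RE.match(raw.strip()))
    if dtype == "float":
        try:
            float(raw)
        except ValueError:
            return False
        return True
    if dtype == "boolean":
        return raw.strip().lower() in _BOOL_TOKENS
    return True  # string accepts anything


def coerce_cell(raw: Optional[str], dtype: str, null_values=DEFAULT_NULL_VALUES):
    """Parse one raw text cell to ``dtype``; failures and nulls become None."""
    if raw is None or raw in null_values:
        return None
    if dtype == "string":
        return raw
    if not _parses_as(raw, dtype):
        return None
    if dtype == "integer":
        return int(raw.strip())
    if dtype == "float":
        return float(raw)
    return _BOOL_TOKENS[raw.strip().lower()]


def infer_column_type(
    cells: Iterable[Optional[str]],
    sample_limit: int = 100,
    null_values=DEFAULT_NULL_VALUES,
) -> str:
    """Infer the narrowest dtype that parses the leading sample of a column.

    At most ``sample_limit`` non-null cells are inspected, matching the
    import dialog's behaviour of reading only the first hundred lines of a
    file; cells beyond the window that later fail the inferred type are
    coerced to null rather than failing the import.  Empty or all-null input
    infers ``string``.
    """
    if sample_limit < 1:
        raise ValueError("sample_limit must be >= 1")
    sampled = []
    for raw in cells:
        if raw is None or raw in null_values:
            continue
        sampled.append(raw)
        if len(sampled) >= sample_limit:
            break
    if not sampled:
        return "string"
    for dtype in DTYPES:
        if all(_parses_as(raw, dtype) for raw in sampled):
            return dtype
    return "string"


# ---------------------------------------------------------------------------
# file import
# ---------------------------------------------------------------------------


def _sniff_delimiter(sample: str) -> str:
    header = sample.splitlines()[0] if sample else ""
    counts = {d: header.count(d) for d in _SNIFF_DELIMITERS}
    best = max(_SNIFF_DELIMITERS, key=lambda d: counts[d])
    return best if counts[best] > 0 else "\t"


def loads_table(text: str, spec: ImportSpec) -> OVTable:
    """Import a table from delimited text already in memory (see load_table)."""
    delimiter = spec.delimiter or _sniff_delimiter(text)
    reader = csv.reader(io.StringIO(text), delimiter=delimiter)
    raw_rows = [row for row in reader]
    if spec.has_header:
        if not raw_rows:
            raise SchemaError("file is empty: no header row")
        header, raw_rows = raw_rows[0], raw_rows[1:]
    else:
        width = max((len(r) for r in raw_rows), default=0)
        header = [f"Column {i + 1}" for i in range(width)]
    # pad ragged rows with nulls
    raw_rows = [tuple(row) + (None,) * (len(header) - len(row)) for row in raw_rows]

    selected = list(spec.selected_columns) if spec.selected_columns else list(header)
    for name in selected:
        if name not in header:
            raise SchemaError(f"selected column {name!r} not in file header")
    for name in spec.dtype_overrides:
        if name not in header:
            raise SchemaError(f"dtype override for unknown column {name!r}")

    col_idx = [header.index(name) for name in selected]
    columns = []
    for name, j in zip(selected, col_idx):
        dtype = spec.dtype_overrides.get(name)
        if dtype is None:
            dtype = infer_column_type(
                (row[j] for row in raw_rows),
                sample_limit=spec.sample_limit,
                null_values=spec.null_values,
            )
        elif dtype not in DTYPES:
            raise ValueError(f"unknown dtype {dtype!r} for column {name!r}")
        columns.append((name, dtype))

    rows = [
        tuple(
            coerce_cell(row[j], dtype, spec.null_values)
            for (name, dtype), j in zip(columns, col_idx)
        )
        for row in raw_rows
    ]
    name = spec.table_name or os.path.splitext(os.path.basename(spec.path or "table"))[0]
    return OVTable(name=name, columns=columns, rows=rows)


def load_table(spec: ImportSpec) -> OVTable:
    """Import a delimited text file into a typed table.

    Column types come from ``spec.dtype_overrides`` where given, otherwise
    from :func:`infer_column_type` on the file's leading lines.  Cells that
    fail coercion to their column dtype become null; the row is kept.
    """
    with open(spec.path, "r", encoding="utf-8", newline="") as fh:
        text = fh.read()
    return loads_table(text, spec)


def table_to_tsv(table: OVTable) -> str:
    """Serialize a table to TSV text (header + canonical cell rendering)."""
    out = io.StringIO()
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow(table.column_names)
    for row in table.rows:
        writer.writerow([_render_cell(c) for c in row])
    return out.getvalue()


def _render_cell(value) -> str:
    if value is None:
        return ""
    if value is True:
        return "true"
    if value is False:
        return "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


# ---------------------------------------------------------------------------
# node-table import (wide -> long melt)
# ---------------------------------------------------------------------------

_DTYPE_ORDER = {d: i for i, d in enumerate(DTYPES)}


def _dtype_join(a: str, b: str) -> str:
    """Least upper bound on the dtype lattice integer < float; anything else -> string."""
    if a == b:
        return a
    if {a, b} == {"integer", "float"}:
        return "float"
    return "string"


def import_from_node_table(network, columns: Sequence[str], connect: bool = True):
    """Melt selected node-attribute columns into a 3-column long table.

    Output columns are ``node`` / ``source`` / ``values``: one row per
    (node, selected column) pair, row order = node order x column order,
    ``source`` holding the originating column name.  The ``values`` dtype is
    the join of the source column dtypes (integer widens to float, anything
    mixed beyond that becomes string, with non-string cells rendered as
    text).  By default the new table is auto-connected back to ``network``
    using the node id as key.

    Returns ``(table, connection)``; ``connection`` is None when
    ``connect=False``.
    """
    if not columns:
        raise SchemaError("no node-table columns selected for import")
    attr_dtypes = {}
    for col in columns:
        dtype = network.node_attribute_dtype(col)
        if dtype is None:
            raise SchemaError(f"no such node attribute column: {col!r}")
        attr_dtypes[col] = dtype
    values_dtype = attr_dtypes[columns[0]]
    for col in columns[1:]:
        values_dtype = _dtype_join(values_dtype, attr_dtypes[col])

    rows = []
    for node in network.nodes:
        for col in columns:
            value = node.attributes.get(col)
            if values_dtype == "string" and value is not None and not isinstance(value, str):
                value = _render_cell(value)
            elif values_dtype == "float" and isinstance(value, int) and not isinstance(value, bool):
                value = float(value)
            rows.append((node.id, col, value))

    table = OVTable(
        name=f"{network.name} node table",
        columns=[("node", "string"), ("source", "string"), ("values", values_dtype)],
        rows=rows,
    )
    conn = None
    if connect:
        from . import network_link  # deferred: network_link imports this module

        conn = network_link.connect(table, network, net_key_col=network_link.NODE_ID_KEY,
                                    table_key_col="node", replace=True)
    return table, conn
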