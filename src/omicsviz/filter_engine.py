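"""Typed row filters: parse boolean formulas and hide non-matching rows.

Filters are trees of criteria ``(column, operator, operand)`` combined with
AND/OR connectives.  Applying a filter only changes which rows are
*visible*; the row data itself is never deleted, so clearing the filter
restores the full table.

Operator admissibility by column dtype:

====================  =======================================================
dtype                 operators
====================  =======================================================
all                   EQUALS, NOT_EQUALS, NULL, NOT_NULL
string                CONTAINS, NOT_CONTAINS, MATCHES (full-string regex)
integer / float       LOWER, LOWER_EQUALS, GREATER, GREATER_EQUALS
====================  =======================================================

Null semantics collapse SQL's three-valued logic at the leaf: any
comparison against a null cell is false, so NULL / NOT_NULL are the only
null detectors.  CONTAINS is a case-sensitive substring test and MATCHES is
an anchored (full-string) regular-expression match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Union

from .table_io import OVTable

__all__ = [
    "OPERATORS",
    "Criterion",
    "BoolExpr",
    "FilterExpr",
    "FilterParseError",
    "FilterTypeError",
    "parse_filter",
    "format_filter",
    "evaluate",
    "apply_filter",
]

NO_OPERAND_OPS = {"NULL", "NOT_NULL"}
UNIVERSAL_OPS = {"EQUALS", "NOT_EQUALS"} | NO_OPERAND_OPS
STRING_OPS = {"CONTAINS", "NOT_CONTAINS", "MATCHES"}
NUMERIC_OPS = {"LOWER", "LOWER_EQUALS", "GREATER", "GREATER_EQUALS"}
OPERATORS = UNIVERSAL_OPS | STRING_OPS | NUMERIC_OPS
CONNECTIVES = ("AND", "OR")


class FilterParseError(ValueError):
    """Malformed filter text; carries the character position of the fault."""

    def __init__(self, message: str, pos: int):
        super().__init__(f"{message} (at position {pos})")
        self.pos = pos


class FilterTypeError(TypeError):
    """Operator not admissible for the column's dtype."""


@dataclass(frozen=True)
class Criterion:
    column: str
    operator: str
    operand: object = None

    def __post_init__(self):
        if self.operator not in OPERATORS:
            raise ValueError(f"unknown operator {self.operator!r}")
        if self.operator in NO_OPERAND_OPS and self.operand is not None:
            raise ValueError(f"{self.operator} takes no operand")


@dataclass(frozen=True)
class BoolExpr:
    connective: str  # "AND" | "OR"
    children: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.connective not in CONNECTIVES:
            raise ValueError(f"unknown connective {self.connective!r}")
        if len(self.children) < 1:
            raise ValueError("connective needs at least one child")


FilterExpr = Union[Criterion, BoolExpr]


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------
# Grammar (whitespace around tokens ignored; column names may contain
# spaces — everything up to the first comma):
#   expr := leaf | node
#   leaf := "(" column "," operator ["," operand] ")"
#   node := "(" ("AND"|"OR") "," expr {"," expr} ")"


def parse_filter(text: str) -> FilterExpr:
    """Parse serialized filter text, e.g. ``(Adj p-value,LOWER_EQUALS,0.01)``."""
    if not text or not text.strip():
        raise FilterParseError("empty filter", 0)
    expr, pos = _parse_expr(text, _skip_ws(text, 0))
    pos = _skip_ws(text, pos)
    if pos != len(text):
        raise FilterParseError("trailing characters after filter", pos)
    return expr


def _skip_ws(text: str, pos: int) -> int:
    while pos < len(text) and text[pos].isspace():
        pos += 1
    return pos


def _parse_expr(text: str, pos: int):
    if pos >= len(text) or text[pos] != "(":
        raise FilterParseError("expected '('", pos)
    inner = _skip_ws(text, pos + 1)
    head, after = _read_token(text, inner)
    if head.strip() in CONNECTIVES:
        return _parse_node(text, pos, head.strip(), after)
    return _parse_leaf(text, pos, head, after)


def _read_token(text: str, pos: int):
    """Read up to the next top-level ',' or ')'; returns (token, stop position)."""
    end = pos
    while end < len(text) and text[end] not in ",)":
        if text[end] == "(":
            raise FilterParseError("unexpected '('", end)
        end += 1
    if end >= len(text):
        raise FilterParseError("unterminated expression", end)
    return text[pos:end], end


def _parse_leaf(text, open_pos, column_token, pos):
    column = column_token.strip()
    if text[pos] != ",":
        raise FilterParseError("expected ',' after column name", pos)
    op_token, pos = _read_token(text, _skip_ws(text, pos + 1))
    operator = op_token.strip()
    if operator not in OPERATORS:
        raise FilterParseError(f"unknown operator {operator!r}", pos - len(op_token))
    operand = None
    if text[pos] == ",":
        if operator in NO_OPERAND_OPS:
            raise FilterParseError(f"{operator} takes no operand", pos)
        raw, pos = _read_token(text, _skip_ws(text, pos + 1))
        operand = _parse_operand(raw.strip())
    elif operator not in NO_OPERAND_OPS:
        raise FilterParseError(f"{operator} requires an operand", pos)
    if text[pos] != ")":
        raise FilterParseError("expected ')'", pos)
    return Criterion(column, operator, operand), pos + 1


def _parse_node(text, open_pos, connective, pos):
    children = []
    while text[pos] == ",":
        child, pos = _parse_expr(text, _skip_ws(text, pos + 1))
        children.append(child)
        pos = _skip_ws(text, pos)
        if pos >= len(text):
            raise FilterParseError("unterminated expression", pos)
    if text[pos] != ")":
        raise FilterParseError("expected ')'", pos)
    if not children:
        raise FilterParseError(f"{connective} needs at least one child", pos)
    return BoolExpr(connective, tuple(children)), pos + 1


def _parse_operand(raw: str):
    if re.fullmatch(r"[+-]?\d+", raw):
        return int(raw)
    try:
        return float(raw)
    except ValueError:
        pass
    if raw.lower() in ("true", "false"):
        return raw.lower() == "true"
    return raw


def format_filter(expr: FilterExpr) -> str:
    """Inverse of parse_filter (up to whitespace and operand spelling)."""
    if isinstance(expr, Criterion):
        if expr.operand is None:
            return f"({expr.column},{expr.operator})"
        operand = expr.operand
        if operand is True:
            operand = "true"
        elif operand is False:
            operand = "false"
        return f"({expr.column},{expr.operator},{operand})"
    parts = ",".join(format_filter(c) for c in expr.children)
    return f"({expr.connective},{parts})"


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def validate(expr: FilterExpr, table: OVTable) -> None:
    """Check every leaf's column exists and its operator fits the dtype."""
    if isinstance(expr, BoolExpr):
        for child in expr.children:
            validate(child, table)
        return
    dtype = table.dtype_of(expr.column)  # raises SchemaError if absent
    admissible = set(UNIVERSAL_OPS)
    if dtype == "string":
        admissible |= STRING_OPS
    elif dtype in ("integer", "float"):
        admissible |= NUMERIC_OPS
    if expr.operator not in admissible:
        raise FilterTypeError(
            f"operator {expr.operator} not admissible for {dtype} column {expr.column!r}"
        )


def evaluate(expr: FilterExpr, table: OVTable, row_index: int) -> bool:
    """Evaluate a filter on one row.  Pure; connectives short-circuit."""
    if isinstance(expr, BoolExpr):
        if expr.connective == "AND":
            return all(evaluate(c, table, row_index) for c in expr.children)
        return any(evaluate(c, table, row_index) for c in expr.children)
    return _evaluate_leaf(expr, table, row_index)


def _evaluate_leaf(crit: Criterion, table: OVTable, row_index: int) -> bool:
    dtype = table.dtype_of(crit.column)
    cell = table.rows[row_index][table.column_index(crit.column)]
    op = crit.operator
    if op == "NULL":
        return cell is None
    if op == "NOT_NULL":
        return cell is not None
    if cell is None:
        return False  # null compares false under every other operator
    operand = _coerce_operand(crit, dtype)
    if op == "EQUALS":
        return cell == operand
    if op == "NOT_EQUALS":
        return cell != operand
    if op in STRING_OPS:
        if dtype != "string":
            raise FilterTypeError(
                f"operator {op} not admissible for {dtype} column {crit.column!r}"
            )
        if op == "CONTAINS":
            return operand in cell
        if op == "NOT_CONTAINS":
            return operand not in cell
        return re.fullmatch(operand, cell) is not None
    # numeric comparisons
    if dtype not in ("integer", "float"):
        raise FilterTypeError(
            f"operator {op} not admissible for {dtype} column {crit.column!r}"
        )
    if op == "LOWER":
        return cell < operand
    if op == "LOWER_EQUALS":
        return cell <= operand
    if op == "GREATER":
        return cell > operand
    return cell >= operand  # GREATER_EQUALS


def _coerce_operand(crit: Criterion, dtype: str):
    operand = crit.operand
    if dtype in ("integer", "float") and crit.operator not in STRING_OPS:
        if isinstance(operand, bool) or not isinstance(operand, (int, float)):
            try:
                operand = float(operand)
            except (TypeError, ValueError):
                raise FilterTypeError(
                    f"operand {crit.operand!r} is not numeric for column {crit.column!r}"
                ) from None
    elif dtype == "string" and not isinstance(operand, str):
        operand = str(operand)
    return operand


def apply_filter(table: OVTable, expr: Optional[FilterExpr]):
    """Apply (or with ``expr=None`` clear) a filter on ``table``.

    Sets ``table.active_filter`` and ``table.visible_row_indices`` and
    returns ``(n_before, n_after)`` visible-row counts for display.  Row
    data is untouched; hidden rows can always be brought back.
    """
    n_before = len(table.visible_row_indices)
    if expr is None:
        table.active_filter = None
        table.visible_row_indices = list(range(len(table.rows)))
        return n_before, len(table.rows)
    validate(expr, table)
    visible = [i for i in range(len(table.rows)) if evaluate(expr, table, i)]
    table.active_filter = expr
    table.visible_row_indices = visible
    return n_before, len(visible)
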