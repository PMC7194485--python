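"""Filter grammar and semantics, checked against a brute-force evaluator."""

import re

import pytest
from hypothesis import given, strategies as st

from omicsviz import (
    BoolExpr,
    Criterion,
    FilterParseError,
    FilterTypeError,
    OVTable,
    apply_filter,
    evaluate,
    format_filter,
    parse_filter,
)

# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def test_parse_single_criterion():
    expr = parse_filter("(Adj p-value,LOWER_EQUALS,0.01)")
    assert expr == Criterion("Adj p-value", "LOWER_EQUALS", 0.01)


def test_parse_nested_formula():
    expr = parse_filter("(AND,(Cluster,EQUALS,A),(EOC vs FTE,GREATER,0))")
    assert isinstance(expr, BoolExpr)
    assert expr.connective == "AND"
    assert expr.children == (
        Criterion("Cluster", "EQUALS", "A"),
        Criterion("EOC vs FTE", "GREATER", 0),
    )


def test_column_names_keep_internal_spaces():
    expr = parse_filter("( EOC vs OSE , NOT_NULL )")
    assert expr == Criterion("EOC vs OSE", "NOT_NULL")


@pytest.mark.parametrize(
    "text",
    [
        "(Cluster,NULL,x)",          # NULL takes no operand
        "(Cluster,EQUALS)",          # EQUALS requires one
        "(Cluster,WEIRD_OP,1)",      # unknown operator
        "(Cluster,EQUALS,A",         # unbalanced parens
        "",
        "(AND)",                     # connective with no children
        "(Cluster,EQUALS,A)x",       # trailing garbage
    ],
)
def test_parse_errors(text):
    with pytest.raises(FilterParseError) as err:
        parse_filter(text)
    assert "position" in str(err.value)


def test_format_parse_round_trip():
    texts = [
        "(Adj p-value,LOWER_EQUALS,0.01)",
        "(OR,(Cluster,EQUALS,A),(AND,(x,NULL),(y,MATCHES,a.*b)))",
    ]
    for text in texts:
        expr = parse_filter(text)
        assert parse_filter(format_filter(expr)) == expr


# ---------------------------------------------------------------------------
# leaf semantics
# ---------------------------------------------------------------------------


def _table(rows):
    return OVTable(
        name="t",
        columns=[("s", "string"), ("x", "float"), ("b", "boolean")],
        rows=rows,
    )


def test_lower_equals_includes_the_boundary():
    table = _table([("a", 0.01, True)])
    assert evaluate(Criterion("x", "LOWER_EQUALS", 0.01), table, 0)
    assert not evaluate(Criterion("x", "LOWER", 0.01), table, 0)


def test_null_cell_comparisons_are_false():
    table = _table([("a", None, None)])
    assert not evaluate(Criterion("x", "LOWER_EQUALS", 0.01), table, 0)
    assert not evaluate(Criterion("x", "EQUALS", 0.0), table, 0)
    assert not evaluate(Criterion("b", "NOT_EQUALS", True), table, 0)
    assert evaluate(Criterion("x", "NULL"), table, 0)
    assert not evaluate(Criterion("x", "NOT_NULL"), table, 0)


def test_contains_is_case_sensitive_and_matches_is_anchored():
    table = _table([("Phospho", 1.0, True)])
    assert evaluate(Criterion("s", "CONTAINS", "hos"), table, 0)
    assert not evaluate(Criterion("s", "CONTAINS", "HOS"), table, 0)
    assert not evaluate(Criterion("s", "MATCHES", "hos"), table, 0)
    assert evaluate(Criterion("s", "MATCHES", "Ph.*o"), table, 0)


def test_operator_dtype_mismatch_names_column_and_operator():
    table = _table([("a", 1.0, True)])
    with pytest.raises(FilterTypeError, match=r"CONTAINS.*'x'"):
        apply_filter(table, Criterion("x", "CONTAINS", "a"))
    with pytest.raises(FilterTypeError, match=r"GREATER.*'s'"):
        apply_filter(table, Criterion("s", "GREATER", 1))


# ---------------------------------------------------------------------------
# apply_filter behaviour
# ---------------------------------------------------------------------------


def test_clearing_restores_all_rows(synthetic_table):
    expr = parse_filter("(Adj p-value,LOWER_EQUALS,0.01)")
    apply_filter(synthetic_table, expr)
    assert len(synthetic_table.visible_row_indices) < synthetic_table.n_rows
    n_before, n_after = apply_filter(synthetic_table, None)
    assert n_after == synthetic_table.n_rows
    assert synthetic_table.active_filter is None


def test_tautology_keeps_every_row(synthetic_table):
    taut = BoolExpr(
        "OR",
        (Criterion("Cluster", "EQUALS", "A"), Criterion("Cluster", "NOT_EQUALS", "A"),
         Criterion("Cluster", "NULL")),
    )
    n_before, n_after = apply_filter(synthetic_table, taut)
    assert n_after == synthetic_table.n_rows


def test_apply_filter_is_idempotent_and_order_preserving(synthetic_table):
    expr = parse_filter("(EOC vs FTE,GREATER,0)")
    apply_filter(synthetic_table, expr)
    first = list(synthetic_table.visible_row_indices)
    apply_filter(synthetic_table, expr)
    assert synthetic_table.visible_row_indices == first
    assert first == sorted(first)
    assert synthetic_table.rows == synthetic_table.rows  # data untouched


def test_de_morgan_duality(synthetic_table):
    """Hidden(AND of criteria) == complement of visible(OR of negations)."""
    pos = BoolExpr(
        "AND",
        (Criterion("Adj p-value", "LOWER_EQUALS", 0.01),
         Criterion("Cluster", "EQUALS", "A")),
    )
    neg = BoolExpr(
        "OR",
        (Criterion("Adj p-value", "GREATER", 0.01),
         Criterion("Cluster", "NOT_EQUALS", "A"),
         Criterion("Adj p-value", "NULL"),
         Criterion("Cluster", "NULL")),
    )
    apply_filter(synthetic_table, pos)
    visible_pos = set(synthetic_table.visible_row_indices)
    apply_filter(synthetic_table, neg)
    visible_neg = set(synthetic_table.visible_row_indices)
    assert visible_pos | visible_neg == set(range(synthetic_table.n_rows))
    assert not visible_pos & visible_neg


# ---------------------------------------------------------------------------
# property: engine == independent brute-force evaluator
# ---------------------------------------------------------------------------


def brute_force(expr, table, i):
    """Independent recursive evaluator building truth values bottom-up."""
    if isinstance(expr, BoolExpr):
        bits = [brute_force(c, table, i) for c in expr.children]
        return all(bits) if expr.connective == "AND" else any(bits)
    cell = table.rows[i][table.column_names.index(expr.column)]
    op, val = expr.operator, expr.operand
    if op == "NULL":
        return cell is None
    if op == "NOT_NULL":
        return cell is not None
    if cell is None:
        return False
    if op == "EQUALS":
        return cell == (float(val) if isinstance(cell, (int, float))
                        and not isinstance(cell, bool) else val)
    if op == "NOT_EQUALS":
        return cell != (float(val) if isinstance(cell, (int, float))
                        and not isinstance(cell, bool) else val)
    if op == "CONTAINS":
        return str(val) in cell
    if op == "NOT_CONTAINS":
        return str(val) not in cell
    if op == "MATCHES":
        return re.fullmatch(str(val), cell) is not None
    return {"LOWER": cell < float(val), "LOWER_EQUALS": cell <= float(val),
            "GREATER": cell > float(val), "GREATER_EQUALS": cell >= float(val)}[op]


_num_cell = st.one_of(st.none(), st.integers(-5, 5).map(float))
_str_cell = st.one_of(st.none(), st.sampled_from(["A", "B", "ab", "ABBA", ""]))
_bool_cell = st.one_of(st.none(), st.booleans())


@st.composite
def tables(draw):
    n = draw(st.integers(0, 8))
    rows = [
        (draw(_str_cell), draw(_num_cell), draw(_bool_cell)) for _ in range(n)
    ]
    return OVTable(
        name="t", columns=[("s", "string"), ("x", "float"), ("b", "boolean")],
        rows=rows,
    )


def _criteria():
    str_ops = st.sampled_from(["EQUALS", "NOT_EQUALS", "CONTAINS", "NOT_CONTAINS",
                               "MATCHES", "NULL", "NOT_NULL"])
    num_ops = st.sampled_from(["EQUALS", "NOT_EQUALS", "LOWER", "LOWER_EQUALS",
                               "GREATER", "GREATER_EQUALS", "NULL", "NOT_NULL"])
    bool_ops = st.sampled_from(["EQUALS", "NOT_EQUALS", "NULL", "NOT_NULL"])

    def build(col, op_strategy, operand_strategy):
        return op_strategy.flatmap(
            lambda op: st.just(Criterion(col, op))
            if op in ("NULL", "NOT_NULL")
            else operand_strategy.map(lambda v: Criterion(col, op, v))
        )

    return st.one_of(
        build("s", str_ops, st.sampled_from(["A", "B", "ab", "A.*", ""])),
        build("x", num_ops, st.integers(-5, 5).map(float)),
        build("b", bool_ops, st.booleans()),
    )


_exprs = st.recursive(
    _criteria(),
    lambda children: st.tuples(
        st.sampled_from(["AND", "OR"]), st.lists(children, min_size=1, max_size=3)
    ).map(lambda t: BoolExpr(t[0], tuple(t[1]))),
    max_leaves=8,
)


@given(table=tables(), expr=_exprs)
def test_engine_matches_brute_force_evaluator(table, expr):
    for i in range(table.n_rows):
        assert evaluate(expr, table, i) == brute_force(expr, table, i)


@given(table=tables(), expr=_exprs)
def test_visible_count_matches_brute_force(table, expr):
    _, n_after = apply_filter(table, expr)
    expected = sum(brute_force(expr, table, i) for i in range(table.n_rows))
    assert n_after == expected
    assert table.visible_row_indices == [
        i for i in range(table.n_rows) if brute_force(expr, table, i)
    ]
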