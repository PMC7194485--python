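# omicsviz

Visualize long-format omics tables on molecular networks as per-node pie
and donut glyphs.

## The problem

Network tools usually attach node attributes through a table with **one
row per node**. Site-resolved omics data does not fit that mold: a
phosphoproteomics experiment yields one row per *phosphorylation site*,
a proteogenomics set one row per peptide or splice isoform, a multi-condition
screen one row per condition — many rows per gene or protein. `omicsviz`
is a library + CLI for exactly that shape of data:

1. **Import** a delimited table where several rows share one node key
   (column types inferred from the first hundred lines, overridable).
2. **Filter** rows with typed boolean formulas
   (`EQUALS`, `NOT_EQUALS`, `NULL`, `NOT_NULL` for all types;
   `CONTAINS`, `NOT_CONTAINS`, `MATCHES` for strings;
   `LOWER`, `LOWER_EQUALS`, `GREATER`, `GREATER_EQUALS` for numbers).
   Filtering hides rows; it never deletes them.
3. **Connect** the table to one or more networks by a pair of key columns
   (a node attribute vs a table column). A table may serve several
   networks; each network binds to at most one table. Per-node
   connected-row counts are bookkept under the `Omics Visualizer::`
   attribute namespace and deliberately ignore any active filter.
   Networks can be loaded from SIF/GraphML or retrieved from a
   STRING-like service through a pluggable client
   (defaults: human taxon 9606, confidence cutoff 0.40, query column
   found by a case-insensitive search for "uniprot").
4. **Visualize** connected rows per node:
   - *pie* (inner): one slice per connected row of a single value column,
     drawn inside the node;
   - *donut* (outer): concentric rings around the node — by default one
     ring per value column (first listed innermost) and one slice per
     row; "ring is row" transposes this.
   Slices partition the circle equally starting at `arcstart`
   (0° = 3 o'clock, clockwise). Values map to colors through a discrete
   mapping (`A:#1F78B4,...`) or a continuous min/mid/max gradient with
   clamping outside the bounds; default bounds are symmetric,
   `(−M, 0, M)` with `M = max(|data min|, |data max|)`.
5. **Legend & render**: grouped legend annotations (swatches, a
   min/mid/max gradient bar, the donut ring order) and a deterministic
   SVG rendering of the decorated network.

## Worked example

```python
from omicsviz import (demo_tables, connect, apply_filter, parse_filter,
                      ContinuousMapping, VizConfig, build_charts,
                      build_legend, render_svg)

table, network = demo_tables()   # small synthetic site table + network
conn = connect(table, network, net_key_col="query term", table_key_col="UniProt")
print({n: len(r) for n, r in conn.rows_per_node.items()})
n_before, n_after = apply_filter(table, parse_filter("(Adj p-value,LOWER_EQUALS,0.01)"))
print(f"{n_before} rows before filtering, {n_after} after")

mapping = ContinuousMapping(-8, 0, 8, "#2166AC", "#F7F7F7", "#B2182B")
config = VizConfig(style="donut", value_columns=["EOC vs FTE", "EOC vs OSE"],
                   mapping=mapping, label_column="AA position", filtered_only=True)
charts = build_charts(conn, config)
print(f"{len(charts)} nodes decorated")
svg = render_svg(network, charts, legend=build_legend([config]), seed=7)
print(f"SVG: {len(svg)} bytes")
```

prints

```
{'9606.P20700': 2, '9606.Q15149': 1, '9606.P49840': 1, '9606.O75822': 1}
5 rows before filtering, 4 after
3 nodes decorated
SVG: 4532 bytes
```

The accession P20700 occurs in two table rows, so its node is linked to
both and its donut carries two slices per ring (log-ratios of the two
sites, labelled by amino-acid position); the blue–white–red gradient runs
from −8 to 8 centered on 0. One node's rows were hidden by the p-value
filter, so with `filtered_only=True` only 3 of the 4 nodes get a chart.

The same workflow from a shell (state lives in a JSON session file):

```sh
ov load file=sites.tsv
ov filter filter="(Adj p-value,LOWER_EQUALS,0.01)"
ov retrieve taxonID=9606 filteredOnly=true queryColumn="UniProt"
ov viz apply outer continuous attributes="EOC vs FTE,EOC vs OSE" \
    labels="AA position" filteredOnly=true rangeMin=-8 rangeMax=8 \
    chartSettings="arcstart:0,labelsize:15"
ov viz apply inner discrete attributes="Cluster" labels="AA position" \
    colorMapping="A:#1F78B4,B:#FF7F00,C:#E31A1C" filteredOnly=true \
    chartSettings="arcstart:0,labelsize:15"
ov legend draw position="EAST_TOP" title=""
ov render out=network.svg
```

`omicsviz.fixtures.write_fixture_dir` generates a matching `sites.tsv`
plus SIF network for experimenting offline.

## Chart strings

Each decorated node also receives a one-line declarative chart string
(attribute `Omics Visualizer::{pie|donut} chart`), in the spirit of the
Cytoscape enhancedGraphics "Custom Chart" strings:

```
ovchart:<style>|node=<id>|arcstart=<deg>|labelsize=<pt or empty>|ring=<slices>|...
slice := <#RRGGBB>,<label>,<value>    (slices ';'-separated)
label := empty, or "t" + percent-encoded text
value := n | i<int> | f<float> | b0 | b1 | s<percent-encoded text>
```

Angles are not stored — they are fully determined by slice count and
`arcstart` — and `parse_chart_string(emit_chart_string(c)) == c` holds
for every chart. Value-list attributes (one for a pie, one per donut
ring) hold the plotted values, shifted by the middle anchor for
continuous mappings so a zero-anchored renderer reproduces the colors;
the source table is never modified.

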