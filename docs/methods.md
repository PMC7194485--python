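# Methods

## Data model

The central container is a *long-format typed table* (`OVTable`): ordered
columns, each `integer | float | boolean | string`; ordered rows of typed
cells where `None` marks a missing value; an optional active filter; and
the ordered set of row indices visible under it. Several rows may share
one *node key* (a protein accession, gene id, …) — that is the point:
each row is a site, peptide, isoform or condition of that node.

Column types are inferred per column as the narrowest dtype on the
lattice `integer → float → boolean → string` that parses every inspected
cell, inspecting at most the first 100 non-null cells (the window the
interactive import dialog it mirrors uses). The window is a deliberate
trade of accuracy for speed on large files: a divergent cell beyond it
makes the column mis-typed, and such cells are then coerced to null
rather than aborting the import (rows are kept intact; nothing else in a
multi-column row is lost). Empty strings and `NA` are read as null; both
are configurable on the import spec. Delimiters are sniffed among tab,
comma and semicolon on the header line.

A *network* is a plain node/edge structure with a per-node attribute map
and a network-level attribute map. Everything this package writes into
those maps is prefixed `Omics Visualizer::` so it can be recognized and
removed as a block.

## Connections

A *connection* binds one table to one network via two key columns: a
node attribute and a table column. Matching is exact string equality
after canonical rendering — numeric keys are printed without a trailing
`.0`, so the integer `42`, the float `42.0` and the string `"42"` all
match. Each node's connected rows are recorded in table order; a table
key occurring in several nodes gives each of those nodes the same rows
(the symmetric choice; the semantics of duplicate node keys were
genuinely open). A table may serve several networks, but a network binds
to at most one table; re-binding requires an explicit `replace` flag so
a connection is never silently stolen.

The per-node connected-row **count** written into the node attributes
reflects *all* matching rows, never the filtered view. Filtering is a
display/selection concept; which rows belong to a node is not a function
of the current filter. The filtered view is available separately
(`Connection.rows_for(..., filtered_only=True)`) and is what the chart
builders consume when asked to honor the filter.

Retrieval from a STRING-like service is a two-call client interface
(`map_identifiers`, then `network` at a confidence cutoff, default 0.40,
default taxon 9606 = human). The returned nodes remember their
originating identifier in the `query term` attribute, which then serves
as the network-side key of the automatic connection. Live service
results are version-dependent, so all tests and demos run against a
deterministic mock client; the HTTP client exists for interactive use.

## Filters

Filters are finite trees: leaves `(column, operator, operand)` and
`AND`/`OR` nodes with ≥ 1 children. Admissibility is typed (string
columns take the substring/regex operators, numeric columns the
comparisons). Null handling collapses three-valued logic at the leaf:
every comparison against a null cell is **false**, making `NULL` /
`NOT_NULL` the only null detectors; negation exists only through paired
operators (there is no `NOT` connective), which keeps De Morgan
reasoning explicit in formulas. `CONTAINS` is case-sensitive and
`MATCHES` is a full-string (anchored) regular expression — both were
open choices and are documented behavior, not claims about any other
implementation. The serialized grammar
`(col,OP[,operand])` / `(AND|OR,expr,...)` takes a column name as
everything up to the first comma, so names may contain spaces.

Applying a filter only rewrites `visible_row_indices` (preserving row
order) and stores the expression; clearing restores all rows. The
engine is checked against an independent brute-force recursive evaluator
over randomized tables and formulas.

## Color mappings

*Discrete*: an ordered value → `#RRGGBB` map, either parsed from
`value:color` text or auto-assigned from a named qualitative palette in
first-appearance order (colors cycle, with a warning, when values
outnumber the palette). Palettes are bundled as literal hex lists
(ColorBrewer-style qualitative and diverging sets, a sampled viridis
ramp) — no runtime dependency.

*Continuous*: three anchors (min, mid, max values and colors). Outside
the bounds, colors clamp to the boundary anchors. At an anchor, the
anchor color is returned bit-exactly; the mid check precedes the others
so a degenerate segment (min = mid or mid = max) maps its shared point
to the mid color. Between anchors, channels interpolate linearly in
sRGB with `round()` — per-channel monotone on each segment. sRGB was
chosen as the least-surprise space for chart renderers; a perceptual
variant could be added behind the same interface. Missing values get a
fixed light gray `#CCCCCC` (configurable per mapping).

Default bounds are computed from the data as `(−M, 0, M)` with
`M = max(|data min|, |data max|)`: symmetric about zero so that, for
log-ratio data, the neutral mid color sits on "no change". All-null or
all-zero data cannot define a gradient and raises instead of guessing.

The *centering shift* exists for emission to zero-anchored downstream
renderers: values and bounds are shifted by the mid anchor
(`v′ = v − mid`) in the emitted node columns only. Composing the shift
with a zero-centered mapping reproduces the original colors exactly,
which is asserted as a property test.

## Charts

Slice angles are exact rationals (`fractions.Fraction`): ring `i` of `k`
slices has boundaries `arcstart + 360·i/k`, so the spans of every ring
sum to exactly 360° with no floating-point closure fudge, and equal
boundaries are shared between adjacent slices. 0° is the 3 o'clock
position; angles increase clockwise (the anchor is standard, the
direction was an open choice). Slice order is table row order and ring
order is the user's column order — never sorted. A null cell keeps its
angular span (painted in the missing color) so rings stay aligned
across a donut.

`ring_is_row` is implemented as the exact transpose of the
`ring_is_column` slice matrix, and a one-column donut produces the same
slice tuples as the pie builder — both are property-tested. Nodes with
zero (visible) connected rows get no chart at all.

Emission writes, per node, the chart string plus one value-list column
for a pie or one per ring for a donut, and a network-level JSON record
of the visualization settings; re-applying a visualization first clears
the style's namespace columns, so emission is overwrite-idempotent. The
chart-string microformat (see README) stores no angles — they are
derived data — and round-trips structurally, including value types
(int/float/bool/string/null are tagged).

## Legends and rendering

A legend is a flat list of primitives — text, color box, gradient bar,
ring-order list — positioned relative to the legend origin and carried
under the single reserved group id `OmicsVisualizerLegend`, so the whole
legend is one unit in the SVG. Gradient-bar ticks are the mapping's
min/mid/max values verbatim, formatted to 4 significant digits; the mid
stop sits at its true proportional offset. Legend geometry (swatch
size, leading, bar size) are fixed module constants; title, font, size
and position (8-way enum, e.g. `EAST_TOP`) are user-set.

SVG rendering is intentionally simple and deterministic: edges as
lines, nodes as 18 px circles, pie wedges inside the node, donut rings
as 8 px annuli outside it, labels at the outermost ring's slice
mid-angle (label collisions are not resolved). Positions come from an
explicit layout, stored node positions, or a seeded spring layout;
coordinates are formatted at fixed precision, so a fixed seed yields
byte-identical output — which is what the determinism tests diff.
Exact radii are renderer parameters, not chart semantics.

## Sessions and the CLI

A session is versioned JSON: tables embedded as TSV blocks (human
diff-able) with their dtypes and serialized filter, networks as node
and edge lists, connections as key-column records (the row lists are
recomputed on load — they are derived data), visualization configs and
legend records. `load(save(s))` re-serializes to identical JSON and
renders identically; a truncated or alien file fails cleanly before any
state is built. Each CLI subcommand maps 1:1 onto a library call; flags
use the automation-style `key=value` syntax (with `--key value` also
accepted). Flags beyond those shown in the README examples
(`ringIsRow`, `rangeMid`, `paletteName`, `colorMin/Mid/Max`,
`loadnetwork`, `session save/load`, `render`) are extensions of this
package and documented only here.

## Synthetic data

The fixture generator emulates the *shape* of a site-level
phosphoproteomics table: accession-like keys (`P#####`), a shifted
Poisson (min 1) number of sites per protein so every protein has at
least one row, integer site positions, one N(0, σ) log-ratio column per
comparison (σ = 2 by default — a realistic spread for log₂ ratios of
regulated sites), an adjusted p-value column with a controllable
fraction of rows ≤ 0.01 (default 0.5), and a cluster label. The
matched network has one node per distinct key with the key mirrored in
`query term`, plus Erdős–Rényi edges (default p = 0.1). Defaults
(40 proteins, mean 2 sites, 2 comparisons) keep the full workflow in
well under a second.

What the generator does **not** emulate: correlated ratios across
comparisons, site-count/abundance relationships, realistic interaction
topology, or identifier mapping failures. Passing tests therefore
demonstrate the mechanics (joins, filtering, geometry, color mapping,
serialization) on data of the right shape — not biological validity of
any rendering on a real phosphoproteome.

The small worked-example pair (`demo_tables`) is likewise synthetic: it
reconstructs the published linkage illustration's *structure* (the
accession P20700 appearing in two table rows and as one node's query
term) with invented cell values.

## Known limitations

- No clustering of retrieved networks; reducing a large network to a
  module of interest is up to the caller.
- The HTTP STRING client is best-effort and untested against the live
  service in CI by design; the client interface is the contract.
- Legend layout is a fixed vertical stack; no wrapping or collision
  handling.
- `MATCHES` uses Python's `re` dialect; other engines' regex dialects
  may disagree on edge cases.
- Spreadsheet (xlsx) import is not implemented; export tables to
  CSV/TSV first.
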