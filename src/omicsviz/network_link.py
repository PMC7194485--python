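"""Networks, table-network connections, and STRING-style network retrieval.

A ``Connection`` binds one long-format table to a network through a pair of
key columns: a node-attribute column on the network side and a table column
on the table side.  Rows and nodes match when the two key values render to
the same canonical text (integers without a decimal point).  One table may
be connected to several networks, but each network is connected to at most
one table.

Connected-row bookkeeping deliberately ignores any active row filter: the
per-node count written into the node attribute table reflects *all* rows
whose key matches, so filtering the table never changes it.

Network files: SIF (tab/space separated ``source interaction target``) and
GraphML, with node attributes optionally supplied as a sidecar TSV keyed on
node id.  Retrieval from a STRING-like service goes through the pluggable
:class:`StringClient` interface; a deterministic offline mock is provided
so the full retrieval workflow runs without any web access.
"""

from __future__ import annotations

import os
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple
import json
import warnings

import networkx as nx

from .table_io import ImportSpec, OVTable, SchemaError, loads_table

__all__ = [
    "NAMESPACE",
    "NODE_ID_KEY",
    "CONNECTED_COUNT_COL",
    "QUERY_TERM_COL",
    "NodeRecord",
    "Network",
    "Connection",
    "ConnectionConflictError",
    "StringQuery",
    "StringClient",
    "MockStringClient",
    "HttpStringClient",
    "RetrievalError",
    "connect",
    "disconnect",
    "detect_query_column",
    "retrieve_string_network",
    "read_sif",
    "write_sif",
    "read_graphml",
    "load_node_attributes",
]

#: Namespace prefixing every node/network attribute this package writes,
#: so they can be identified (and hidden) as a block.
NAMESPACE = "Omics Visualizer"
CONNECTED_COUNT_COL = f"{NAMESPACE}::connected rows"
#: Node attribute holding the original query identifier after retrieval.
QUERY_TERM_COL = "query term"
#: Sentinel for connecting on the node id itself rather than an attribute.
NODE_ID_KEY = "::id"


class ConnectionConflictError(RuntimeError):
    """Network already bound to a table and replace was not requested."""


class RetrievalError(RuntimeError):
    """The STRING-like client failed; carries the client's message."""


@dataclass
class NodeRecord:
    id: str
    attributes: dict = field(default_factory=dict)
    position: Optional[Tuple[float, float]] = None

    def key_value(self, key_col: str):
        if key_col == NODE_ID_KEY:
            return self.id
        return self.attributes.get(key_col)


@dataclass
class Network:
    """Node/edge graph with per-node and network-level attribute tables."""

    name: str
    nodes: List[NodeRecord] = field(default_factory=list)
    edges: List[tuple] = field(default_factory=list)  # (source, target, attrs)
    attributes: dict = field(default_factory=dict)  # network-level table
    connection: Optional["Connection"] = None

    def __post_init__(self):
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise SchemaError(f"duplicate node ids in network {self.name!r}")
        known = set(ids)
        for src, tgt, *_ in self.edges:
            if src not in known or tgt not in known:
                raise SchemaError(f"edge ({src},{tgt}) references unknown node")

    @property
    def node_ids(self) -> List[str]:
        return [n.id for n in self.nodes]

    def node(self, node_id: str) -> NodeRecord:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise SchemaError(f"no such node: {node_id!r}")

    def node_attribute_names(self) -> List[str]:
        seen: List[str] = []
        for n in self.nodes:
            for k in n.attributes:
                if k not in seen:
                    seen.append(k)
        return seen

    def node_attribute_dtype(self, name: str) -> Optional[str]:
        """Dtype of a node-attribute column, or None if the column is absent."""
        if name == NODE_ID_KEY:
            return "string"
        present = False
        dtype = None
        for n in self.nodes:
            if name in n.attributes:
                present = True
                v = n.attributes[name]
                d = _value_dtype(v)
                dtype = d if dtype is None else _join(dtype, d)
        return dtype if present else None

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(name=self.name)
        for n in self.nodes:
            g.add_node(n.id, **n.attributes)
        for src, tgt, *rest in self.edges:
            g.add_edge(src, tgt, **(rest[0] if rest else {}))
        return g


def _value_dtype(v) -> Optional[str]:
    if v is None:
        return None
    if isinstance(v, bool):
        return "boolean"
    if isinstance(v, int):
        return "integer"
    if isinstance(v, float):
        return "float"
    return "string"


def _join(a: Optional[str], b: Optional[str]) -> str:
    if a is None:
        return b
    if b is None or a == b:
        return a
    if {a, b} == {"integer", "float"}:
        return "float"
    return "string"


# ---------------------------------------------------------------------------
# connections
# ---------------------------------------------------------------------------


def canonical_key(value) -> Optional[str]:
    """Render a key cell to matching text: integers drop any decimal point."""
    if value is None:
        return None
    if value is True:
        return "true"
    if value is False:
        return "false"
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value)


@dataclass
class Connection:
    """Binding of one table to one network via matching key columns.

    ``rows_per_node`` maps node id to the ordered list of table row indices
    whose key matches that node; it covers all rows, ignoring any active
    filter.
    """

    table: OVTable
    network: Network
    net_key_col: str
    table_key_col: str
    rows_per_node: Dict[str, List[int]] = field(default_factory=dict)

    def rows_for(self, node_id: str, filtered_only: bool = False) -> List[int]:
        rows = self.rows_per_node.get(node_id, [])
        if not filtered_only:
            return list(rows)
        visible = set(self.table.visible_row_indices)
        return [i for i in rows if i in visible]


def connect(
    table: OVTable,
    network: Network,
    net_key_col: str,
    table_key_col: str,
    replace: bool = False,
) -> Connection:
    """Connect ``table`` to ``network`` on matching key columns.

    Every node whose key equals a row's key (string equality after
    canonical rendering) gets that row; duplicate node keys all receive the
    same rows.  A per-node connected-row count is written to the node
    attribute table under the package namespace.  A network holds at most
    one connection; pass ``replace=True`` to re-bind explicitly.
    """
    table.column_index(table_key_col)  # raises SchemaError if absent
    if (network.nodes and net_key_col != NODE_ID_KEY
            and network.node_attribute_dtype(net_key_col) is None):
        raise SchemaError(f"no such node attribute column: {net_key_col!r}")
    if network.connection is not None and not replace:
        raise ConnectionConflictError(
            f"network {network.name!r} is already connected to table "
            f"{network.connection.table.name!r}; pass replace=True to re-bind"
        )
    if network.connection is not None:
        disconnect(network)

    key_idx = table.column_index(table_key_col)
    by_key: Dict[str, List[int]] = {}
    for i, row in enumerate(table.rows):
        k = canonical_key(row[key_idx])
        if k is not None:
            by_key.setdefault(k, []).append(i)

    rows_per_node = {}
    for node in network.nodes:
        k = canonical_key(node.key_value(net_key_col))
        rows = by_key.get(k, []) if k is not None else []
        rows_per_node[node.id] = list(rows)
        node.attributes[CONNECTED_COUNT_COL] = len(rows)

    conn = Connection(table, network, net_key_col, table_key_col, rows_per_node)
    network.connection = conn
    return conn


def disconnect(network: Network) -> None:
    """Remove a network's connection and its namespace bookkeeping columns.

    Disconnecting an unconnected network warns instead of raising; the
    table itself is never touched.
    """
    if network.connection is None:
        warnings.warn(f"network {network.name!r} has no connection", stacklevel=2)
        return
    for node in network.nodes:
        for key in [k for k in node.attributes if k.startswith(f"{NAMESPACE}::")]:
            del node.attributes[key]
    for key in [k for k in network.attributes if k.startswith(f"{NAMESPACE}::")]:
        del network.attributes[key]
    network.connection = None


def detect_query_column(table: OVTable) -> Optional[str]:
    """First column whose name contains "uniprot", case-insensitively."""
    for name in table.column_names:
        if "uniprot" in name.lower():
            return name
    return None


# ---------------------------------------------------------------------------
# STRING-like retrieval
# ---------------------------------------------------------------------------


@dataclass
class StringQuery:
    """Parameters of a network retrieval (defaults: human, 0.40 cutoff)."""

    query_column: Optional[str] = None
    species_taxon: int = 9606
    confidence_cutoff: float = 0.40
    filtered_only: bool = False

    def __post_init__(self):
        if not 0.0 <= self.confidence_cutoff <= 1.0:
            raise ValueError("confidence cutoff must lie in [0, 1]")


class StringClient:
    """Interface to a STRING-like service; mirrors the public API shape.

    ``map_identifiers`` resolves free-form identifiers to service ids;
    ``network`` fetches the interaction network among the resolved ids at a
    confidence cutoff.  Production and mock implementations share it so the
    whole retrieval path can run offline.
    """

    def map_identifiers(self, identifiers: Sequence[str], taxon: int) -> Dict[str, str]:
        raise NotImplementedError

    def network(self, resolved_ids: Sequence[str], cutoff: float):
        """Return (nodes, edges): nodes as {resolved_id: attribute dict}."""
        raise NotImplementedError


class MockStringClient(StringClient):
    """Deterministic offline client for tests and demos.

    Resolves every identifier to ``<taxon>.<identifier>`` and links
    consecutive resolved ids with edges carrying score 0.9.  Records the
    arguments of the last calls so contract tests can inspect the taxon and
    cutoff actually received.
    """

    def __init__(self):
        self.last_map_args = None
        self.last_network_args = None

    def map_identifiers(self, identifiers, taxon):
        self.last_map_args = (list(identifiers), taxon)
        return {ident: f"{taxon}.{ident}" for ident in identifiers}

    def network(self, resolved_ids, cutoff):
        self.last_network_args = (list(resolved_ids), cutoff)
        nodes = {rid: {"display name": rid.split(".", 1)[-1]} for rid in resolved_ids}
        edges = [
            (resolved_ids[i], resolved_ids[i + 1], {"score": 0.9})
            for i in range(len(resolved_ids) - 1)
            if 0.9 >= cutoff
        ]
        return nodes, edges


class HttpStringClient(StringClient):
    """Production client speaking the public STRING REST API over HTTP."""

    def __init__(self, base_url: str = "https://string-db.org/api"):
        self.base_url = base_url.rstrip("/")

    def _get_json(self, endpoint: str, params: dict):
        url = f"{self.base_url}/json/{endpoint}?{urllib.parse.urlencode(params)}"
        try:
            with urllib.request.urlopen(url, timeout=60) as resp:
                return json.loads(resp.read().decode("utf-8"))
        except Exception as exc:  # noqa: BLE001 - wrapped for the caller
            raise RetrievalError(str(exc)) from exc

    def map_identifiers(self, identifiers, taxon):
        data = self._get_json(
            "get_string_ids",
            {"identifiers": "\r".join(identifiers), "species": taxon,
             "limit": 1, "echo_query": 1},
        )
        return {rec["queryItem"]: rec["stringId"] for rec in data}

    def network(self, resolved_ids, cutoff):
        data = self._get_json(
            "network",
            {"identifiers": "\r".join(resolved_ids),
             "required_score": int(round(cutoff * 1000))},
        )
        nodes: Dict[str, dict] = {}
        edges = []
        for rec in data:
            a, b = rec["stringId_A"], rec["stringId_B"]
            nodes.setdefault(a, {"display name": rec.get("preferredName_A", a)})
            nodes.setdefault(b, {"display name": rec.get("preferredName_B", b)})
            edges.append((a, b, {"score": rec.get("score")}))
        for rid in resolved_ids:
            nodes.setdefault(rid, {})
        return nodes, edges


def retrieve_string_network(
    table: OVTable,
    query: StringQuery,
    client: StringClient,
    network_name: Optional[str] = None,
) -> Tuple[Network, Connection]:
    """Retrieve a network for the table's identifiers and auto-connect it.

    Unique identifiers are taken from the query column (visible rows only
    when ``query.filtered_only``), sent to the client, and the resulting
    nodes each remember their originating identifier in the 'query term'
    attribute — which then serves as the network-side key for the automatic
    connection back to the table.
    """
    query_col = query.query_column or detect_query_column(table)
    if query_col is None:
        raise SchemaError(
            "no query column given and none containing 'uniprot' was found"
        )
    values = table.column_values(query_col, visible_only=query.filtered_only)
    identifiers = []
    for v in values:
        k = canonical_key(v)
        if k is not None and k not in identifiers:
            identifiers.append(k)
    if not identifiers:
        raise ValueError("no identifiers to query (is everything filtered out?)")

    try:
        resolved = client.map_identifiers(identifiers, query.species_taxon)
        resolved_ids = [resolved[i] for i in identifiers if i in resolved]
        node_attrs, edge_list = client.network(resolved_ids, query.confidence_cutoff)
    except RetrievalError:
        raise
    except Exception as exc:  # noqa: BLE001 - client contract violation
        raise RetrievalError(str(exc)) from exc

    query_of = {rid: ident for ident, rid in resolved.items()}
    nodes = []
    for rid, attrs in node_attrs.items():
        attrs = dict(attrs)
        if rid in query_of:
            attrs[QUERY_TERM_COL] = query_of[rid]
        nodes.append(NodeRecord(id=rid, attributes=attrs))
    net = Network(
        name=network_name or f"STRING network ({table.name})",
        nodes=nodes,
        edges=[(a, b, attrs) for a, b, attrs in edge_list],
    )
    conn = connect(table, net, net_key_col=QUERY_TERM_COL, table_key_col=query_col)
    return net, conn


# ---------------------------------------------------------------------------
# network file formats
# ---------------------------------------------------------------------------


def read_sif(path: str, name: Optional[str] = None) -> Network:
    """Read a SIF file (``source<TAB>interaction<TAB>target...`` per line).

    Tab-delimited when the line contains tabs, otherwise whitespace
    delimited; a line with a single token declares an isolated node; a line
    may list several targets.
    """
    nodes: List[NodeRecord] = []
    seen = set()
    edges = []

    def ensure(nid: str):
        if nid not in seen:
            seen.add(nid)
            nodes.append(NodeRecord(id=nid))

    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            parts = [p for p in parts if p != ""]
            if len(parts) == 1:
                ensure(parts[0])
                continue
            if len(parts) < 3:
                raise SchemaError(f"malformed SIF line: {line!r}")
            src, interaction, targets = parts[0], parts[1], parts[2:]
            ensure(src)
            for tgt in targets:
                ensure(tgt)
                edges.append((src, tgt, {"interaction": interaction}))
    return Network(name=name or os.path.splitext(os.path.basename(path))[0],
                   nodes=nodes, edges=edges)


def write_sif(network: Network, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        linked = set()
        for src, tgt, *rest in network.edges:
            attrs = rest[0] if rest else {}
            interaction = attrs.get("interaction", "interacts")
            fh.write(f"{src}\t{interaction}\t{tgt}\n")
            linked.update((src, tgt))
        for node in network.nodes:
            if node.id not in linked:
                fh.write(f"{node.id}\n")


def read_graphml(path: str, name: Optional[str] = None) -> Network:
    g = nx.read_graphml(path)
    nodes = [NodeRecord(id=str(n), attributes=dict(d)) for n, d in g.nodes(data=True)]
    edges = [(str(a), str(b), dict(d)) for a, b, d in g.edges(data=True)]
    return Network(name=name or (g.name or "graphml network"), nodes=nodes, edges=edges)


def load_node_attributes(network: Network, path: str, delimiter: str = "\t") -> None:
    """Merge a sidecar attribute TSV (first column = node id) into the network.

    Column types are inferred the same way as table import; unknown node
    ids in the file are ignored.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    table = loads_table(text, ImportSpec(path=path, delimiter=delimiter))
    if not table.columns:
        return
    id_col = table.column_names[0]
    by_id = {n.id: n for n in network.nodes}
    for row in table.rows:
        node = by_id.get(canonical_key(row[0]))
        if node is None:
            continue
        for (col, _dtype), value in zip(table.columns[1:], row[1:]):
            node.attributes[col] = value
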