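"""Deterministic synthetic site-level tables and matched random networks.

Real inputs for this kind of visualization are site-resolved proteomics
tables: one row per phosphorylation site, keyed by a protein accession,
with one log-ratio column per condition comparison, an adjusted p-value
and a cluster label.  The generator reproduces that *shape* — accession-like
keys, several sites per protein, centered log-ratios, a controllable
fraction of significant sites — without attempting to mimic any real
phosphoproteome's statistics.  Everything is seeded, so tests and demos
run offline and reproducibly.

The worked-example pair :func:`demo_tables` is a small synthetic stand-in
reconstructing the published linkage illustration: an accession (P20700)
that occurs in two table rows and as the 'query term' of one network node.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .network_link import QUERY_TERM_COL, Network, NodeRecord, write_sif
from .table_io import OVTable, table_to_tsv

__all__ = [
    "FixtureConfig",
    "make_table",
    "make_network",
    "write_fixture_dir",
    "demo_tables",
]

# Default comparison names follow the ovarian-cancer-vs-healthy-tissue
# naming used throughout the worked examples; extra comparisons beyond the
# first two get generic names.
_COMPARISON_NAMES = ("EOC vs FTE", "EOC vs OSE")


@dataclass
class FixtureConfig:
    """Shape parameters of one synthetic data set.

    ``sites_per_protein`` is the mean of a shifted-Poisson site count
    (minimum 1, so every protein has at least one row);
    ``frac_significant`` is the fraction of rows with adjusted p <= 0.01;
    ``effect_sd`` is the spread of the centered-normal log-ratios.
    """

    n_proteins: int = 40
    sites_per_protein: float = 2.0
    n_comparisons: int = 2
    effect_sd: float = 2.0
    frac_significant: float = 0.5
    n_clusters: int = 3
    edge_prob: float = 0.1
    seed: int = 42

    def __post_init__(self):
        if min(self.n_proteins, self.n_comparisons, self.n_clusters) < 1:
            raise ValueError("counts must be >= 1")
        if self.sites_per_protein < 1:
            raise ValueError("sites_per_protein must be >= 1")
        if not (0 <= self.frac_significant <= 1 and 0 <= self.edge_prob <= 1):
            raise ValueError("fractions/probabilities must lie in [0, 1]")


def _comparison_name(i: int) -> str:
    if i < len(_COMPARISON_NAMES):
        return _COMPARISON_NAMES[i]
    return f"Log ratio {i + 1}"


def _accession(rng: np.random.Generator) -> str:
    return "P" + "".join(str(d) for d in rng.integers(0, 10, size=5))


def make_table(config: FixtureConfig) -> OVTable:
    """Generate a site-level table: key, site position, log-ratios, p, cluster.

    Columns: 'UniProt' (accession-like key, exercising key-column
    auto-detection), integer 'AA position', one float log-ratio column per
    comparison drawn from N(0, effect_sd), float 'Adj p-value' with
    ``frac_significant`` of rows at or below 0.01, and a 'Cluster' label
    among A, B, C, ...  Deterministic per seed.
    """
    rng = np.random.default_rng(config.seed)
    keys = []
    seen = set()
    while len(keys) < config.n_proteins:
        acc = _accession(rng)
        if acc not in seen:
            seen.add(acc)
            keys.append(acc)
    site_counts = 1 + rng.poisson(config.sites_per_protein - 1.0, size=config.n_proteins)
    n_rows = int(site_counts.sum())

    cluster_labels = [chr(ord("A") + i) for i in range(config.n_clusters)]
    significant = rng.random(n_rows) < config.frac_significant
    rows = []
    i = 0
    for key, count in zip(keys, site_counts):
        positions = np.sort(rng.integers(1, 2000, size=count))
        for pos in positions:
            ratios = rng.normal(0.0, config.effect_sd, size=config.n_comparisons)
            if significant[i]:
                pval = float(rng.uniform(0.0, 0.01))
            else:
                pval = float(rng.uniform(0.011, 1.0))
            cluster = cluster_labels[int(rng.integers(0, config.n_clusters))]
            rows.append(
                (key, int(pos), *[float(r) for r in ratios], pval, cluster)
            )
            i += 1

    columns = [("UniProt", "string"), ("AA position", "integer")]
    columns += [(_comparison_name(j), "float") for j in range(config.n_comparisons)]
    columns += [("Adj p-value", "float"), ("Cluster", "string")]
    return OVTable(name=f"synthetic sites (seed {config.seed})",
                   columns=columns, rows=rows)


def make_network(
    table: OVTable,
    edge_prob: float = 0.1,
    seed: int = 42,
    key_column: str = "UniProt",
) -> Network:
    """Random network matched to a table: one node per distinct key.

    Each node stores its key in the 'query term' attribute, mirroring the
    retrieval workflow, so connecting on 'query term' vs the key column
    links every table row.  Edges are Erdos-Renyi with ``edge_prob``,
    deterministic per seed.
    """
    key_idx = table.column_index(key_column)
    keys = []
    for row in table.rows:
        k = row[key_idx]
        if k is not None and k not in keys:
            keys.append(k)
    rng = np.random.default_rng(seed)
    nodes = [
        NodeRecord(id=str(k), attributes={QUERY_TERM_COL: str(k), "display name": str(k)})
        for k in keys
    ]
    edges = []
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            if rng.random() < edge_prob:
                edges.append((str(keys[i]), str(keys[j]), {"interaction": "pp"}))
    return Network(name=f"synthetic network (seed {seed})", nodes=nodes, edges=edges)


def write_fixture_dir(config: FixtureConfig, directory: str) -> dict:
    """Write fixture TSV + SIF + sidecar node-attribute TSV files.

    Returns the paths written, keyed 'table', 'network', 'attributes'.
    """
    os.makedirs(directory, exist_ok=True)
    table = make_table(config)
    network = make_network(table, edge_prob=config.edge_prob, seed=config.seed)
    table_path = os.path.join(directory, "sites.tsv")
    sif_path = os.path.join(directory, "network.sif")
    attr_path = os.path.join(directory, "node_attributes.tsv")
    with open(table_path, "w", encoding="utf-8") as fh:
        fh.write(table_to_tsv(table))
    write_sif(network, sif_path)
    with open(attr_path, "w", encoding="utf-8") as fh:
        fh.write("id\tquery term\tdisplay name\n")
        for node in network.nodes:
            fh.write(
                f"{node.id}\t{node.attributes[QUERY_TERM_COL]}\t"
                f"{node.attributes['display name']}\n"
            )
    return {"table": table_path, "network": sif_path, "attributes": attr_path}


def demo_tables() -> Tuple[OVTable, Network]:
    """Synthetic stand-in for the published two-table linkage illustration.

    A small site-level table and a node table whose 'query term' values
    match the table's 'UniProt' accessions; P20700 appears in exactly two
    table rows and as one node, so connecting the pair links that node to
    two rows.  The cell values other than the published accessions are
    invented.
    """
    table = OVTable(
        name="demo sites",
        columns=[
            ("UniProt", "string"), ("AA position", "integer"),
            ("EOC vs FTE", "float"), ("EOC vs OSE", "float"),
            ("Adj p-value", "float"), ("Cluster", "string"),
        ],
        rows=[
            ("P20700", 393, 1.8, 2.4, 0.004, "C"),
            ("Q15149", 4613, -2.1, -1.3, 0.008, "A"),
            ("P20700", 23, 0.9, 1.1, 0.002, "C"),
            ("P49840", 219, -0.4, 2.2, 0.03, "B"),
            ("O75822", 58, 3.0, -0.7, 0.001, "B"),
        ],
    )
    nodes = [
        NodeRecord(id=f"9606.{acc}", attributes={QUERY_TERM_COL: acc, "display name": name})
        for acc, name in [
            ("P20700", "LMNB1"), ("Q15149", "PLEC"),
            ("P49840", "GSK3A"), ("O75822", "EIF3J"),
        ]
    ]
    edges = [
        ("9606.P20700", "9606.Q15149", {"interaction": "pp"}),
        ("9606.P49840", "9606.O75822", {"interaction": "pp"}),
    ]
    return table, Network(name="demo network", nodes=nodes, edges=edges)
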