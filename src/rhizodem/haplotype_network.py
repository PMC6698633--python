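"""Minimum spanning networks over multilocus haplotypes.

A minimum spanning network (MSN) generalizes the minimum spanning tree:
when several edges of equal weight could each join two previously separate
components, all of them are retained, so reticulations record ambiguity in
the haplotype genealogy.  Distances are nucleotide mismatches between
concatenated haplotype sequences (after the missing-data policy applied at
collapse time).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .mlst_io import HaplotypeTable, MLSTDataset

__all__ = ["HaplotypeNetwork", "build_msn", "write_graphml", "edge_table"]


@dataclass
class HaplotypeNetwork:
    """Nodes are haplotypes (labelled H1, H2, ... in table order); edges
    carry mismatch weights.  ``spanning`` edges realize one minimum spanning
    tree; ``co_minimal`` edges are equal-weight alternatives retained by the
    tie rule."""

    graph: nx.Graph
    total_spanning_weight: int
    node_order: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()


def _mismatch(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def build_msn(table: HaplotypeTable, node_attrs: dict[str, dict] | None = None) -> HaplotypeNetwork:
    """Kruskal construction with tie retention.

    Edges are processed in (weight, endpoints) order.  Within each weight
    class, every edge whose endpoints were in different components *at the
    start of the class* is retained; edges that actually merge components
    first are flagged spanning, the rest co-minimal.
    """
    k = table.k
    if k < 2:
        raise ValueError("need >= 2 haplotypes")
    labels = [f"H{i + 1}" for i in range(k)]
    edges = []
    for i in range(k):
        for j in range(i + 1, k):
            edges.append((_mismatch(table.sequences[i], table.sequences[j]),
                          labels[i], labels[j]))
    edges.sort()

    g = nx.Graph()
    for lab, count, members in zip(labels, table.counts, table.members):
        g.add_node(lab, count=int(count), members=",".join(members))
    if node_attrs:
        for attr, mapping in node_attrs.items():
            nx.set_node_attributes(g, mapping, attr)

    parent = {lab: lab for lab in labels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    total = 0
    idx = 0
    while idx < len(edges):
        w = edges[idx][0]
        group = []
        while idx < len(edges) and edges[idx][0] == w:
            group.append(edges[idx])
            idx += 1
        snapshot = {lab: find(lab) for lab in labels}
        for w_, u, v in group:
            if snapshot[u] != snapshot[v]:
                ru, rv = find(u), find(v)
                spanning = ru != rv
                if spanning:
                    parent[ru] = rv
                    total += w_
                g.add_edge(u, v, weight=int(w_), spanning=bool(spanning),
                           co_minimal=bool(not spanning))
    return HaplotypeNetwork(g, total, labels)


def composition_attrs(table: HaplotypeTable, ds: MLSTDataset) -> dict[str, dict]:
    """Per-node country/clade/species composition strings from metadata."""
    if ds.metadata is None:
        raise ValueError("dataset has no metadata")
    attrs: dict[str, dict] = {"country": {}, "clade": {}, "species": {}}
    for i, members in enumerate(table.members):
        lab = f"H{i + 1}"
        sub = ds.metadata.loc[[m for m in members if m in ds.metadata.index]]
        for col in attrs:
            counts = sub[col].value_counts()
            attrs[col][lab] = ";".join(f"{k}:{v}" for k, v in counts.items())
    return attrs


def write_graphml(net: HaplotypeNetwork, path) -> None:
    nx.write_graphml(net.graph, path)


def edge_table(net: HaplotypeNetwork) -> pd.DataFrame:
    rows = [
        {"from": u, "to": v, "weight": d["weight"],
         "spanning": d["spanning"], "co_minimal": d["co_minimal"]}
        for u, v, d in sorted(net.graph.edges(data=True),
                              key=lambda e: (e[2]["weight"], e[0], e[1]))
    ]
    return pd.DataFrame(rows)
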