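"""Top-gene subgraph extraction for visualization.

The highest-ranked genes are placed back into the context of the original
network: the vertex-induced subgraph over the selected genes, with edges
optionally filtered by a minimum weight.  Node selection is either the top-n
genes by rank or all genes above a probability threshold (the intersection
when both are given), always capped at 50 nodes so an exported graph stays
readable.  Output is data a viewer can load — JSON node-link or GraphML —
rather than a rendered layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import ParameterError
from .network import GeneNetwork

MAX_NODES = 50


@dataclass(frozen=True)
class SubgraphExport:
    """Induced, edge-filtered subgraph of top-ranked genes."""

    nodes: tuple[dict, ...]  # entrez, symbol, probability, training_label, rank
    edges: tuple[tuple[str, str, float], ...]
    n_nodes_requested: int
    prob_threshold: float | None
    edge_threshold: float

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(node["entrez"], **{k: v for k, v in node.items() if k != "entrez"})
        for a, b, w in self.edges:
            g.add_edge(a, b, weight=w)
        return g

    def to_json(self, path: str | Path) -> None:
        payload = {
            "nodes": list(self.nodes),
            "links": [{"source": a, "target": b, "weight": w} for a, b, w in self.edges],
            "thresholds": {
                "n_nodes": self.n_nodes_requested,
                "prob_threshold": self.prob_threshold,
                "edge_threshold": self.edge_threshold,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_graphml(self, path: str | Path) -> None:
        g = self.to_networkx()
        nx.write_graphml(g, path)


def top_subgraph(
    table: pd.DataFrame,
    network: GeneNetwork,
    n_nodes: int = MAX_NODES,
    prob_threshold: float | None = None,
    edge_threshold: float = 0.0,
) -> SubgraphExport:
    """Extract the subgraph of top-predicted genes.

    ``table`` is a prediction table from :func:`gbanet.model.predict_all`.
    Selection takes the top ``n_nodes`` by rank, intersected with the
    probability threshold when one is given, and is capped at 50 nodes.
    Induced edges below ``edge_threshold`` are dropped (nodes are retained
    even if they end up isolated).
    """
    if n_nodes <= 0:
        raise ParameterError(f"n_nodes must be positive, got {n_nodes}")
    n_keep = min(n_nodes, MAX_NODES)
    selected = table.sort_values("Rank").head(n_keep)
    if prob_threshold is not None:
        selected = selected[selected["Probability"] >= prob_threshold]
    nodes = tuple(
        {
            "entrez": row["Entrez"],
            "symbol": row["Symbol"],
            "probability": float(row["Probability"]),
            "training_label": row["Training-Label"],
            "rank": int(row["Rank"]),
        }
        for _, row in selected.iterrows()
    )
    node_ids = {n["entrez"] for n in nodes}
    edges = tuple(
        (network.nodes[i], network.nodes[j], float(w))
        for i, j, w in network.edges
        if network.nodes[i] in node_ids
        and network.nodes[j] in node_ids
        and w >= edge_threshold
    )
    return SubgraphExport(
        nodes=nodes,
        edges=edges,
        n_nodes_requested=n_nodes,
        prob_threshold=prob_threshold,
        edge_threshold=edge_threshold,
    )
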