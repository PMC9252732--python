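"""Weighted undirected gene networks.

Networks are loaded from plain edge-list TSV files (``entrez_a  entrez_b
[weight]``) and canonicalized into a :class:`GeneNetwork`: nodes are the set
of edge endpoints ordered by ascending numeric Entrez ID, self-loops are
dropped, duplicate undirected edges are collapsed keeping the maximum weight.
The canonical form is invariant to the row order of the input file, so matrix
layouts derived from a network are reproducible across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .errors import EmptyInputError, ParseError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneNetwork:
    """A weighted undirected network over Entrez-identified genes.

    Parameters
    ----------
    name
        Human-readable network name (used in summaries and fingerprints).
    nodes
        Node identifiers in canonical order (ascending numeric Entrez).
    edges
        Undirected edges as ``(i, j, weight)`` index triples with ``i < j``
        referring to positions in ``nodes``; weights are strictly positive.
    """

    name: str
    nodes: tuple[str, ...]
    edges: tuple[tuple[int, int, float], ...]
    node_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "node_index", {g: i for i, g in enumerate(self.nodes)}
        )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def node_set(self) -> frozenset[str]:
        return frozenset(self.nodes)

    def adjacency(self) -> sp.csr_array:
        """Symmetric sparse adjacency matrix in canonical node order."""
        n = self.n_nodes
        if not self.edges:
            return sp.csr_array((n, n))
        ii, jj, ww = zip(*self.edges)
        rows = np.concatenate([ii, jj])
        cols = np.concatenate([jj, ii])
        vals = np.concatenate([ww, ww])
        return sp.csr_array((vals, (rows, cols)), shape=(n, n))

    def degree_vector(self) -> np.ndarray:
        """Weighted degree ``deg(i) = sum_j w_ij``; strictly positive since
        every node is an edge endpoint."""
        return np.asarray(self.adjacency().sum(axis=1)).ravel()


def _node_sort_key(gene: str):
    # Numeric Entrez IDs sort numerically; anything else sorts after, lexically.
    return (0, int(gene)) if gene.isdigit() else (1, 0, gene)


def from_edges(name: str, raw_edges: list[tuple[str, str, float]]) -> GeneNetwork:
    """Canonicalize raw ``(gene_a, gene_b, weight)`` triples into a network.

    Self-loops are dropped (logged), duplicate undirected pairs keep the
    maximum weight, and nodes are ordered by ascending numeric Entrez ID.
    """
    best: dict[tuple[str, str], float] = {}
    n_self = 0
    for a, b, w in raw_edges:
        if a == b:
            n_self += 1
            continue
        key = (a, b) if _node_sort_key(a) <= _node_sort_key(b) else (b, a)
        if w > best.get(key, 0.0):
            best[key] = w
    if n_self:
        logger.info("network %s: dropped %d self-loop(s)", name, n_self)
    if not best:
        raise EmptyInputError(f"network {name!r} has no valid edges")
    nodes = tuple(sorted({g for pair in best for g in pair}, key=_node_sort_key))
    index = {g: i for i, g in enumerate(nodes)}
    edges = tuple(
        sorted(
            (min(index[a], index[b]), max(index[a], index[b]), w)
            for (a, b), w in best.items()
        )
    )
    return GeneNetwork(name=name, nodes=nodes, edges=edges)


def load_edge_list(path: str | Path, name: str | None = None) -> GeneNetwork:
    """Load a network from an edge-list TSV.

    The file has two or three tab-separated columns: ``entrez_a entrez_b
    [weight]``; a missing weight defaults to 1.0.  A header row is detected
    when the third column of the first row is non-numeric (or, for 2-column
    files, never assumed — 2-column rows are gene pairs unless the row is
    the literal header of the writer).
    """
    path = Path(path)
    name = name or path.stem
    raw: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected >= 2 columns")
            a, b = fields[0].strip(), fields[1].strip()
            if lineno == 1 and not a.isdigit() and not b.isdigit():
                # header row (node IDs are numeric Entrez strings)
                continue
            if len(fields) >= 3 and fields[2].strip():
                try:
                    w = float(fields[2])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric weight {fields[2]!r}"
                    ) from None
            else:
                w = 1.0
            if w <= 0:
                raise ParseError(f"{path}:{lineno}: non-positive weight {w}")
            raw.append((a, b, w))
    if not raw:
        raise EmptyInputError(f"edge list {path} is empty")
    return from_edges(name, raw)


def write_edge_list(network: GeneNetwork, path: str | Path) -> None:
    """Write the canonical edge list (TSV with header)."""
    with open(path, "w") as fh:
        fh.write("entrez_a\tentrez_b\tweight\n")
        for i, j, w in network.edges:
            fh.write(f"{network.nodes[i]}\t{network.nodes[j]}\t{w:g}\n")
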