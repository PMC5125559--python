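"""Protein interactome construction and centrality-based target prioritization.

The drug-target shortlist is built from two node centralities computed on the
(undirected, unweighted) protein-protein interaction graph:

* **Subgraph centrality** ``SC(u) = sum_j (v_j^u)^2 * exp(lambda_j)`` — the
  diagonal of the matrix exponential of the adjacency matrix, i.e. a
  1/k!-weighted count of closed walks through *u*.  High SC correlates with
  protein lethality.
* **Betweenness centrality** ``BC(v)`` — the fraction of shortest paths
  between other node pairs that pass through *v* ("bottleneck-ness"),
  normalized by ``2/((n-1)(n-2))`` so values lie in [0, 1].

Targets are ranked by BC descending after filtering for SC above a threshold
(default 1e23, the scale observed on a bacterial interactome of ~1000
reviewed proteins).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "InteractomeGraph",
    "CentralityRecord",
    "parse_string_links",
    "restrict_to_nodes",
    "subgraph_centrality",
    "betweenness_centrality",
    "centrality_records",
    "prioritize_targets",
    "write_shortlist",
    "read_shortlist",
]

logger = logging.getLogger(__name__)

#: components larger than this use the truncated closed-walk series for SC
#: instead of a dense eigendecomposition (bounded memory at interactome scale)
DENSE_SC_LIMIT = 3000

#: truncation order of the closed-walk series fallback: sum_k (A^k)_uu / k!
SERIES_ORDER = 60


class InteractomeGraph(nx.Graph):
    """Simple undirected PPI graph.

    Nodes are protein identifier strings; edges may carry an integer
    ``confidence`` attribute (STRING combined score, 0-1000).  Self-loops and
    parallel edges are never stored: ``add_edge`` silently drops loops and
    collapses duplicates (keeping the highest confidence seen).
    """

    def add_edge(self, u, v, **attr):  # noqa: D102 - see class docstring
        if u == v:
            return
        if self.has_edge(u, v):
            old = self[u][v].get("confidence")
            new = attr.get("confidence")
            if old is not None and new is not None:
                attr["confidence"] = max(old, new)
        super().add_edge(u, v, **attr)


@dataclass(frozen=True)
class CentralityRecord:
    """Per-protein centrality values used for target prioritization."""

    protein_id: str
    sc: float
    bc: float

    def __post_init__(self):
        if self.sc < 1.0 - 1e-9:
            raise ValueError(
                f"subgraph centrality must be >= 1 (closed walk of length 0), "
                f"got {self.sc} for {self.protein_id}"
            )
        if not (-1e-12 <= self.bc <= 1.0 + 1e-12):
            raise ValueError(
                f"normalized betweenness must lie in [0, 1], got {self.bc}"
            )


class ParseError(ValueError):
    """Raised for malformed interaction edge-list lines."""


def parse_string_links(path, min_score: int = 0) -> InteractomeGraph:
    """Parse a STRING ``protein.links``-dialect edge list.

    Each data line is whitespace-separated ``protein1 protein2 [combined_score]``;
    a single header line starting with ``protein1`` is skipped.  Edges with
    score below ``min_score`` are excluded (threshold is inclusive: score >=
    min_score is kept), self-loops dropped and duplicate lines collapsed.

    Parameters
    ----------
    path : str or Path
        Edge-list file.  An empty file yields an empty graph.
    min_score : int
        Minimum combined score to retain an edge.  The default 0 keeps
        everything, since no cutoff is assumed for the published interactome.
    """
    graph = InteractomeGraph()
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if lineno == 1 and fields[0].lower().startswith("protein1"):
                continue
            if len(fields) < 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected at least 2 columns, "
                    f"got {len(fields)}: {line!r}"
                )
            u, v = fields[0], fields[1]
            score = None
            if len(fields) >= 3:
                try:
                    score = int(fields[2])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}: line {lineno}: combined_score is not an "
                        f"integer: {fields[2]!r}"
                    ) from exc
            graph.add_node(u)
            graph.add_node(v)
            if score is not None and score < min_score:
                continue
            if score is None:
                graph.add_edge(u, v)
            else:
                graph.add_edge(u, v, confidence=score)
    return graph


def restrict_to_nodes(graph: nx.Graph, keep: Iterable[str]) -> InteractomeGraph:
    """Induced subgraph on ``nodes(graph) & keep``.

    Used to restrict an interactome to reviewed (Swiss-Prot) proteins; edges
    with either endpoint removed are dropped.  An empty intersection yields an
    empty graph.
    """
    keep = set(keep)
    sub = InteractomeGraph()
    sub.add_nodes_from(n for n in graph.nodes if n in keep)
    for u, v, data in graph.edges(data=True):
        if u in keep and v in keep:
            sub.add_edge(u, v, **data)
    return sub


def _sc_series(adj: np.ndarray, order: int = SERIES_ORDER) -> np.ndarray:
    """Diagonal of exp(A) via the truncated closed-walk series sum_k (A^k)_uu / k!."""
    n = adj.shape[0]
    term = np.eye(n)
    diag = np.ones(n)
    for k in range(1, order + 1):
        term = term @ adj
        diag = diag + np.diag(term) / math.factorial(k)
    return diag


def subgraph_centrality(graph: nx.Graph) -> dict:
    """Subgraph centrality ``SC(u) = sum_j (v_j^u)^2 exp(lambda_j)`` per node.

    Computed per connected component by dense symmetric eigendecomposition;
    components above :data:`DENSE_SC_LIMIT` nodes fall back to the truncated
    closed-walk series (order :data:`SERIES_ORDER`) with a logged warning.
    Isolated nodes get exactly 1.0 (the zero-length closed walk).
    """
    result: dict = {}
    for component in nx.connected_components(graph):
        nodes = sorted(component)
        if len(nodes) == 1:
            result[nodes[0]] = 1.0
            continue
        adj = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
        if len(nodes) > DENSE_SC_LIMIT:
            logger.warning(
                "component with %d nodes exceeds dense limit %d; "
                "using truncated closed-walk series (order %d)",
                len(nodes), DENSE_SC_LIMIT, SERIES_ORDER,
            )
            diag = _sc_series(adj)
        else:
            eigenvalues, eigenvectors = np.linalg.eigh(adj)
            diag = (eigenvectors ** 2) @ np.exp(eigenvalues)
        for node, value in zip(nodes, diag):
            result[node] = float(value)
    return result


def betweenness_centrality(graph: nx.Graph) -> dict:
    """Normalized betweenness ``BC(v) = 2/((n-1)(n-2)) * sum σ(s,t|v)/σ(s,t)``.

    Endpoint-excluding; disconnected pairs contribute 0; graphs with fewer
    than 3 nodes return 0.0 for every node.
    """
    n = graph.number_of_nodes()
    if n < 3:
        return {node: 0.0 for node in graph.nodes}
    return nx.betweenness_centrality(graph, normalized=True, weight=None)


def centrality_records(graph: nx.Graph) -> list:
    """Compute both centralities and package them per protein."""
    sc = subgraph_centrality(graph)
    bc = betweenness_centrality(graph)
    return [CentralityRecord(node, sc[node], bc[node]) for node in sorted(graph.nodes)]


def prioritize_targets(
    records: Sequence[CentralityRecord], sc_min: float = 1e23, k: int = 10
) -> list:
    """Rank putative drug targets: SC filter then BC-descending sort.

    Keeps records with ``sc > sc_min`` (strict), sorts by BC descending with
    ties broken by SC descending then protein_id ascending, and truncates to
    the first ``k``.
    """
    if sc_min <= 0:
        raise ValueError("sc_min must be positive")
    if k < 0:
        raise ValueError("k must be nonnegative")
    kept = [r for r in records if r.sc > sc_min]
    kept.sort(key=lambda r: (-r.bc, -r.sc, r.protein_id))
    return kept[:k]


def write_shortlist(records: Sequence[CentralityRecord], path) -> None:
    """Write a shortlist TSV: ``protein_id  sc  bc`` (sc as 3-sig-digit
    scientific notation, bc with 4 decimals)."""
    with open(path, "w") as handle:
        handle.write("protein_id\tsc\tbc\n")
        for rec in records:
            handle.write(f"{rec.protein_id}\t{rec.sc:.2E}\t{rec.bc:.4f}\n")


def read_shortlist(path) -> list:
    """Read a shortlist TSV written by :func:`write_shortlist`."""
    records = []
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("protein_id"):
            raise ParseError(f"{path}: missing shortlist header")
        for line in handle:
            if not line.strip():
                continue
            pid, sc, bc = line.rstrip("\n").split("\t")
            records.append(CentralityRecord(pid, float(sc), float(bc)))
    return records
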