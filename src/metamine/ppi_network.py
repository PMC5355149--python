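"""Induced protein-protein interaction networks and degree ranking.

Interaction data are consumed as a pre-exported edge table (interactorA,
interactorB, source, evidence).  Only experimentally supported rows are
kept.  The analysis network is induced on the mined gene list: an edge
survives only if BOTH endpoints are query genes; self-loops are dropped and
so are nodes left without any edge.  The node statistic is degree — the
number of distinct interaction partners — and high-degree nodes are the
candidate hub regulators.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, TextIO

import networkx as nx

Edge = tuple[str, str, str, str]  # (a, b, source, evidence)


class EdgeParseError(ValueError):
    pass


@dataclass
class InteractionNetwork:
    """Undirected simple graph over gene symbols; edge data keep provenance."""

    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b in self.graph.edges}

    def degree(self, symbol: str) -> int:
        return int(self.graph.degree[symbol])

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def load_edges(stream: TextIO | str) -> list[Edge]:
    """Read an edge-list TSV: interactorA, interactorB[, source[, evidence]].

    Lines starting with ``#`` are comments.  Rows whose evidence column is
    present and not ``experimental`` (case-insensitive) are dropped.
    Duplicate unordered pairs collapse to the first row seen.  A data row
    with fewer than two columns raises :class:`EdgeParseError` naming the
    line number.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    edges: list[Edge] = []
    seen: set[frozenset[str]] = set()
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise EdgeParseError(f"line {lineno}: edge row needs at least 2 columns")
        a, b = fields[0].strip(), fields[1].strip()
        source = fields[2].strip() if len(fields) > 2 else ""
        evidence = fields[3].strip() if len(fields) > 3 else "experimental"
        if evidence.lower() != "experimental":
            continue
        key = frozenset((a, b))
        if key in seen:
            continue
        seen.add(key)
        edges.append((a, b, source, evidence))
    return edges


def build_induced_network(
    edges: Iterable[Edge], query_nodes: set[str]
) -> InteractionNetwork:
    """Keep edges with both endpoints in ``query_nodes``; drop self-loops
    and nodes that end up isolated."""
    if not query_nodes:
        raise ValueError("query_nodes must be non-empty")
    graph = nx.Graph()
    for a, b, source, evidence in edges:
        if a == b:
            continue
        if a in query_nodes and b in query_nodes:
            graph.add_edge(a, b, source=source, evidence=evidence)
    # nodes only enter via edges, so no isolates can exist; assert the contract
    assert all(d > 0 for _, d in graph.degree)
    return InteractionNetwork(graph=graph)


def degree_ranking(network: InteractionNetwork, n: int) -> list[tuple[str, int]]:
    """Top-n nodes by degree, descending; ties lexicographic by symbol."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(network.graph.degree, key=lambda kv: (-kv[1], kv[0]))
    return [(sym, int(deg)) for sym, deg in ranked[:n]]


def export_network_gexf(network: InteractionNetwork, path: str) -> None:
    """GEXF 1.2 export with a ``degree`` node attribute."""
    graph = network.graph.copy()
    for node in graph.nodes:
        graph.nodes[node]["degree"] = int(graph.degree[node])
    nx.write_gexf(graph, path, version="1.2draft")


def ranking_to_tsv(ranking: Iterable[tuple[str, int]], stream: TextIO) -> None:
    stream.write("node\tdegree\n")
    for symbol, degree in ranking:
        stream.write(f"{symbol}\t{degree}\n")
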