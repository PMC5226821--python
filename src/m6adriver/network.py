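"""Reference protein-protein interaction network: parsing, cleaning, queries.

The network is an undirected simple graph over gene symbols.  Gene identity
is exact string match (case preserved): mapping aliases between resources is
a data-curation step that happens before this package sees the file.
Preprocessing removes self-interactions and isolated proteins, after which
every node has degree >= 1 and every edge is an unordered, deduplicated pair.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import networkx as nx

from .errors import EmptyNetworkError, FormatError, MissingNodeError

logger = logging.getLogger(__name__)


class _Unreachable:
    """Sentinel for node pairs in different connected components."""

    def __repr__(self) -> str:  # pragma: no cover
        return "UNREACHABLE"

    def __eq__(self, other) -> bool:
        return isinstance(other, _Unreachable)

    def __hash__(self) -> int:
        return hash("UNREACHABLE")


UNREACHABLE = _Unreachable()

#: Default interactor-symbol columns of a BioGRID TAB 3.0 export.
BIOGRID_SYMBOL_COLUMNS = (
    "Official Symbol Interactor A",
    "Official Symbol Interactor B",
)


def read_edge_list(
    path: str | Path,
    fmt: str = "tsv2col",
    symbol_columns: tuple[str, str] = BIOGRID_SYMBOL_COLUMNS,
) -> nx.Graph:
    """Parse an edge list into a raw undirected graph.

    ``fmt='tsv2col'`` reads the first two tab-separated columns of each
    non-comment row; ``fmt='biogrid_tab'`` reads a tab-delimited file whose
    header names the two interactor-symbol columns (``symbol_columns``).
    Self-loops survive until :func:`preprocess_network`; duplicate edges are
    collapsed by the graph container.
    """
    path = Path(path)
    graph = nx.Graph()
    if fmt == "tsv2col":
        with open(path) as handle:
            for line in handle:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise FormatError(
                        f"{path}: expected >=2 tab-separated columns, got {line!r}"
                    )
                graph.add_edge(parts[0], parts[1])
    elif fmt == "biogrid_tab":
        with open(path) as handle:
            header_line = handle.readline().rstrip("\n")
            header = header_line.lstrip("#").split("\t")
            try:
                col_a = header.index(symbol_columns[0])
                col_b = header.index(symbol_columns[1])
            except ValueError as exc:
                missing = [c for c in symbol_columns if c not in header]
                raise FormatError(
                    f"{path}: missing required column(s) {missing}"
                ) from exc
            for line in handle:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                graph.add_edge(parts[col_a], parts[col_b])
    else:
        raise ValueError(f"unknown edge-list format {fmt!r}")

    if graph.number_of_edges() == 0:
        raise EmptyNetworkError(f"{path}: no edges parsed")
    return graph


def preprocess_network(graph: nx.Graph) -> nx.Graph:
    """Drop self-interactions, then proteins left without any interaction.

    Returns a new graph; idempotent on already-clean input.
    """
    clean = graph.copy()
    loops = list(nx.selfloop_edges(clean))
    clean.remove_edges_from(loops)
    isolated = [n for n, d in clean.degree() if d == 0]
    clean.remove_nodes_from(isolated)
    if loops or isolated:
        logger.info(
            "preprocess: removed %d self-loop(s) and %d isolated node(s)",
            len(loops),
            len(isolated),
        )
    if clean.number_of_nodes() == 0:
        raise EmptyNetworkError("network is empty after preprocessing")
    return clean


def degree_classes(graph: nx.Graph) -> list[int]:
    """Distinct node degrees of a preprocessed network, strictly increasing."""
    return sorted({d for _, d in graph.degree()})


def shortest_path_length(graph: nx.Graph, u: str, v: str) -> int | _Unreachable:
    """Unweighted shortest-path distance L between two distinct nodes.

    Returns :data:`UNREACHABLE` when the nodes lie in different components.
    """
    for node in (u, v):
        if node not in graph:
            raise MissingNodeError(node)
    try:
        return nx.shortest_path_length(graph, u, v)
    except nx.NetworkXNoPath:
        return UNREACHABLE


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Write the network as a two-column TSV (sorted, reproducible)."""
    with open(path, "w") as handle:
        handle.write("#gene_a\tgene_b\n")
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges()):
            handle.write(f"{u}\t{v}\n")


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def network_hash(graph: nx.Graph) -> str:
    """Order-independent hash of the edge set, used as model provenance."""
    edges = sorted(tuple(sorted(e)) for e in graph.edges())
    digest = hashlib.sha256("\n".join(f"{u}\t{v}" for u, v in edges).encode())
    return digest.hexdigest()[:16]
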