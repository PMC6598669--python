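"""Gene interaction networks: reading, filtering, ID mapping, and summary statistics.

Networks are undirected simple graphs over opaque, case-sensitive gene
identifiers, held as :class:`networkx.Graph` objects. Duplicate and reversed
edge rows collapse to a single undirected edge; self-loops are dropped (and
counted in the log). Interaction counts from the common public resources
(STRING, BioGrid, Pathway Commons) are treated as undirected edges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkStats",
    "read_edge_list",
    "write_edge_list",
    "read_gene_list",
    "read_id_map",
    "map_ids",
    "induced_subnetwork",
    "density",
    "truncate_decimals",
    "network_stats",
]


@dataclass(frozen=True)
class NetworkStats:
    """Summary statistics of an interaction network.

    ``density`` uses the undirected convention 2E / (N(N-1)) and is NaN for
    fewer than two nodes. ``diameter`` is the longest shortest path within the
    largest connected component, or None for an edgeless network.
    """

    n_nodes: int
    n_edges: int
    density: float
    diameter: int | None


def read_edge_list(
    path: str | Path,
    score_column: int | None = None,
    min_score: float | None = None,
) -> nx.Graph:
    """Read a tab/whitespace-separated edge list into an undirected simple graph.

    Parameters
    ----------
    path
        Text file with at least two columns per non-comment line; lines
        starting with ``#`` are skipped.
    score_column
        1-based column index holding a numeric confidence score.
    min_score
        When given together with ``score_column``, rows scoring below this
        threshold are dropped (STRING-style confidence filtering).

    Raises
    ------
    ValueError
        On a malformed line (too few columns, or a non-numeric score),
        reported with its line number.
    """
    path = Path(path)
    net: nx.Graph = nx.Graph()
    n_self_loops = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 columns, got {len(fields)}")
            a, b = fields[0], fields[1]
            if score_column is not None and min_score is not None:
                if len(fields) < score_column:
                    raise ValueError(f"{path}:{lineno}: no score column {score_column}")
                try:
                    score = float(fields[score_column - 1])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric score {fields[score_column - 1]!r}") from exc
                if score < min_score:
                    continue
            if a == b:
                n_self_loops += 1
                continue
            net.add_edge(a, b)
    if n_self_loops:
        logger.info("read_edge_list(%s): dropped %d self-loop row(s)", path, n_self_loops)
    return net


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    """Write a network as a two-column TSV, one undirected edge per line."""
    with Path(path).open("w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.edges()):
            fh.write(f"{a}\t{b}\n")


def read_gene_list(path: str | Path) -> set[str]:
    """Read a plain-text gene list (one identifier per line, '#' comments)."""
    genes: set[str] = set()
    with Path(path).open() as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return genes


def read_id_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV of (source identifier, target identifier).

    The mapping must be a function: a source appearing twice with different
    targets is an error.
    """
    idmap: dict[str, str] = {}
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            src, tgt = fields[0], fields[1]
            if src in idmap and idmap[src] != tgt:
                raise ValueError(f"{path}:{lineno}: {src!r} maps to both {idmap[src]!r} and {tgt!r}")
            idmap[src] = tgt
    return idmap


def map_ids(genes: Iterable[str], idmap: Mapping[str, str]) -> tuple[set[str], list[str]]:
    """Translate identifiers through a many-to-one map.

    Returns the set of mapped target identifiers and the sorted list of
    inputs with no entry in the map. Unmapped genes are a report, not an
    error; the map never invents identifiers.
    """
    mapped: set[str] = set()
    unmapped: list[str] = []
    for g in genes:
        if g in idmap:
            mapped.add(idmap[g])
        else:
            unmapped.append(g)
    return mapped, sorted(unmapped)


def induced_subnetwork(net: nx.Graph, genes: Iterable[str]) -> nx.Graph:
    """Subnetwork on ``net.nodes & genes`` keeping edges with both endpoints inside.

    This is how a pathway subnetwork is extracted from a complete interaction
    network given the pathway's gene list.
    """
    keep = set(genes) & set(net.nodes)
    return nx.Graph(net.subgraph(keep))


def density(n_nodes: int, n_edges: int) -> float:
    """Undirected density 2E / (N(N-1)); NaN when N < 2."""
    if n_nodes < 2:
        return math.nan
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def truncate_decimals(x: float, ndigits: int = 4) -> float:
    """Truncate (not round) toward zero at ``ndigits`` decimal places."""
    factor = 10**ndigits
    return math.trunc(x * factor) / factor


def network_stats(net: nx.Graph) -> NetworkStats:
    """Node/edge counts, undirected density, and largest-component diameter."""
    n, e = net.number_of_nodes(), net.number_of_edges()
    if e == 0:
        diam = None
    else:
        components = list(nx.connected_components(net))
        giant = max(components, key=len)
        if len(components) > 1:
            logger.info("network_stats: diameter computed on largest component (%d of %d nodes)", len(giant), n)
        diam = nx.diameter(net.subgraph(giant))
    return NetworkStats(n_nodes=n, n_edges=e, density=density(n, e), diameter=diam)
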