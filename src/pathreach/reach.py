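"""m-reach topology: per-gene reach fractions and quantile reach levels.

The m-reach of a gene is the number of unique network nodes reachable from it
in m links or fewer (the node itself excluded), divided by the network size.
It generalizes the degree (1-reach is degree / N). Sorting the network by
m-reach and cutting into equal-count segments yields reach *levels*:
Level 1 holds the best-connected genes, the last level the least connected.
Gene interaction networks are small-world, so a small m already spans a large
fraction of the network; m = 2 gives the broadest, most discriminating
reach distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["ReachProfile", "ReachLevels", "m_reach", "nominal_level_size", "assign_levels", "reach_distribution"]


@dataclass(frozen=True)
class ReachProfile:
    """Per-gene reach fractions for a fixed step count m.

    ``values`` is indexed by gene identifier; every network node has an entry.
    With the default denominator (network size N) values lie in [0, 1);
    with the N-1 convention a node seeing the whole network scores exactly 1.
    """

    m: int
    values: pd.Series
    denominator: str = "n"


@dataclass(frozen=True)
class ReachLevels:
    """Quantile partition of a reach profile.

    ``assignment`` maps gene -> level in 1..n_levels (1 = highest reach).
    ``cutpoints`` holds the maximum reach value inside each level;
    ``min_reach`` the overall minimum. ``nominal_per_level`` is floor(N / n_levels),
    the headline per-quantile count (actual sizes differ by at most 1).
    """

    n_levels: int
    assignment: pd.Series
    cutpoints: dict[int, float] = field(repr=False)
    min_reach: float = 0.0
    nominal_per_level: int = 0

    def level_sizes(self) -> dict[int, int]:
        counts = self.assignment.value_counts()
        return {lvl: int(counts.get(lvl, 0)) for lvl in range(1, self.n_levels + 1)}


def m_reach(net: nx.Graph, m: int, denominator: str = "n") -> ReachProfile:
    """Compute the m-reach fraction of every node.

    Parameters
    ----------
    net
        Undirected interaction network; must be non-empty.
    m
        Step count (>= 1). Reach counts nodes at shortest-path distance
        1..m; the source node never counts toward its own reach.
    denominator
        ``"n"`` divides by the total node count N (default); ``"n-1"``
        divides by N-1 so that full access scores exactly 1.0.

    Isolated nodes have reach 0.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("network is empty")
    if denominator not in ("n", "n-1"):
        raise ValueError(f"unknown denominator convention {denominator!r}")
    denom = n if denominator == "n" else max(n - 1, 1)
    values = {
        node: (len(nx.single_source_shortest_path_length(net, node, cutoff=m)) - 1) / denom
        for node in net.nodes
    }
    series = pd.Series(values, dtype=float).sort_index()
    return ReachProfile(m=m, values=series, denominator=denominator)


def nominal_level_size(n_nodes: int, n_levels: int = 4) -> int:
    """Nominal per-quantile node count, floor(N / n_levels)."""
    return n_nodes // n_levels


def assign_levels(profile: ReachProfile, n_levels: int = 4) -> ReachLevels:
    """Partition genes into equal-count reach levels.

    Genes are sorted by reach descending with ties broken by gene identifier
    ascending, so the assignment is reproducible across runs and input
    orderings. The sorted list is cut into ``n_levels`` contiguous segments
    whose sizes differ by at most one; remainder nodes go to the
    highest-reach levels first. Cutpoints report each level's maximum reach.
    """
    values = profile.values
    n = len(values)
    if n == 0:
        raise ValueError("empty reach profile")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if n_levels > n:
        raise ValueError(f"n_levels={n_levels} exceeds node count {n}")

    order = sorted(values.index, key=lambda g: (-values[g], g))
    base, rem = divmod(n, n_levels)
    sizes = [base + (1 if lvl <= rem else 0) for lvl in range(1, n_levels + 1)]

    assignment: dict[str, int] = {}
    cutpoints: dict[int, float] = {}
    pos = 0
    for lvl, size in enumerate(sizes, start=1):
        segment = order[pos : pos + size]
        for g in segment:
            assignment[g] = lvl
        cutpoints[lvl] = float(values[segment[0]]) if segment else float("nan")
        pos += size

    return ReachLevels(
        n_levels=n_levels,
        assignment=pd.Series(assignment, dtype=int).sort_index(),
        cutpoints=cutpoints,
        min_reach=float(values.min()),
        nominal_per_level=nominal_level_size(n, n_levels),
    )


def reach_distribution(profile: ReachProfile, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of reach values over [0, 1]; returns (bin_edges, counts)."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    counts, edges = np.histogram(profile.values.to_numpy(), bins=n_bins, range=(0.0, 1.0))
    return edges, counts
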