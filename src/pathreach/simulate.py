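"""Synthetic networks, pathway databases and planted driver sets.

Everything the method consumes can be simulated so the full pipeline is
testable without downloading interaction or pathway databases:

* a connected, degree-skewed interaction network (preferential-attachment
  growth, emulating the hub-dominated small-world structure of real
  protein-interaction networks);
* overlapping pathway gene sets of varying size;
* a *reference* driver set with the joint structure the method detects:
  reference drivers are drawn degree-weighted (drivers sit at network hubs)
  and each is seeded into a "core" pathway specific to its own 2-reach
  level, so reference drivers of the same connectivity level also share
  pathway membership — pathway resemblance and reach resemblance are
  correlated across the reference set, the way driver genes cluster into
  pathway communities tied to their network position;
* a *planted* driver set whose resemblance to the reference set is
  controlled by an ``enrichment`` probability. An enriched planted gene
  copies the pathway memberships of a randomly chosen reference template
  and is chosen from the template's 2-reach level, so the drivers it is
  pathway-similar to are the same drivers it is reach-similar to (the
  joint (1,1) contingency cell); a non-enriched one is a random gene left
  untouched.

All randomness flows from one seed through numpy ``SeedSequence`` child
streams (0 = network, 1 = pathways, 2 = planting), so fixtures are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .pathways import PathwayDB
from .reach import ReachLevels, assign_levels, m_reach

__all__ = ["SyntheticConfig", "PlantedScenario", "simulate_network", "simulate_pathways", "plant_drivers", "simulate_scenario"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic scenario.

    ``enrichment`` is the probability that a planted driver copies a
    reference driver's pathway memberships and shares its reach level
    (1.0 = fully planted signal, 0.0 = pure null). ``channels`` restricts
    which resemblance channels are enriched, to probe how the joint test
    loses power when only one channel carries signal.
    """

    n_genes: int = 200
    edges_per_new_node: int = 3
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (5, 15)
    n_reference_drivers: int = 40
    n_planted_drivers: int = 20
    enrichment: float = 1.0
    n_levels: int = 4
    channels: tuple[str, ...] = ("pathway", "reach")
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.enrichment <= 1.0):
            raise ValueError("enrichment must lie in [0, 1]")
        if min(self.n_genes, self.n_pathways, self.n_reference_drivers, self.n_planted_drivers) < 1:
            raise ValueError("counts must be positive")
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi <= self.n_genes):
            raise ValueError("invalid pathway size range")
        if self.n_genes < self.edges_per_new_node + 1:
            raise ValueError("n_genes must exceed edges_per_new_node")
        unknown = set(self.channels) - {"pathway", "reach"}
        if unknown:
            raise ValueError(f"unknown channels {sorted(unknown)}")


@dataclass(frozen=True)
class PlantedScenario:
    """Outcome of planting: reference/planted sets, modified pathway DB and reports."""

    reference: frozenset[str]
    planted: frozenset[str]
    db: PathwayDB = field(repr=False)
    templates: dict[str, str | None] = field(repr=False)  # planted gene -> copied reference gene
    levels: ReachLevels = field(repr=False)  # 2-reach levels used for the reach channel


def _streams(seed: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(3)
    return [np.random.default_rng(c) for c in children]


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


def simulate_network(config: SyntheticConfig) -> nx.Graph:
    """Grow a connected degree-skewed network by preferential attachment.

    Growth rule: start from a triangle (3 nodes, 3 edges); each subsequent
    node attaches to ``edges_per_new_node`` distinct existing nodes chosen
    with probability proportional to current degree. The edge count is
    therefore exactly 3 + (n - 3) * edges_per_new_node for n > 3.
    """
    rng = _streams(config.seed)[0]
    n, m = config.n_genes, config.edges_per_new_node
    net: nx.Graph = nx.Graph()
    if n <= 3:
        net.add_nodes_from(_gene_name(i) for i in range(n))
        if n >= 2:
            net.add_edge(_gene_name(0), _gene_name(1))
        if n == 3:
            net.add_edges_from([(_gene_name(0), _gene_name(2)), (_gene_name(1), _gene_name(2))])
        return net
    net.add_edges_from([(_gene_name(0), _gene_name(1)), (_gene_name(0), _gene_name(2)), (_gene_name(1), _gene_name(2))])
    # endpoint multiset: sampling from it is degree-proportional
    endpoints: list[str] = [_gene_name(0), _gene_name(1), _gene_name(2)] * 2
    for i in range(3, n):
        new = _gene_name(i)
        k = min(m, i)
        targets: set[str] = set()
        while len(targets) < k:
            targets.add(endpoints[rng.integers(len(endpoints))])
        for t in sorted(targets):
            net.add_edge(new, t)
            endpoints.extend([new, t])
    return net


def simulate_pathways(net: nx.Graph, config: SyntheticConfig) -> PathwayDB:
    """Draw overlapping pathway gene sets uniformly over the network's genes."""
    rng = _streams(config.seed)[1]
    genes = np.array(sorted(net.nodes))
    lo, hi = config.pathway_size_range
    db: PathwayDB = {}
    for k in range(config.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        db[f"PW{k + 1:03d}"] = set(members.tolist())
    return db


def plant_drivers(net: nx.Graph, db: PathwayDB, config: SyntheticConfig) -> PlantedScenario:
    """Choose reference drivers and plant a driver set with tunable resemblance.

    Reference drivers are sampled without replacement, degree-weighted, from
    the high-connectivity half of the 2-reach ranking (levels 1..n_levels/2)
    — curated driver sets are strongly enriched for network hubs, and
    restricting to the well-populated levels keeps every reference
    community large enough to resemble. One dedicated *core* pathway per
    occupied reach level (``CORE_L1`` ...) collects the reference drivers of
    that level,
    emulating the driver-community pathways curated databases contain, so
    reference drivers of the same connectivity level also share pathway
    membership. Each planted slot then flips an
    ``enrichment`` coin: on success a reference template is drawn and the
    planted gene (a) is selected from the template's 2-reach level when the
    "reach" channel is on, and (b) has its pathway memberships overwritten
    to the template's when the "pathway" channel is on; on failure a random
    non-reference gene is planted untouched. Reference and planted sets are
    disjoint.
    """
    rng = _streams(config.seed)[2]
    genes = sorted(net.nodes)
    if config.n_reference_drivers + config.n_planted_drivers > len(genes):
        raise ValueError("not enough genes for disjoint reference and planted sets")
    db = {name: set(members) for name, members in db.items()}

    levels = assign_levels(m_reach(net, m=2), n_levels=config.n_levels)
    hub_levels = max(1, config.n_levels // 2)
    eligible = [g for g in genes if levels.assignment[g] <= hub_levels]
    if config.n_reference_drivers > len(eligible):
        raise ValueError("not enough hub-level genes for the reference set")
    weights = np.array([net.degree(g) for g in eligible], dtype=float) + 1.0
    reference = [
        str(g)
        for g in rng.choice(eligible, size=config.n_reference_drivers, replace=False,
                            p=weights / weights.sum())
    ]
    for ref in reference:
        db.setdefault(f"CORE_L{int(levels.assignment[ref])}", set()).add(ref)

    ref_set = set(reference)
    available = [g for g in genes if g not in ref_set]
    by_level: dict[int, list[str]] = {}
    for g in available:
        by_level.setdefault(int(levels.assignment[g]), []).append(g)

    planted: list[str] = []
    templates: dict[str, str | None] = {}
    used: set[str] = set()
    for _ in range(config.n_planted_drivers):
        enriched = rng.random() < config.enrichment
        template = str(reference[rng.integers(len(reference))]) if enriched else None
        if enriched and "reach" in config.channels:
            pool = [g for g in by_level.get(int(levels.assignment[template]), []) if g not in used]
            if not pool:
                pool = [g for g in available if g not in used]
        else:
            pool = [g for g in available if g not in used]
        if not pool:
            raise ValueError("ran out of genes while planting drivers")
        gene = str(pool[rng.integers(len(pool))])
        used.add(gene)
        planted.append(gene)
        templates[gene] = template
        if enriched and "pathway" in config.channels:
            for members in db.values():
                members.discard(gene)
            for name in sorted(db):
                if template in db[name]:
                    db[name].add(gene)
    db = {name: members for name, members in db.items() if members}
    return PlantedScenario(
        reference=frozenset(reference),
        planted=frozenset(planted),
        db=db,
        templates=templates,
        levels=levels,
    )


def simulate_scenario(config: SyntheticConfig) -> tuple[nx.Graph, PlantedScenario]:
    """Network + pathways + planting in one call (shared seed streams)."""
    net = simulate_network(config)
    db = simulate_pathways(net, config)
    return net, plant_drivers(net, db, config)
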