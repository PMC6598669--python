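"""End-to-end orchestration of a pathway-and-reach run.

The full pipeline: load network -> (optional ID mapping) -> m-reach on the
FULL network -> reach levels -> binary similarity matrices P (pathway,
Jaccard-thresholded) and R (shared reach level) against the reference
drivers -> resampled Fisher p-values -> Benjamini-Hochberg correction ->
gene scores -> candidate selection -> optional classifier evaluation.

Reach is deliberately computed on the complete interaction network, not the
pathway subnetwork: levels rank genes within the total network, and the
induced pathway subnetwork is used only for reporting subnetwork statistics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import AbstractSet, Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from . import __version__
from .evaluation import ConfusionMetrics, RocCurve, confusion, roc_curve
from .network import induced_subnetwork, network_stats
from .pathways import DEFAULT_JSI_CUTOFF, PathwayDB, pathway_similarity_matrix
from .reach import ReachLevels, assign_levels, m_reach
from .stats import adjust_matrix, candidate_table, resample_pvalues, select_candidates

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ParResult", "run_par", "compare_reach_orders", "derive_reference_sets", "VennPartition", "write_artifacts"]


@dataclass(frozen=True)
class RunConfig:
    """File-based configuration for a command-line run (flags mirror these names)."""

    network: str
    gmt: str
    drivers: str
    cd_pathway: str | None = None  # cdGenes = members of this pathway in the GMT
    cd_genes: str | None = None  # ... or an explicit gene-list file
    id_map: str | None = None
    score_column: int | None = None
    min_score: float | None = None
    m: int = 2
    n_levels: int = 4
    jsi_cutoff: float = DEFAULT_JSI_CUTOFF
    reps: int = 1000
    subset_size: int = 50
    alpha: float = 0.05
    gs_max: float = 1.0
    alternative: str = "greater"
    bh_scope: str = "per_replicate"
    seed: int | None = None
    gold: str | None = None
    outdir: str = "pathreach_out"

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.subset_size < 2:
            raise ValueError("subset_size must be >= 2")
        if (self.cd_pathway is None) == (self.cd_genes is None):
            raise ValueError("give exactly one of cd_pathway or cd_genes")


@dataclass
class ParResult:
    """All artifacts of one pipeline run."""

    levels: ReachLevels
    P: pd.DataFrame
    R: pd.DataFrame
    pvalues: pd.DataFrame  # nominal, genes x replicates
    adjusted: pd.DataFrame  # BH-adjusted, same shape
    candidates: pd.DataFrame  # per-gene GS table (ascending GS)
    selected: list[str]  # GS <= gs_max, ranked
    novel: list[str]  # selected minus known drivers
    subnetwork_stats: dict = field(default_factory=dict)
    metrics: ConfusionMetrics | None = None
    roc: RocCurve | None = None
    log: dict = field(default_factory=dict)


def run_par(
    net: nx.Graph,
    db: PathwayDB,
    cd_genes: Iterable[str],
    drivers: Iterable[str],
    *,
    m: int = 2,
    n_levels: int = 4,
    jsi_cutoff: float = DEFAULT_JSI_CUTOFF,
    reps: int = 1000,
    subset_size: int = 50,
    alpha: float = 0.05,
    gs_max: float = 1.0,
    alternative: str = "greater",
    bh_scope: str = "per_replicate",
    seed: int | None = None,
    gold: AbstractSet[str] | None = None,
) -> ParResult:
    """Run the full pathway-and-reach pipeline on in-memory inputs.

    ``cd_genes`` are the candidate genes (typically the full gene complement
    of one pathway); ``drivers`` the reference driver pool from which
    ``subset_size``-gene subsets are resampled ``reps`` times. ``gold``
    triggers classifier evaluation over the candidate universe.
    """
    cd = sorted(set(cd_genes) & set(net.nodes))
    dr = sorted(set(drivers) & set(net.nodes))
    dropped_cd = len(set(cd_genes)) - len(cd)
    dropped_dr = len(set(drivers)) - len(dr)
    if not cd:
        raise ValueError("no candidate genes present in the network (check ID mapping)")
    if not dr:
        raise ValueError("no reference drivers present in the network (check ID mapping)")
    if dropped_cd or dropped_dr:
        logger.info("run_par: dropped %d candidate and %d driver gene(s) absent from the network",
                    dropped_cd, dropped_dr)

    profile = m_reach(net, m=m)  # full network, not the pathway subnetwork
    levels = assign_levels(profile, n_levels=n_levels)
    P = pathway_similarity_matrix(db, cd, dr, jsi_cutoff=jsi_cutoff)
    from .stats import reach_similarity_matrix  # local to keep module surfaces explicit

    R = reach_similarity_matrix(levels, cd, dr)
    pvals = resample_pvalues(P, R, dr, reps=reps, subset_size=subset_size,
                             seed=seed, alternative=alternative)
    adjusted = adjust_matrix(pvals, scope=bh_scope)
    table = candidate_table(adjusted, known_drivers=dr, alpha=alpha)
    selected, novel = select_candidates(table, known_drivers=dr, gs_max=gs_max)

    sub = induced_subnetwork(net, cd)
    sub_stats = dataclasses.asdict(network_stats(sub)) | {"n_known_drivers": len(set(dr) & set(sub.nodes))}

    metrics = roc = None
    if gold is not None:
        universe = set(cd)
        metrics = confusion(set(selected) & universe, set(gold), universe)
        roc = roc_curve({g: float(table.at[g, "gs"]) for g in cd}, set(gold), universe)

    result = ParResult(
        levels=levels, P=P, R=R, pvalues=pvals, adjusted=adjusted,
        candidates=table, selected=selected, novel=novel,
        subnetwork_stats=sub_stats, metrics=metrics, roc=roc,
        log={
            "version": __version__,
            "m": m, "n_levels": n_levels, "jsi_cutoff": jsi_cutoff,
            "reps": reps, "subset_size": subset_size, "alpha": alpha,
            "gs_max": gs_max, "alternative": alternative, "bh_scope": bh_scope,
            "seed": seed,
            "n_candidates_in_network": len(cd), "n_drivers_in_network": len(dr),
            "n_candidates_dropped": dropped_cd, "n_drivers_dropped": dropped_dr,
        },
    )
    return result


def compare_reach_orders(
    net: nx.Graph,
    db: PathwayDB,
    cd_genes: Iterable[str],
    drivers: Iterable[str],
    gold: AbstractSet[str],
    m_values: Sequence[int] = (1, 2, 3),
    **kwargs,
) -> dict[int, ParResult]:
    """One full run per reach order m, identical inputs and seed throughout.

    Used to ask which m best separates known drivers from the rest
    (ROC/AUC per m); everything except the reach order is held fixed.
    """
    return {
        m: run_par(net, db, cd_genes, drivers, m=m, gold=gold, **kwargs)
        for m in m_values
    }


@dataclass(frozen=True)
class VennPartition:
    """Overlap structure of several driver gene lists."""

    union: frozenset[str]
    overlap_counts: dict[int, int]  # genes present in exactly k lists -> count
    in_all: frozenset[str]  # dr3Genes-style reference set
    in_at_least_two: frozenset[str]  # dr2Genes-style reference set


def derive_reference_sets(lists: Sequence[AbstractSet[str]]) -> VennPartition:
    """Venn partition of 2-3 driver lists and the derived reference sets.

    ``in_all`` is the strict intersection (the primary reference set);
    ``in_at_least_two`` the genes supported by two or more lists (the
    extended reference set used for evaluation).
    """
    if len(lists) < 2:
        raise ValueError("need at least 2 driver lists")
    sets = [set(s) for s in lists]
    union = set().union(*sets)
    member_count = {g: sum(g in s for s in sets) for g in union}
    counts = {k: sum(1 for v in member_count.values() if v == k) for k in range(1, len(sets) + 1)}
    return VennPartition(
        union=frozenset(union),
        overlap_counts=counts,
        in_all=frozenset(g for g, v in member_count.items() if v == len(sets)),
        in_at_least_two=frozenset(g for g, v in member_count.items() if v >= 2),
    )


def write_artifacts(result: ParResult, outdir: str | Path) -> None:
    """Write plain-text run artifacts: CSV/TSV tables plus a JSON manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.candidates.to_csv(out / "candidates.csv")
    result.adjusted.to_csv(out / "pvalues.csv")
    result.levels.assignment.rename("level").to_csv(out / "levels.tsv", sep="\t")
    stats = {
        "subnetwork": result.subnetwork_stats,
        "level_sizes": result.levels.level_sizes(),
        "cutpoints": result.levels.cutpoints,
        "min_reach": result.levels.min_reach,
        "nominal_per_level": result.levels.nominal_per_level,
        "n_selected": len(result.selected),
        "n_novel": len(result.novel),
        "log": result.log,
    }
    (out / "stats.json").write_text(json.dumps(stats, indent=2, default=str) + "\n")
    if result.metrics is not None:
        (out / "metrics.json").write_text(
            json.dumps(dataclasses.asdict(result.metrics), indent=2) + "\n")
    if result.roc is not None:
        pd.DataFrame({"fpr": result.roc.fpr, "tpr": result.roc.tpr}).to_csv(out / "roc.csv", index=False)
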