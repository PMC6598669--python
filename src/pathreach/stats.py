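"""Statistical core of the pathway-and-reach method.

For each candidate gene the binary pathway-similarity row (matrix P) and
reach-similarity row (matrix R) over a random subset of reference drivers
are cross-tabulated into a 2x2 contingency table

    ============  =========  =========
    .             Reach (1)  Reach (0)
    Pathway (1)       A          B
    Pathway (0)       C          D
    ============  =========  =========

and tested with Fisher's exact test. Repeating over many random reference
subsets yields a p-value matrix (genes x replicates), which is adjusted for
false discovery (Benjamini-Hochberg) and summarized per gene by the score

    GS = count(p > alpha) / n_replicates + mean(p),      GS in [0, 2]

where lower is more driver-like; GS <= 1 defines candidacy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .reach import ReachLevels

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "reach_similarity_matrix",
    "contingency",
    "fisher_exact",
    "resample_pvalues",
    "bh_adjust",
    "adjust_matrix",
    "gene_score",
    "candidate_table",
    "select_candidates",
    "red_band_cluster",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of the four (pathway, reach) flag combinations over one driver subset."""

    A: int  # pathway 1, reach 1
    B: int  # pathway 1, reach 0
    C: int  # pathway 0, reach 1
    D: int  # pathway 0, reach 0

    @property
    def total(self) -> int:
        return self.A + self.B + self.C + self.D


def reach_similarity_matrix(
    levels: ReachLevels,
    cd_genes: Iterable[str],
    dr_genes: Iterable[str],
) -> pd.DataFrame:
    """Binary matrix R: entry(r, c) = 1 iff candidate r and driver c share a reach level.

    Genes absent from the level assignment (i.e. not in the network) are
    dropped with a logged warning.
    """
    assignment = levels.assignment
    cd = sorted(set(cd_genes))
    dr = sorted(set(dr_genes))
    if not cd or not dr:
        raise ValueError("cd_genes and dr_genes must both be non-empty")
    cd_known = [g for g in cd if g in assignment.index]
    dr_known = [g for g in dr if g in assignment.index]
    dropped = (set(cd) - set(cd_known)) | (set(dr) - set(dr_known))
    if dropped:
        logger.warning("reach_similarity_matrix: dropped %d gene(s) absent from the network: %s",
                       len(dropped), ", ".join(sorted(dropped)[:10]))
    if not cd_known or not dr_known:
        raise ValueError("no candidate/driver genes left after dropping genes absent from the network")
    lv_cd = assignment[cd_known].to_numpy()[:, None]
    lv_dr = assignment[dr_known].to_numpy()[None, :]
    return pd.DataFrame((lv_cd == lv_dr).astype(int), index=cd_known, columns=dr_known)


def contingency(
    p_row: pd.Series,
    r_row: pd.Series,
    columns: Sequence[str] | None = None,
) -> ContingencyTable:
    """Cross-tabulate one pathway row against one reach row over selected columns."""
    if columns is not None:
        missing = [c for c in columns if c not in p_row.index or c not in r_row.index]
        if missing:
            raise ValueError(f"columns not shared by both rows: {missing[:5]}")
        p_row = p_row[list(columns)]
        r_row = r_row[list(columns)]
    elif not p_row.index.equals(r_row.index):
        raise ValueError("p_row and r_row must share column labels")
    if len(p_row) == 0:
        raise ValueError("empty column subset")
    p = p_row.to_numpy().astype(bool)
    r = r_row.to_numpy().astype(bool)
    return ContingencyTable(
        A=int((p & r).sum()),
        B=int((p & ~r).sum()),
        C=int((~p & r).sum()),
        D=int((~p & ~r).sum()),
    )


@lru_cache(maxsize=1_000_000)
def _fisher_cached(a: int, b: int, c: int, d: int, alternative: str) -> float:
    return float(scipy.stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])


def fisher_exact(table: ContingencyTable, alternative: str = "greater") -> float:
    """Exact hypergeometric p-value for a 2x2 table.

    ``alternative`` is one of ``greater`` (enrichment of the joint
    pathway-and-reach cell A, the default signal of interest), ``less`` or
    ``two_sided``. The all-zero table is degenerate and returns p = 1.
    """
    alt = {"two_sided": "two-sided"}.get(alternative, alternative)
    if alt not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if min(table.A, table.B, table.C, table.D) < 0:
        raise ValueError("negative count in contingency table")
    if table.total == 0:
        logger.debug("fisher_exact: degenerate all-zero table, p = 1")
        return 1.0
    return _fisher_cached(table.A, table.B, table.C, table.D, alt)


def resample_pvalues(
    P: pd.DataFrame,
    R: pd.DataFrame,
    driver_pool: Iterable[str],
    reps: int = 1000,
    subset_size: int = 50,
    seed: int | None = None,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Nominal Fisher p-values over resampled reference-driver subsets.

    For each of ``reps`` replicates one subset of ``subset_size`` drivers is
    drawn uniformly without replacement from ``driver_pool`` (independently
    across replicates); for every candidate gene the P/R contingency over
    that subset is Fisher-tested. Returns a genes x replicates DataFrame,
    reproducible given ``seed``.
    """
    pool = sorted(set(driver_pool) & set(P.columns) & set(R.columns))
    if subset_size > len(pool):
        raise ValueError(f"subset_size={subset_size} exceeds driver pool size {len(pool)}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    genes = [g for g in P.index if g in R.index]
    if not genes:
        raise ValueError("P and R share no row genes")

    p_arr = P.loc[genes, pool].to_numpy().astype(bool)
    r_arr = R.loc[genes, pool].to_numpy().astype(bool)
    rng = np.random.default_rng(seed)

    out = np.empty((len(genes), reps), dtype=float)
    for j in range(reps):
        idx = rng.choice(len(pool), size=subset_size, replace=False)
        ps, rs = p_arr[:, idx], r_arr[:, idx]
        a = (ps & rs).sum(axis=1)
        b = (ps & ~rs).sum(axis=1)
        c = (~ps & rs).sum(axis=1)
        d = (~ps & ~rs).sum(axis=1)
        for i in range(len(genes)):
            out[i, j] = fisher_exact(ContingencyTable(int(a[i]), int(b[i]), int(c[i]), int(d[i])),
                                     alternative=alternative)
    return pd.DataFrame(out, index=genes, columns=[f"rep{j + 1}" for j in range(reps)])


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr <= 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def adjust_matrix(pmat: pd.DataFrame, scope: str = "per_replicate") -> pd.DataFrame:
    """BH-adjust a p-value matrix.

    ``per_replicate`` (default) treats each replicate column as one family
    of tests across the candidate genes; ``global`` adjusts the flattened
    matrix as a single family.
    """
    if scope == "per_replicate":
        return pmat.apply(lambda col: pd.Series(bh_adjust(col.to_numpy()), index=col.index), axis=0)
    if scope == "global":
        flat = bh_adjust(pmat.to_numpy().ravel())
        return pd.DataFrame(flat.reshape(pmat.shape), index=pmat.index, columns=pmat.columns)
    raise ValueError(f"unknown BH scope {scope!r}")


def gene_score(pvalues: Sequence[float] | np.ndarray, alpha: float = 0.05) -> tuple[float, float, float]:
    """Gene score GS = count(p > alpha)/len + mean(p); returns (GS, freq, mean).

    The count divisor is the actual vector length, so reduced-replicate runs
    stay on the [0, 2] scale. Lower scores mark stronger candidates.
    """
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    freq = float((arr > alpha).sum()) / arr.size
    mean = float(arr.mean())
    return freq + mean, freq, mean


def candidate_table(
    pmat: pd.DataFrame,
    known_drivers: Iterable[str] = (),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene score table from an (adjusted) p-value matrix.

    Columns: ``gs``, ``freq_gt_alpha`` (count(p > alpha)/reps), ``mean_p``,
    ``rank`` (1 = best; ties broken by smaller mean then gene identifier)
    and ``known_driver``.
    """
    known = set(known_drivers)
    rows = []
    for gene in pmat.index:
        gs, freq, mean = gene_score(pmat.loc[gene].to_numpy(), alpha=alpha)
        rows.append((gene, gs, freq, mean, gene in known))
    df = pd.DataFrame(rows, columns=["gene", "gs", "freq_gt_alpha", "mean_p", "known_driver"]).set_index("gene")
    order = sorted(df.index, key=lambda g: (df.at[g, "gs"], df.at[g, "mean_p"], g))
    df["rank"] = pd.Series({g: i + 1 for i, g in enumerate(order)}, dtype=int)
    return df.loc[order]


def select_candidates(
    scores: pd.DataFrame,
    known_drivers: Iterable[str] = (),
    gs_max: float = 1.0,
) -> tuple[list[str], list[str]]:
    """Ranked candidates with GS <= gs_max, and the novel-only sublist.

    Returns (all_candidates, novel_candidates) in ascending-GS order with
    ties broken by smaller mean component, then gene identifier.
    """
    known = set(known_drivers)
    kept = scores[scores["gs"] <= gs_max]
    ranked = sorted(kept.index, key=lambda g: (kept.at[g, "gs"], kept.at[g, "mean_p"], g))
    novel = [g for g in ranked if g not in known]
    return ranked, novel


def red_band_cluster(pmat: pd.DataFrame, n_clusters: int) -> set[str]:
    """Genes in the lowest-mean-p cluster of a hierarchical row clustering.

    This mirrors the "red band" a clustered heatmap forms from genes with
    consistently low adjusted p-values: rows are clustered by average
    linkage on Euclidean distance and the cluster with the lowest mean
    p-value is returned. GS-threshold selection is the primary candidate
    path; this clustering corroborates it.
    """
    if len(pmat) == 1:
        return set(pmat.index)
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if n_clusters > len(pmat):
        raise ValueError(f"n_clusters={n_clusters} exceeds row count {len(pmat)}")
    # label-sorted rows so linkage tie-breaks do not depend on input order
    ordered = pmat.loc[sorted(pmat.index)]
    link = sch.linkage(ordered.to_numpy(), method="average", metric="euclidean")
    labels = sch.fcluster(link, t=n_clusters, criterion="maxclust")
    means = {lab: ordered.to_numpy()[labels == lab].mean() for lab in np.unique(labels)}
    best = min(sorted(means), key=lambda lab: means[lab])
    return set(ordered.index[labels == best])
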