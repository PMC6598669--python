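"""Pathway gene sets, membership profiles, and the binary pathway-similarity matrix P.

A pathway database maps pathway names to member gene sets (GMT format).
Two genes are pathway-similar when the Jaccard similarity index (JSI) of
their full membership lists reaches a cutoff; membership is always computed
against *all* pathways in the database, not only the pathway under analysis.
With a Reactome-scale listing the minimal nonzero JSI is about 0.0036, so
that default cutoff amounts to "shares at least one pathway".
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import AbstractSet, Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["PathwayDB", "read_gmt", "write_gmt", "membership", "membership_index", "jsi", "pathway_similarity_matrix"]

#: pathway name -> set of member gene identifiers
PathwayDB = dict[str, set[str]]

DEFAULT_JSI_CUTOFF = 0.0036


def read_gmt(path: str | Path) -> PathwayDB:
    """Read a GMT file: name, description, then member genes, tab-separated.

    Duplicate genes within a line are stored once. A line with fewer than
    three fields (no members) is an error.
    """
    db: PathwayDB = {}
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >= 1 gene")
            name = fields[0]
            if name in db:
                raise ValueError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            db[name] = {g for g in fields[2:] if g}
    return db


def write_gmt(db: PathwayDB, path: str | Path, description: str = "na") -> None:
    """Write a pathway database in GMT format (members name-sorted)."""
    with Path(path).open("w") as fh:
        for name in sorted(db):
            fh.write("\t".join([name, description, *sorted(db[name])]) + "\n")


def membership(db: Mapping[str, AbstractSet[str]], gene: str) -> list[str]:
    """All pathways containing ``gene``, name-sorted; empty list if none."""
    return sorted(name for name, members in db.items() if gene in members)


def membership_index(db: Mapping[str, AbstractSet[str]], genes: Iterable[str]) -> dict[str, frozenset[str]]:
    """Membership sets for many genes in one pass over the database."""
    genes = set(genes)
    idx: dict[str, set[str]] = {g: set() for g in genes}
    for name, members in db.items():
        for g in genes & set(members):
            idx[g].add(name)
    return {g: frozenset(s) for g, s in idx.items()}


def jsi(lr: AbstractSet[str], lc: AbstractSet[str]) -> float:
    """Jaccard similarity index |Lr ∩ Lc| / |Lr ∪ Lc|; 0 when both sets are empty."""
    if not lr and not lc:
        return 0.0
    inter = len(lr & lc)
    return inter / (len(lr) + len(lc) - inter)


def pathway_similarity_matrix(
    db: Mapping[str, AbstractSet[str]],
    cd_genes: Iterable[str],
    dr_genes: Iterable[str],
    jsi_cutoff: float = DEFAULT_JSI_CUTOFF,
    exclude_self: bool = False,
) -> pd.DataFrame:
    """Binary matrix P: candidate rows x reference-driver columns.

    entry(r, c) = 1 iff JSI(membership(r), membership(c)) >= jsi_cutoff.
    Genes with no pathway annotation produce all-zero rows/columns and are
    logged. When a candidate is itself a reference column, the self cell is
    kept by default (``exclude_self=True`` zeroes it instead).
    """
    cd = sorted(set(cd_genes))
    dr = sorted(set(dr_genes))
    if not cd or not dr:
        raise ValueError("cd_genes and dr_genes must both be non-empty")
    if not (0.0 < jsi_cutoff <= 1.0):
        raise ValueError(f"jsi_cutoff must be in (0, 1], got {jsi_cutoff}")

    idx = membership_index(db, set(cd) | set(dr))
    unannotated = sorted(g for g in set(cd) | set(dr) if not idx[g])
    if unannotated:
        logger.info("pathway_similarity_matrix: %d gene(s) with no pathway membership: %s",
                    len(unannotated), ", ".join(unannotated[:10]))

    mat = pd.DataFrame(0, index=cd, columns=dr, dtype=int)
    for r in cd:
        lr = idx[r]
        for c in dr:
            if exclude_self and r == c:
                continue
            if jsi(lr, idx[c]) >= jsi_cutoff:
                mat.at[r, c] = 1
    return mat
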