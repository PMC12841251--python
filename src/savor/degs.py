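"""Threshold-based differential-expression screening and gene-set algebra.

Consumes any per-gene table with a log2 fold change and an FDR (e.g. DESeq2
output); applies the conventional |log2FC| >= 1, FDR <= 0.05 filter; and
provides the set arithmetic behind upset/Venn-style shared- and unique-gene
counts plus a directional-consistency count for genes shared between two
contrasts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .stats import benjamini_hochberg

__all__ = ["DegFilterResult", "GeneSetSummary", "filter_degs", "detected_gene_upset", "shared_deg_consistency"]

REQUIRED_DEG_COLUMNS = ("gene_id", "log2fc")


@dataclass
class DegFilterResult:
    """Filtered DEG table plus direction counts (up: log2fc > 0)."""

    table: pd.DataFrame
    n_up: int
    n_down: int

    @property
    def n_kept(self) -> int:
        return len(self.table)


@dataclass
class GeneSetSummary:
    """Shared/unique counts over per-group detected-gene sets."""

    set_sizes: dict[str, int]
    all_shared: int
    exclusive: dict[str, int]
    pairwise: dict[tuple[str, str], int] = field(default_factory=dict)


def _check_deg_table(table: pd.DataFrame, need_fdr: bool = False) -> None:
    missing = [c for c in REQUIRED_DEG_COLUMNS if c not in table.columns]
    if need_fdr and "fdr" not in table.columns and "pvalue" not in table.columns:
        missing.append("fdr (or pvalue)")
    if missing:
        raise ValueError(f"DEG table missing columns: {missing}")
    if table["gene_id"].duplicated().any():
        dupes = table.loc[table["gene_id"].duplicated(), "gene_id"].tolist()[:5]
        raise ValueError(f"duplicate gene ids in DEG table (first few: {dupes})")


def filter_degs(
    table: pd.DataFrame, lfc_min: float = 1.0, fdr_max: float = 0.05
) -> DegFilterResult:
    """Keep genes with |log2fc| >= lfc_min AND fdr <= fdr_max (both inclusive).

    If the table has p-values but no ``fdr`` column, Benjamini–Hochberg is
    applied to the p-values first. Genes with log2fc exactly 0 that survive
    the filter are excluded from both direction counts with a warning.
    """
    _check_deg_table(table, need_fdr=True)
    table = table.copy()
    if "fdr" not in table.columns:
        table["fdr"] = benjamini_hochberg(table["pvalue"].to_numpy())
    kept = table[(table["log2fc"].abs() >= lfc_min) & (table["fdr"] <= fdr_max)]
    n_zero = int((kept["log2fc"] == 0).sum())
    if n_zero:
        warnings.warn(f"{n_zero} kept genes have log2fc == 0; not counted as up or down")
    return DegFilterResult(
        table=kept.reset_index(drop=True),
        n_up=int((kept["log2fc"] > 0).sum()),
        n_down=int((kept["log2fc"] < 0).sum()),
    )


def detected_gene_upset(per_group_gene_sets: Mapping[str, Iterable]) -> GeneSetSummary:
    """Exact shared/exclusive/pairwise counts over >= 2 gene sets.

    ``all_shared`` is the size of the intersection of every set;
    ``exclusive[g]`` counts genes found only in group g; ``pairwise`` holds
    plain pairwise intersection sizes.
    """
    sets = {g: set(s) for g, s in per_group_gene_sets.items()}
    if len(sets) < 2:
        raise ValueError("need at least two gene sets")
    names = list(sets)
    universe_others = {g: set().union(*(sets[h] for h in names if h != g)) for g in names}
    return GeneSetSummary(
        set_sizes={g: len(s) for g, s in sets.items()},
        all_shared=len(set.intersection(*sets.values())),
        exclusive={g: len(sets[g] - universe_others[g]) for g in names},
        pairwise={
            (a, b): len(sets[a] & sets[b]) for a, b in itertools.combinations(names, 2)
        },
    )


def shared_deg_consistency(
    contrast_a: pd.DataFrame, contrast_b: pd.DataFrame, genes: Iterable
) -> tuple[int, int]:
    """Count same-sign vs opposite-sign fold changes for shared genes.

    A gene is consistent when sign(log2fc) agrees between the two contrasts
    and is nonzero in both; a zero log2fc counts as opposing, with a warning.
    """
    a = contrast_a.set_index("gene_id")["log2fc"]
    b = contrast_b.set_index("gene_id")["log2fc"]
    genes = list(genes)
    for g in genes:
        if g not in a.index or g not in b.index:
            raise KeyError(f"gene {g!r} missing from one of the contrasts")
    n_consistent = n_opposing = 0
    for g in genes:
        fa, fb = float(a.loc[g]), float(b.loc[g])
        if fa == 0 or fb == 0:
            warnings.warn(f"gene {g!r} has log2fc == 0; counted as opposing")
            n_opposing += 1
        elif (fa > 0) == (fb > 0):
            n_consistent += 1
        else:
            n_opposing += 1
    return n_consistent, n_opposing
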