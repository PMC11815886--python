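"""Dotplot-style summaries and pair-pattern checks on single-cell counts.

The question asked here: is a gene pair's predictive ordering reversal,
found in bulk data between two patient groups, localized to a specific cell
type? For every (gene, cell type, condition) stratum we record the percent
of cells expressing the gene (count > 0) and the median count over all
cells of the stratum (zeros included) — the two numbers a dotplot encodes —
then flag cell types where the pair's median ordering flips between the two
condition groups with adequate expression support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import GeneLookupError, ValidationError
from .types import SingleCellDataset

__all__ = [
    "DotplotSummary",
    "PairPatternVerdict",
    "summarize",
    "pair_pattern_check",
]


@dataclass
class DotplotSummary:
    """Long-format table: gene, cell_type, condition, pct_expressing, median_expr.

    Strata with zero cells are absent rather than zero-filled.
    """

    table: pd.DataFrame

    def get(self, gene: str, cell_type: str, condition: str) -> tuple[float, float]:
        t = self.table
        row = t[(t.gene == gene) & (t.cell_type == cell_type) & (t.condition == condition)]
        if row.empty:
            raise GeneLookupError(
                f"no stratum for gene={gene!r}, cell_type={cell_type!r}, "
                f"condition={condition!r}"
            )
        return float(row.pct_expressing.iloc[0]), float(row.median_expr.iloc[0])

    def cell_types(self) -> list[str]:
        return sorted(self.table.cell_type.unique())


@dataclass
class PairPatternVerdict:
    """Per-cell-type orderings of a pair in two groups and the reversal flag.

    ``table`` columns: cell_type, ordering_a (ordering in group A: one of
    ``a<b``, ``a>b``, ``tie``), ordering_b, supported, reversed. A cell type
    is reversed only when both orderings are non-tie, opposite, and the
    expression-support floor is met in both groups.
    """

    pair: tuple[str, str]
    groups: tuple[str, str]
    table: pd.DataFrame
    min_pct: float

    @property
    def reversed_cell_types(self) -> list[str]:
        return list(self.table.loc[self.table["reversed"], "cell_type"])

    @property
    def n_reversed(self) -> int:
        return int(self.table["reversed"].sum())


def summarize(
    dataset: SingleCellDataset,
    genes: list[str],
    group_by: tuple[str, str] = ("cell_type", "condition"),
) -> DotplotSummary:
    """Exact stratified percent-expressing and median expression per gene."""
    type_col, cond_col = group_by
    for col in group_by:
        if col not in dataset.cell_meta.columns:
            raise GeneLookupError(f"metadata column {col!r} not present")
    gene_idx = {}
    for g in genes:
        try:
            gene_idx[g] = dataset.gene_ids.index(g)
        except ValueError:
            raise GeneLookupError(f"gene {g!r} not in dataset") from None

    counts = dataset.counts.tocsc()
    meta = dataset.cell_meta
    rows = []
    grouped = meta.groupby([type_col, cond_col], sort=True, observed=True)
    for (ctype, cond), sub in grouped:
        cell_rows = meta.index.get_indexer(sub.index)
        for g, j in gene_idx.items():
            col = np.asarray(counts[:, j].todense()).ravel()[cell_rows]
            rows.append(
                {
                    "gene": g,
                    "cell_type": ctype,
                    "condition": cond,
                    "pct_expressing": 100.0 * float((col > 0).mean()),
                    "median_expr": float(np.median(col)),
                    "n_cells": len(col),
                }
            )
    return DotplotSummary(pd.DataFrame(rows))


def pair_pattern_check(
    summary: DotplotSummary,
    pair: tuple[str, str],
    groups: tuple[str, str],
    min_pct: float = 10.0,
) -> PairPatternVerdict:
    """Flag cell types where the pair's median ordering reverses between groups.

    A cell type is *supported* when, in each group, the gene with the higher
    median has percent-expressing >= ``min_pct`` (an ordering read off genes
    that are barely detected is noise, not pattern). It is *reversed* when
    both orderings are strict and opposite and the support floor holds.
    """
    gene_a, gene_b = pair
    group_a, group_b = groups
    t = summary.table
    cell_types = sorted(
        set(t.loc[t.gene == gene_a, "cell_type"]) & set(t.loc[t.gene == gene_b, "cell_type"])
    )
    if not cell_types:
        raise ValidationError("pair genes share no summarized cell types")
    rows = []
    for ct in cell_types:
        try:
            stats = {
                g: {grp: summary.get(g, ct, grp) for grp in groups}
                for g in pair
            }
        except GeneLookupError:
            continue  # cell type absent from one condition group
        orderings = {}
        support = {}
        for grp in groups:
            ma = stats[gene_a][grp][1]
            mb = stats[gene_b][grp][1]
            if ma < mb:
                orderings[grp] = "a<b"
                support[grp] = stats[gene_b][grp][0] >= min_pct
            elif ma > mb:
                orderings[grp] = "a>b"
                support[grp] = stats[gene_a][grp][0] >= min_pct
            else:
                orderings[grp] = "tie"
                support[grp] = False
        supported = all(support.values())
        rev = (
            supported
            and orderings[group_a] != "tie"
            and orderings[group_b] != "tie"
            and orderings[group_a] != orderings[group_b]
        )
        rows.append(
            {
                "cell_type": ct,
                "ordering_a": orderings[group_a],
                "ordering_b": orderings[group_b],
                "supported": supported,
                "reversed": rev,
            }
        )
    if not rows:
        raise ValidationError("no cell type present in both condition groups")
    return PairPatternVerdict(pair, groups, pd.DataFrame(rows), min_pct)
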