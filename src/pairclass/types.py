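"""Core in-memory containers shared by every stage of the pipeline.

All containers are lightweight dataclasses wrapping numpy / pandas / scipy
structures, validated on construction. Expression values are assumed to be
*within-sample comparable*: any strictly increasing per-sample transform of
the values leaves every gene-pair ordering unchanged, which is the property
the downstream pair features rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .exceptions import GeneLookupError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "ClusterLabeling",
    "SurvivalRecord",
    "SurvivalTable",
    "AliasMap",
    "SingleCellDataset",
]


@dataclass
class ExpressionMatrix:
    """Dense genes-by-samples expression matrix.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene symbols, one per row.
    sample_ids : list of str
        Unique sample identifiers, one per column.
    values : ndarray of shape (n_genes, n_samples)
        Finite, non-negative values on a within-sample comparable scale
        (arbitrary units; only within-sample order matters downstream).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n_genes, n_samples = self.values.shape
        if n_genes != len(self.gene_ids) or n_samples != len(self.sample_ids):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if n_genes < 2 or n_samples < 1:
            raise ValidationError("need at least 2 genes and 1 sample")
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("gene_ids must be unique")
        if len(set(self.sample_ids)) != n_samples:
            raise ValidationError("sample_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must all be finite")
        if np.any(self.values < 0):
            raise ValidationError("expression values must be non-negative")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._sample_index = {s: j for j, s in enumerate(self.sample_ids)}

    # -- lookups ----------------------------------------------------------
    def gene_row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self._gene_index[gene]]
        except KeyError:
            raise GeneLookupError(f"gene {gene!r} not in matrix") from None

    def gene_position(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise GeneLookupError(f"gene {gene!r} not in matrix") from None

    def has_gene(self, gene: str) -> bool:
        return gene in self._gene_index

    def select_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        cols = [self._sample_index[s] for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.allclose(self.values, other.values, rtol=0, atol=1e-9)
        )


@dataclass
class ClusterLabeling:
    """Assignment of samples to a fixed, ordered set of cluster labels."""

    assignments: dict[str, str]
    label_set: list[str]

    def __post_init__(self) -> None:
        if len(set(self.label_set)) != len(self.label_set):
            raise ValidationError("label_set contains duplicates")
        bad = {v for v in self.assignments.values() if v not in set(self.label_set)}
        if bad:
            raise ValidationError(f"assigned labels not in label_set: {sorted(bad)}")
        if len(set(self.assignments.values())) < 2:
            raise ValidationError("need at least 2 distinct labels among assignments")

    def samples_in(self, cluster: str) -> list[str]:
        return [s for s, c in self.assignments.items() if c == cluster]

    def labeled(self, sample_ids: list[str]) -> list[str]:
        """Subset of ``sample_ids`` (order preserved) that carry a label."""
        return [s for s in sample_ids if s in self.assignments]

    def subset(self, sample_ids: list[str]) -> "ClusterLabeling":
        sub = {s: self.assignments[s] for s in sample_ids if s in self.assignments}
        return ClusterLabeling(sub, list(self.label_set))

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in self.label_set}
        for c in self.assignments.values():
            out[c] += 1
        return out


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    time: float
    event: int
    group: str | None = None


@dataclass
class SurvivalTable:
    """Right-censored survival outcomes. ``event`` = 1 death observed, 0 censored."""

    records: list[SurvivalRecord]

    def __post_init__(self) -> None:
        for r in self.records:
            if not (np.isfinite(r.time) and r.time > 0):
                raise ValidationError(f"non-positive or non-finite time for {r.sample_id}")
            if r.event not in (0, 1):
                raise ValidationError(f"event must be 0 or 1 for {r.sample_id}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.records],
                "time": [r.time for r in self.records],
                "event": [r.event for r in self.records],
                "group": [r.group for r in self.records],
            }
        )

    def with_groups(self, grouping: dict[str, str]) -> "SurvivalTable":
        """Return a copy whose group column is taken from ``grouping``.

        Records whose sample id is absent from ``grouping`` are dropped.
        """
        recs = [
            SurvivalRecord(r.sample_id, r.time, r.event, grouping[r.sample_id])
            for r in self.records
            if r.sample_id in grouping
        ]
        return SurvivalTable(recs)


@dataclass
class AliasMap:
    """Many-to-one map from gene alias symbols to canonical symbols.

    Applying the map is idempotent: canonical symbols must not themselves be
    aliases of a different symbol.
    """

    entries: dict[str, str]

    def __post_init__(self) -> None:
        for alias, canon in self.entries.items():
            if not canon:
                raise ValidationError(f"empty canonical symbol for alias {alias!r}")
        for canon in set(self.entries.values()):
            if canon in self.entries and self.entries[canon] != canon:
                raise ValidationError(
                    f"canonical symbol {canon!r} is itself an alias of "
                    f"{self.entries[canon]!r}; mapping would not be idempotent"
                )

    def apply(self, symbol: str) -> str:
        return self.entries.get(symbol, symbol)


@dataclass
class SingleCellDataset:
    """Sparse cells-by-genes count matrix plus per-cell metadata.

    ``cell_meta`` is indexed by cell id and must carry at least the columns
    named by downstream grouping calls (typically ``cell_type`` and
    ``condition``).
    """

    counts: sparse.csr_matrix
    gene_ids: list[str]
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        n_cells, n_genes = self.counts.shape
        if n_genes != len(self.gene_ids):
            raise ValidationError("gene list length does not match matrix columns")
        if n_cells != len(self.cell_meta):
            raise ValidationError("cell metadata length does not match matrix rows")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("counts must be non-negative")
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("gene_ids must be unique")

    def gene_column(self, gene: str) -> np.ndarray:
        try:
            j = self.gene_ids.index(gene)
        except ValueError:
            raise GeneLookupError(f"gene {gene!r} not in dataset") from None
        return np.asarray(self.counts[:, j].todense()).ravel()
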