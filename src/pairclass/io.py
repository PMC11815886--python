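"""Readers and writers for the tabular and sparse formats the pipeline touches.

All tabular files are tab-delimited UTF-8 without quoting. Expression is
stored genes-in-rows with a header of sample ids; single-cell counts as a
matrix-market file (cells in rows) plus a plain-text gene list and a cell
metadata TSV. Every writer/reader pair round-trips losslessly up to a float
formatting tolerance of 1e-9. Schemas are documented in docs/formats.md.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .exceptions import FormatError, ParseError, ValidationError
from .scoring import FeatureSet
from .types import (
    AliasMap,
    ClusterLabeling,
    ExpressionMatrix,
    SingleCellDataset,
    SurvivalRecord,
    SurvivalTable,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression", "write_expression",
    "read_labels", "write_labels",
    "read_survival", "write_survival",
    "read_pairs", "write_pairs",
    "read_alias_map", "write_alias_map",
    "read_single_cell", "write_single_cell",
]

_FLOAT_FMT = "%.12g"


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, alias_map: AliasMap | None = None) -> ExpressionMatrix:
    """Read a genes x samples TSV into a validated :class:`ExpressionMatrix`.

    The first column holds gene symbols, the header row sample ids. When an
    alias map is supplied, symbols are mapped to canonical form first; rows
    mapping to the reserved symbol ``unknown`` (any case) are dropped with a
    logged count, and duplicate symbols after mapping are resolved by keeping
    the row with the highest mean (logged).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"could not read {path}: {exc}") from exc
    if df.columns.size == 0 or df.index.name is None and df.index.size == 0:
        raise FormatError(f"{path}: malformed header (no sample columns)")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().values)
    if bad.size:
        i, j = bad[0]
        raise ParseError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at gene "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    genes = [str(g) for g in df.index]
    values = numeric.values.astype(float)

    if alias_map is not None:
        genes = [alias_map.apply(g) for g in genes]
        unknown = [i for i, g in enumerate(genes) if g.lower() == "unknown"]
        if unknown:
            logger.warning("%s: dropping %d rows with unmapped symbols", path, len(unknown))
            keep = [i for i in range(len(genes)) if i not in set(unknown)]
            genes = [genes[i] for i in keep]
            values = values[keep]

    if len(set(genes)) != len(genes):
        keep_row: dict[str, int] = {}
        means = values.mean(axis=1)
        n_dup = 0
        for i, g in enumerate(genes):
            if g in keep_row:
                n_dup += 1
                if means[i] > means[keep_row[g]]:
                    keep_row[g] = i
            else:
                keep_row[g] = i
        logger.warning("%s: resolved %d duplicate symbols by keeping highest-mean row",
                       path, n_dup)
        idx = sorted(keep_row.values())
        genes = [genes[i] for i in idx]
        values = values[idx]

    if values.size == 0:
        raise ValidationError(f"{path}: empty expression matrix")
    return ExpressionMatrix(genes, [str(c) for c in df.columns], values)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="gene")


# ---------------------------------------------------------------------------
# Cluster labels
# ---------------------------------------------------------------------------

def read_labels(path: str | Path, label_order: list[str] | None = None) -> ClusterLabeling:
    """Read a sample_id / cluster TSV.

    ``label_set`` follows ``label_order`` when given, else the sorted distinct
    labels found. Duplicate sample ids and labels outside ``label_order`` are
    errors; samples unknown to any expression matrix are permitted here and
    matched later.
    """
    df = _read_required(path, ["sample_id", "cluster"])
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"{path}: sample {dup!r} assigned more than once")
    assignments = dict(zip(df["sample_id"].astype(str), df["cluster"].astype(str)))
    if label_order is not None:
        extra = set(assignments.values()) - set(label_order)
        if extra:
            raise ValidationError(f"{path}: labels {sorted(extra)} not in label_order")
        label_set = list(label_order)
    else:
        label_set = sorted(set(assignments.values()))
    return ClusterLabeling(assignments, label_set)


def write_labels(labels: ClusterLabeling, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(labels.assignments), "cluster": list(labels.assignments.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def read_survival(path: str | Path) -> SurvivalTable:
    """Read sample_id / time / event (+ optional group) records.

    ``time`` is in days, strictly positive. ``event`` is 1 for an observed
    death and 0 for censoring — the direction is fixed by the column name.
    """
    df = _read_required(path, ["sample_id", "time", "event"])
    groups = df["group"] if "group" in df.columns else [None] * len(df)
    records = []
    for sid, t, e, g in zip(df["sample_id"], df["time"], df["event"], groups):
        try:
            t = float(t)
            e = int(e)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: bad survival row for {sid!r}") from exc
        records.append(SurvivalRecord(str(sid), t, e, None if g in (None, "") else str(g)))
    return SurvivalTable(records)


def write_survival(table: SurvivalTable, path: str | Path) -> None:
    df = table.to_frame()
    if df["group"].isna().all():
        df = df.drop(columns=["group"])
    else:
        df["group"] = df["group"].fillna("")
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Gene-pair feature sets
# ---------------------------------------------------------------------------

_PAIR_ALIASES = {"clusterlabel": "cluster", "genea": "gene_a", "geneb": "gene_b"}


def read_pairs(path: str | Path) -> FeatureSet:
    """Read a cluster / gene_a / gene_b TSV into a FeatureSet.

    Header names ClusterLabel / GeneA / GeneB are accepted as synonyms, so
    published aggregated-feature tables paste in directly. Lines starting
    with ``#`` are treated as provenance comments and skipped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    df.columns = [_PAIR_ALIASES.get(c.lower(), c.lower()) for c in df.columns]
    missing = {"cluster", "gene_a", "gene_b"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    pairs: dict[str, list[tuple[str, str]]] = {}
    for _, row in df.iterrows():
        pairs.setdefault(str(row["cluster"]), []).append(
            (str(row["gene_a"]), str(row["gene_b"]))
        )
    return FeatureSet(pairs)


def write_pairs(feature_set: FeatureSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in sorted(feature_set.provenance.items()):
            fh.write(f"# {key}: {val}\n")
        fh.write("cluster\tgene_a\tgene_b\n")
        for cluster, plist in feature_set.pairs.items():
            for a, b in plist:
                fh.write(f"{cluster}\t{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Alias maps
# ---------------------------------------------------------------------------

def read_alias_map(path: str | Path) -> AliasMap:
    df = _read_required(path, ["alias", "canonical"])
    entries: dict[str, str] = {}
    for a, c in zip(df["alias"].astype(str), df["canonical"].astype(str)):
        if a in entries and entries[a] != c:
            raise ValidationError(f"{path}: alias {a!r} maps to two canonical symbols")
        entries[a] = c
    return AliasMap(entries)


def write_alias_map(alias_map: AliasMap, path: str | Path) -> None:
    pd.DataFrame(
        {"alias": list(alias_map.entries), "canonical": list(alias_map.entries.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Single cell (matrix-market triple)
# ---------------------------------------------------------------------------

def read_single_cell(
    matrix_path: str | Path, genes_path: str | Path, meta_path: str | Path
) -> SingleCellDataset:
    """Read a cells x genes sparse triple: .mtx matrix, gene list, metadata TSV."""
    counts = sparse.csr_matrix(spio.mmread(matrix_path))
    genes = [ln.strip() for ln in Path(genes_path).read_text().splitlines() if ln.strip()]
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    return SingleCellDataset(counts, genes, meta)


def write_single_cell(
    ds: SingleCellDataset,
    matrix_path: str | Path,
    genes_path: str | Path,
    meta_path: str | Path,
) -> None:
    spio.mmwrite(str(matrix_path), sparse.coo_matrix(ds.counts))
    Path(genes_path).write_text("\n".join(ds.gene_ids) + "\n")
    ds.cell_meta.to_csv(meta_path, sep="\t", index_label="cell_id")


# ---------------------------------------------------------------------------

def _read_required(path: str | Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise FormatError(f"could not read {path}: {exc}") from exc
    missing = set(required) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    return df
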