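"""Experiment designs: platform transfer, round-trip validation, aggregation.

These orchestrate the scoring and ensemble modules into the three study
designs used to establish that a pair-feature model generalizes:

* **transfer**: train on one platform view of a cohort, predict another;
* **round trip**: predict labels on an unlabeled cohort, train a fresh
  model on those predicted labels, and predict back onto the original
  labeled cohort — high back-prediction accuracy shows the label structure
  survived the transfer;
* **aggregation**: train one model per dataset, collect each model's most
  informative pairs per cluster, and keep pairs that replicate across at
  least ``min_datasets`` datasets (always including a designated reference),
  guarding against features that are informative in only one cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .ensemble import (
    ClassificationReport,
    EnsembleModel,
    ModelParams,
    PredictionResult,
    SelectionConfig,
    binarize,
    classification_report,
    feature_importance,
    predict,
    train,
)
from .exceptions import ValidationError
from .scoring import FeatureSet, rank_pairs, select_features
from .survival import SurvivalSummary, summarize_survival
from .types import ClusterLabeling, ExpressionMatrix, SurvivalTable

logger = logging.getLogger(__name__)

__all__ = [
    "TransferResult",
    "AggregatedFeatureReport",
    "fit_model",
    "transfer_predict",
    "round_trip",
    "aggregate_features",
]


@dataclass
class TransferResult:
    source_id: str
    target_id: str
    model: EnsembleModel
    predictions: PredictionResult
    report: ClassificationReport | None = None
    survival_summary: SurvivalSummary | None = None


@dataclass
class AggregatedFeatureReport:
    """Replication counts per informative pair plus the aggregated FeatureSet."""

    table: pd.DataFrame  # cluster, gene_a, gene_b, dataset_count, per-dataset gains
    selected: FeatureSet
    min_datasets: int
    reference: str


def fit_model(
    expr: ExpressionMatrix,
    labels: ClusterLabeling,
    feature_set: FeatureSet,
    params: ModelParams,
    missing: str = "error",
) -> EnsembleModel:
    """Binarize and train in one step."""
    return train(binarize(expr, feature_set, missing=missing), labels, params)


def transfer_predict(
    train_expr: ExpressionMatrix,
    train_labels: ClusterLabeling,
    feature_set: FeatureSet,
    params: ModelParams,
    target_expr: ExpressionMatrix,
    target_labels: ClusterLabeling | None = None,
    target_survival: SurvivalTable | None = None,
    protective: str | None = None,
    missing: str = "error",
    source_id: str = "source",
    target_id: str = "target",
) -> TransferResult:
    """Train on the source cohort, predict cluster labels on the target.

    When target labels are known a classification report is attached; when a
    survival table is given, the predictions stratify it and the log-rank
    summary is attached.
    """
    model = fit_model(train_expr, train_labels, feature_set, params, missing=missing)
    preds = predict(model, target_expr, missing=missing)
    report = classification_report(target_labels, preds) if target_labels else None
    surv = None
    if target_survival is not None:
        surv = summarize_survival(
            target_survival,
            grouping=dict(zip(preds.sample_ids, preds.best_calls)),
            protective=protective,
        )
    return TransferResult(source_id, target_id, model, preds, report, surv)


def round_trip(
    train_expr: ExpressionMatrix,
    train_labels: ClusterLabeling,
    feature_set: FeatureSet,
    params: ModelParams,
    other_expr: ExpressionMatrix,
    missing: str = "error",
) -> tuple[PredictionResult, ClassificationReport]:
    """Label an unlabeled cohort, retrain on it, and predict back.

    Stage 1 predicts labels on ``other_expr`` with a model trained on the
    labeled cohort. Stage 2 trains a fresh model on ``other_expr`` using
    those predicted labels (clusters receiving no predictions are skipped
    with a warning). Stage 3 predicts back onto ``train_expr`` and scores
    against the known labels.
    """
    stage1 = fit_model(train_expr, train_labels, feature_set, params, missing=missing)
    other_preds = predict(stage1, other_expr, missing=missing)
    predicted_clusters = sorted(set(other_preds.best_calls))
    skipped = [c for c in train_labels.label_set if c not in predicted_clusters]
    if skipped:
        logger.warning("no samples predicted for cluster(s) %s; "
                       "stage-2 model trains without them", skipped)
    other_labels = ClusterLabeling(
        dict(zip(other_preds.sample_ids, other_preds.best_calls)),
        [c for c in train_labels.label_set if c in predicted_clusters],
    )
    stage2 = fit_model(other_expr, other_labels, feature_set, params, missing=missing)
    back = predict(stage2, train_expr, missing=missing)
    return other_preds, classification_report(train_labels, back)


def aggregate_features(
    datasets: list[tuple[ExpressionMatrix, ClusterLabeling, str]],
    selection: SelectionConfig,
    params: ModelParams,
    top_n: int = 10,
    min_datasets: int = 3,
    reference: str | None = None,
) -> AggregatedFeatureReport:
    """Keep pairs that rank informative in at least ``min_datasets`` datasets.

    Per dataset: run ranking + greedy selection, train a model, and extract
    the top ``top_n`` pairs per cluster by median gain (restricted to the
    cluster's own pair features). A pair is identified by its cluster and
    unordered gene pair, so opposite canonical orientations in different
    datasets still count as the same feature. Selected pairs must appear in
    the reference dataset's informative lists; their orientation is taken
    from the reference.
    """
    ids = [d[2] for d in datasets]
    if reference is None:
        reference = ids[0]
    if reference not in ids:
        raise ValidationError(f"reference dataset {reference!r} not among {ids}")
    if len(datasets) < min_datasets:
        raise ValidationError(
            f"need at least min_datasets={min_datasets} datasets, got {len(datasets)}"
        )

    # informative lists per dataset: {cluster: {frozen pair: (orientation, gain)}}
    informative: dict[str, dict[str, dict[frozenset, tuple[tuple[str, str], float]]]] = {}
    for expr, labels, did in datasets:
        ranked = rank_pairs(
            expr, labels, pd_min=selection.pd_min,
            candidate_genes=selection.candidate_genes,
        )
        fs = select_features(
            ranked, expr, labels,
            k_per_cluster=selection.k_per_cluster, corr_max=selection.corr_max,
        )
        model = fit_model(expr, labels, fs, params)
        gains = feature_importance(model)
        per_cluster: dict[str, dict[frozenset, tuple[tuple[str, str], float]]] = {}
        for cluster in fs.clusters:
            own_prefix = f"{cluster}:"
            lst = [(fid, g) for fid, g in gains.get(cluster, []) if fid.startswith(own_prefix)]
            entry: dict[frozenset, tuple[tuple[str, str], float]] = {}
            for fid, g in lst[:top_n]:
                a, b = fid[len(own_prefix):].split("<", 1)
                entry[frozenset((a, b))] = ((a, b), g)
            per_cluster[cluster] = entry
        informative[did] = per_cluster

    ref_lists = informative[reference]
    clusters = sorted({c for d in informative.values() for c in d})
    rows = []
    selected_pairs: dict[str, list[tuple[str, str]]] = {}
    for cluster in clusters:
        seen: dict[frozenset, tuple[str, str]] = {}
        for did in ids:
            for key, (orient, _) in informative[did].get(cluster, {}).items():
                seen.setdefault(key, orient)
        for key, orient in seen.items():
            count = sum(1 for did in ids if key in informative[did].get(cluster, {}))
            row = {
                "cluster": cluster,
                "gene_a": orient[0],
                "gene_b": orient[1],
                "dataset_count": count,
            }
            for did in ids:
                hit = informative[did].get(cluster, {}).get(key)
                row[f"gain_{did}"] = hit[1] if hit else float("nan")
            rows.append(row)
            if count >= min_datasets and key in ref_lists.get(cluster, {}):
                ref_orient = ref_lists[cluster][key][0]
                selected_pairs.setdefault(cluster, []).append(ref_orient)
    table = pd.DataFrame(rows).sort_values(
        ["cluster", "dataset_count"], ascending=[True, False]
    ).reset_index(drop=True)
    selected = FeatureSet(
        selected_pairs,
        provenance={
            "top_n": top_n,
            "min_datasets": min_datasets,
            "reference": reference,
            "datasets": ids,
        },
    )
    return AggregatedFeatureReport(table, selected, min_datasets, reference)
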