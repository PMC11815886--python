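"""Ensemble classifier over binarized gene-pair features.

The classifier mirrors the robust-ensemble design used for rank-based
subtype calling: expression is reduced to binary within-sample comparisons
(1 iff value(gene_a) < value(gene_b)), one stack of ``ensemble_size``
binary gradient-boosted learners is trained per cluster (one-vs-rest), each
on an independent stratified random subsample of the training data, the
per-cluster score is the median of the stack members' positive-class
probabilities, and a final multi-class boosted learner maps the vector of
per-cluster median scores to the "best call" label.

Because the features are within-sample rank comparisons, predictions are
invariant to any strictly increasing per-sample transform of the input
matrix — the property that lets one model serve microarray and RNA-seq
views of the same cohort.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .exceptions import GeneLookupError, ValidationError
from .scoring import FeatureSet, rank_pairs, select_features
from .types import ClusterLabeling, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PairFeatureMatrix",
    "ModelParams",
    "SelectionConfig",
    "EnsembleModel",
    "PredictionResult",
    "ClassificationReport",
    "binarize",
    "train",
    "predict",
    "cross_validate",
    "classification_report",
    "feature_importance",
    "grid_search",
]


@dataclass
class PairFeatureMatrix:
    """Samples x binary pair features; entry 1 iff value(gene_a) < value(gene_b)."""

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValidationError("feature matrix shape mismatch")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValidationError("feature ids must be unique")
        if self.values.size and not np.isin(self.values, (0, 1)).all():
            raise ValidationError("feature values must be 0/1")

    def select_samples(self, sample_ids: list[str]) -> "PairFeatureMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return PairFeatureMatrix(list(sample_ids), list(self.feature_ids), self.values[rows])


@dataclass
class ModelParams:
    """Hyperparameters of the pair ensemble.

    Ensemble size 11 and tree depth 12 are the tuned defaults for the
    unbalanced five-cluster setting; eta/nrounds/lambda/alpha are ordinary
    boosting knobs left at conventional values and exposed to grid search.
    """

    ensemble_size: int = 11
    subsample_fraction: float = 0.80
    max_depth: int = 12
    eta: float = 0.3
    nrounds: int = 50
    reg_lambda: float = 1.0
    reg_alpha: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ensemble_size < 1 or self.ensemble_size % 2 == 0:
            raise ValidationError("ensemble_size must be odd and >= 1")
        if not 0 < self.subsample_fraction <= 1:
            raise ValidationError("subsample_fraction must be in (0, 1]")
        if self.max_depth < 1:
            raise ValidationError("max_depth must be >= 1")


@dataclass
class SelectionConfig:
    """Feature-selection settings for in-fold selection during CV."""

    pd_min: float = 0.5
    k_per_cluster: int = 10
    corr_max: float = 0.85
    candidate_genes: list[str] | None = None


@dataclass
class EnsembleModel:
    feature_set: FeatureSet
    params: ModelParams
    label_set: list[str]
    feature_ids: list[str]
    stacks: dict[str, list[XGBClassifier]] = field(default_factory=dict)
    final_predictor: XGBClassifier | None = None
    majority_label: str | None = None  # fallback when no features survive


@dataclass
class PredictionResult:
    """Per-sample per-cluster median scores and the final best-call label."""

    sample_ids: list[str]
    label_set: list[str]
    scores: np.ndarray
    best_calls: list[str]

    def __post_init__(self) -> None:
        bad = set(self.best_calls) - set(self.label_set)
        if bad:
            raise ValidationError(f"best calls outside label set: {sorted(bad)}")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, index=self.sample_ids, columns=self.label_set)
        df["best_call"] = self.best_calls
        df.index.name = "sample_id"
        return df

    def as_labeling(self) -> ClusterLabeling:
        return ClusterLabeling(
            dict(zip(self.sample_ids, self.best_calls)), list(self.label_set)
        )


@dataclass
class ClassificationReport:
    confusion: pd.DataFrame  # rows true, columns predicted
    accuracy: float
    per_cluster: pd.DataFrame  # columns f1, sensitivity, specificity
    macro_f1: float


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------

def binarize(
    expr: ExpressionMatrix, feature_set: FeatureSet, missing: str = "error"
) -> PairFeatureMatrix:
    """Turn expression into binary pair features, pooled across clusters.

    Feature ids are ``cluster:gene_a<gene_b``. Ties score 0. Under
    ``missing="drop"`` pairs with an absent gene are dropped with a warning,
    refusing if more than 25% of any cluster's pairs would vanish; the
    default ``"error"`` raises instead.
    """
    if missing not in ("error", "drop"):
        raise ValidationError(f"unknown missing-gene policy {missing!r}")
    cols: list[np.ndarray] = []
    ids: list[str] = []
    for cluster, plist in feature_set.pairs.items():
        dropped = 0
        for a, b in plist:
            if not (expr.has_gene(a) and expr.has_gene(b)):
                if missing == "error":
                    raise GeneLookupError(
                        f"feature gene missing from matrix: pair ({a}, {b})"
                    )
                dropped += 1
                logger.warning("dropping pair (%s, %s) of %s: gene missing", a, b, cluster)
                continue
            ids.append(f"{cluster}:{a}<{b}")
            cols.append((expr.gene_row(a) < expr.gene_row(b)).astype(np.int8))
        if plist and dropped > 0.25 * len(plist):
            raise ValidationError(
                f"{dropped}/{len(plist)} pairs of cluster {cluster} lack genes; "
                "refusing under the 25% cap"
            )
    values = (
        np.column_stack(cols) if cols else np.zeros((len(expr.sample_ids), 0), np.int8)
    )
    return PairFeatureMatrix(list(expr.sample_ids), ids, values)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _learner_seed(base: int, cluster_index: int, member_index: int) -> int:
    """Documented per-learner seed schedule: SeedSequence over the triple."""
    ss = np.random.SeedSequence([int(base), int(cluster_index), int(member_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def _make_xgb(params: ModelParams, seed: int, n_classes: int = 2) -> XGBClassifier:
    kwargs = dict(
        n_estimators=params.nrounds,
        max_depth=params.max_depth,
        learning_rate=params.eta,
        reg_lambda=params.reg_lambda,
        reg_alpha=params.reg_alpha,
        n_jobs=1,
        tree_method="hist",
        random_state=seed,
        verbosity=0,
    )
    if n_classes == 2:
        kwargs.update(objective="binary:logistic", eval_metric="logloss")
    else:
        kwargs.update(objective="multi:softprob", eval_metric="mlogloss")
    return XGBClassifier(**kwargs)


def _stratified_subsample(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Random subsample preserving class balance, with >= 1 of each class."""
    idx = []
    for cls in (0, 1):
        members = np.flatnonzero(y == cls)
        k = max(1, round(fraction * len(members)))
        idx.append(rng.choice(members, size=min(k, len(members)), replace=False))
    out = np.concatenate(idx)
    out.sort()
    return out


def train(
    features: PairFeatureMatrix, labels: ClusterLabeling, params: ModelParams
) -> EnsembleModel:
    """Fit per-cluster binary stacks plus the final best-call predictor.

    For each cluster present in the labels, ``ensemble_size`` binary
    learners are fit on independent stratified ``subsample_fraction``
    subsamples of the labeled training samples; the final multi-class
    learner is then fit on the per-cluster median scores of the full
    training set. All randomness derives from ``params.seed`` through a
    per-learner seed schedule, so training is reproducible.
    """
    labeled = labels.labeled(features.sample_ids)
    missing = set(labels.assignments) - set(features.sample_ids)
    if missing:
        raise ValidationError(f"labeled samples missing from features: {sorted(missing)[:5]}")
    fm = features.select_samples(labeled)
    y_lab = np.array([labels.assignments[s] for s in labeled])
    present = [c for c in labels.label_set if (y_lab == c).sum() > 0]
    for c in present:
        if (y_lab == c).sum() < 2:
            raise ValidationError(f"cluster {c!r} has fewer than 2 samples")
    if len(present) < 2:
        raise ValidationError("need at least 2 clusters with samples")

    model = EnsembleModel(
        feature_set=features_feature_set(features),
        params=params,
        label_set=present,
        feature_ids=list(features.feature_ids),
    )
    if fm.values.shape[1] == 0:
        counts = {c: int((y_lab == c).sum()) for c in present}
        model.majority_label = max(present, key=lambda c: (counts[c], -present.index(c)))
        logger.warning("no features available; falling back to majority label %s",
                       model.majority_label)
        return model

    X = fm.values.astype(np.float32)
    for ci, c in enumerate(present):
        y = (y_lab == c).astype(int)
        stack = []
        for mi in range(params.ensemble_size):
            seed = _learner_seed(params.seed, ci, mi)
            rng = np.random.default_rng(seed)
            sub = _stratified_subsample(y, params.subsample_fraction, rng)
            clf = _make_xgb(params, seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(X[sub], y[sub])
            stack.append(clf)
        model.stacks[c] = stack

    med = _median_scores(model, X)
    y_idx = np.array([present.index(c) for c in y_lab])
    final = _make_xgb(params, _learner_seed(params.seed, len(present), 0),
                      n_classes=len(present))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(med, y_idx)
    model.final_predictor = final
    return model


def features_feature_set(features: PairFeatureMatrix) -> FeatureSet:
    """Recover the FeatureSet implied by a feature matrix's column ids."""
    pairs: dict[str, list[tuple[str, str]]] = {}
    for fid in features.feature_ids:
        cluster, rest = fid.split(":", 1)
        a, b = rest.split("<", 1)
        pairs.setdefault(cluster, []).append((a, b))
    return FeatureSet(pairs)


def _median_scores(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    out = np.empty((X.shape[0], len(model.label_set)))
    for k, c in enumerate(model.label_set):
        probs = np.stack([clf.predict_proba(X)[:, 1] for clf in model.stacks[c]])
        out[:, k] = np.median(probs, axis=0)
    return out


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict(
    model: EnsembleModel, expr: ExpressionMatrix, missing: str = "error"
) -> PredictionResult:
    """Score every sample of ``expr`` and emit best-call labels."""
    fm = binarize(expr, model.feature_set, missing=missing)
    return predict_features(model, fm)


def predict_features(model: EnsembleModel, fm: PairFeatureMatrix) -> PredictionResult:
    if model.majority_label is not None:
        k = len(model.label_set)
        scores = np.full((len(fm.sample_ids), k), 1.0 / k)
        return PredictionResult(
            list(fm.sample_ids), list(model.label_set), scores,
            [model.majority_label] * len(fm.sample_ids),
        )
    if fm.feature_ids != model.feature_ids:
        idx = {f: i for i, f in enumerate(fm.feature_ids)}
        missing = [f for f in model.feature_ids if f not in idx]
        if missing:
            raise ValidationError(f"feature columns missing: {missing[:5]}")
        fm = PairFeatureMatrix(
            fm.sample_ids, list(model.feature_ids),
            fm.values[:, [idx[f] for f in model.feature_ids]],
        )
    X = fm.values.astype(np.float32)
    med = _median_scores(model, X)
    proba = model.final_predictor.predict_proba(med)
    calls = []
    for i in range(len(fm.sample_ids)):
        # argmax with ties broken by median cluster score, then label order
        best = 0
        for k in range(1, proba.shape[1]):
            if proba[i, k] > proba[i, best] or (
                proba[i, k] == proba[i, best] and med[i, k] > med[i, best]
            ):
                best = k
        calls.append(model.label_set[best])
    return PredictionResult(list(fm.sample_ids), list(model.label_set), med, calls)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def classification_report(
    true: ClusterLabeling, pred: PredictionResult
) -> ClassificationReport:
    """Confusion matrix, accuracy, one-vs-rest F1 / sensitivity / specificity.

    Macro F1 averages over the true label set. F1 is defined as 0 when
    precision + recall is 0.
    """
    common = [s for s in pred.sample_ids if s in true.assignments]
    if not common:
        raise ValidationError("no overlap between true labels and predictions")
    pred_map = dict(zip(pred.sample_ids, pred.best_calls))
    y_true = [true.assignments[s] for s in common]
    y_pred = [pred_map[s] for s in common]
    all_labels = list(true.label_set) + [
        c for c in pred.label_set if c not in true.label_set
    ]
    conf = pd.DataFrame(0, index=all_labels, columns=all_labels, dtype=int)
    for t, p in zip(y_true, y_pred):
        conf.loc[t, p] += 1
    n = len(common)
    accuracy = float(np.trace(conf.values) / n)
    rows = {}
    for c in all_labels:
        tp = conf.loc[c, c]
        fn = conf.loc[c].sum() - tp
        fp = conf[c].sum() - tp
        tn = n - tp - fn - fp
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        prec = tp / (tp + fp) if tp + fp else 0.0
        f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
        rows[c] = {"f1": f1, "sensitivity": sens, "specificity": spec}
    per_cluster = pd.DataFrame(rows).T
    macro = float(per_cluster.loc[list(true.label_set), "f1"].mean())
    return ClassificationReport(conf, accuracy, per_cluster, macro)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def cross_validate(
    expr: ExpressionMatrix,
    labels: ClusterLabeling,
    params: ModelParams,
    feature_set: FeatureSet | None = None,
    selection: SelectionConfig | None = None,
    n_folds: int = 10,
    seed: int | None = None,
) -> tuple[PredictionResult, ClassificationReport]:
    """Stratified k-fold CV; predictions collated over folds, one report.

    With a :class:`SelectionConfig`, pair ranking and selection are re-run
    inside every training fold so no information from the held-out fold can
    leak into the features. Otherwise the provided ``feature_set`` is used
    throughout.
    """
    if (feature_set is None) == (selection is None):
        raise ValidationError("provide exactly one of feature_set or selection")
    seed = params.seed if seed is None else seed
    labeled = labels.labeled(expr.sample_ids)
    y = np.array([labels.assignments[s] for s in labeled])
    smallest = min(np.unique(y, return_counts=True)[1])
    if n_folds > smallest:
        raise ValidationError(
            f"n_folds={n_folds} exceeds the smallest cluster size ({smallest}); "
            "stratified folds would lack a class"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
    collated: dict[str, tuple[np.ndarray, str, list[str]]] = {}
    for train_idx, test_idx in skf.split(np.zeros(len(labeled)), y):
        train_ids = [labeled[i] for i in train_idx]
        test_ids = [labeled[i] for i in test_idx]
        train_expr = expr.select_samples(train_ids)
        train_labels = labels.subset(train_ids)
        fs = feature_set
        if selection is not None:
            ranked = rank_pairs(
                train_expr, train_labels, pd_min=selection.pd_min,
                candidate_genes=selection.candidate_genes,
            )
            fs = select_features(
                ranked, train_expr, train_labels,
                k_per_cluster=selection.k_per_cluster, corr_max=selection.corr_max,
            )
        fm_train = binarize(train_expr, fs)
        model = train(fm_train, train_labels, params)
        res = predict(model, expr.select_samples(test_ids))
        for i, s in enumerate(res.sample_ids):
            collated[s] = (res.scores[i], res.best_calls[i], res.label_set)

    full_label_set = list(labels.label_set)
    scores = np.zeros((len(labeled), len(full_label_set)))
    calls = []
    for i, s in enumerate(labeled):
        row, call, lset = collated[s]
        for k, c in enumerate(lset):
            scores[i, full_label_set.index(c)] = row[k]
        calls.append(call)
    result = PredictionResult(list(labeled), full_label_set, scores, calls)
    report = classification_report(labels, result)
    return result, report


# ---------------------------------------------------------------------------
# Importance and grid search
# ---------------------------------------------------------------------------

def feature_importance(model: EnsembleModel) -> dict[str, list[tuple[str, float]]]:
    """Per-cluster median (across stack members) total split gain per feature.

    Gains are in the boosting library's native total-gain units. Features
    never split on receive gain 0. Lists are sorted by gain descending, ties
    by feature id, so output is deterministic under a fixed seed.
    """
    if not model.stacks:
        raise ValidationError("model has no trained stacks")
    out: dict[str, list[tuple[str, float]]] = {}
    n_feat = len(model.feature_ids)
    for c, stack in model.stacks.items():
        gains = np.zeros((len(stack), n_feat))
        for m, clf in enumerate(stack):
            score = clf.get_booster().get_score(importance_type="total_gain")
            for key, g in score.items():
                gains[m, int(key[1:])] = g
        med = np.median(gains, axis=0)
        order = sorted(range(n_feat), key=lambda j: (-med[j], model.feature_ids[j]))
        out[c] = [(model.feature_ids[j], float(med[j])) for j in order]
    return out


_GRID_ALIASES = {"lambda": "reg_lambda", "alpha": "reg_alpha"}


def grid_search(
    expr: ExpressionMatrix,
    labels: ClusterLabeling,
    feature_set: FeatureSet,
    grid: dict[str, list],
    n_folds: int = 5,
    seed: int = 0,
    base_params: ModelParams | None = None,
) -> tuple[ModelParams, pd.DataFrame]:
    """Exhaustive CV search over boosting parameters, maximizing macro F1.

    Ties are broken by smaller max_depth, then smaller nrounds, then first
    point in grid order. The full table of grid points is returned for audit.
    """
    if not grid:
        raise ValidationError("grid must be non-empty")
    base = base_params or ModelParams(seed=seed)
    valid = {f.name for f in fields(ModelParams)}
    keys = []
    for k in grid:
        canon = _GRID_ALIASES.get(k, k)
        if canon not in valid:
            raise ValidationError(f"unknown parameter {k!r}")
        keys.append(canon)
    rows = []
    best: tuple | None = None
    for gi, combo in enumerate(itertools.product(*grid.values())):
        params = replace(base, **dict(zip(keys, combo)), seed=seed)
        _, report = cross_validate(
            expr, labels, params, feature_set=feature_set, n_folds=n_folds, seed=seed
        )
        rows.append({**dict(zip(keys, combo)), "macro_f1": report.macro_f1})
        key = (-report.macro_f1, params.max_depth, params.nrounds, gi)
        if best is None or key < best[0]:
            best = (key, params)
    return best[1], pd.DataFrame(rows)
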