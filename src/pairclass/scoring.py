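"""Gene-pair scoring, ranking and feature selection.

The unit of information is the *oriented* gene pair (A, B) judged against one
target cluster. Writing ``S`` for the labeled samples, ``s`` for those in the
cluster and ``t`` for those outside it, the statistics are

* ``p_in``  — fraction of in-cluster samples with value(A) < value(B),
* ``p_out`` — the same fraction among out-of-cluster samples,
* ``PD = p_in - p_out`` — the proportion difference, in [-1, 1],
* ``Q`` / ``R`` — mean of value(A) - value(B) inside / outside the cluster,
* ``score = |PD| * (-1 * Q * R)`` — positive exactly when the mean ordering
  is reversed between the cluster and the rest (Q and R of opposite sign)
  and the rank pattern is informative (PD != 0).

When a second, independent cohort is available, the cross-cohort score
``|PD| * |PD_val| * (-1 * Q * R)`` up-ranks pairs whose proportion difference
replicates; pairs whose PD changes sign across cohorts are zeroed out, since
a direction-discordant pair cannot transfer.

Ties in expression count as *not* satisfying A < B. This makes the indicator
deterministic and exactly antisymmetric in the absence of ties, which matters
for count data where ties are common.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .exceptions import GeneLookupError, ValidationError
from .types import ClusterLabeling, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PairStats",
    "FeatureSet",
    "proportion_difference",
    "pair_score",
    "updated_pair_score",
    "rank_pairs",
    "select_features",
    "cross_platform_refine",
]


@dataclass
class PairStats:
    """Rank and magnitude statistics for one oriented pair and one cluster."""

    gene_a: str
    gene_b: str
    cluster: str
    p_in: float
    p_out: float
    pd: float
    q: float
    r: float
    score: float | None = None
    pd_val: float | None = None
    updated_score: float | None = None


@dataclass
class FeatureSet:
    """Per-cluster ordered lists of oriented gene pairs, with provenance.

    Within a cluster no gene may appear in two pairs (greedy selection with a
    correlation cap enforces this automatically: a gene's correlation with
    itself is 1).
    """

    pairs: dict[str, list[tuple[str, str]]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cluster, plist in self.pairs.items():
            seen: set[str] = set()
            for a, b in plist:
                if a == b:
                    raise ValidationError(f"pair ({a}, {b}) in {cluster} repeats a gene")
                if a in seen or b in seen:
                    raise ValidationError(
                        f"gene reused across pairs within cluster {cluster}"
                    )
                seen.add(a)
                seen.add(b)

    @property
    def clusters(self) -> list[str]:
        return list(self.pairs)

    def all_genes(self) -> list[str]:
        out: list[str] = []
        seen: set[str] = set()
        for plist in self.pairs.values():
            for a, b in plist:
                for g in (a, b):
                    if g not in seen:
                        seen.add(g)
                        out.append(g)
        return out

    def n_pairs(self) -> int:
        return sum(len(v) for v in self.pairs.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureSet):
            return NotImplemented
        return self.pairs == other.pairs


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def proportion_difference(
    expr: ExpressionMatrix,
    labels: ClusterLabeling,
    cluster: str,
    pair: tuple[str, str],
) -> PairStats:
    """Compute p_in, p_out, PD, Q, R for one oriented pair and one cluster.

    Only labeled samples participate. The indicator is the strict inequality
    value(gene_a) < value(gene_b); ties count as not satisfying it.
    """
    gene_a, gene_b = pair
    va = expr.gene_row(gene_a)
    vb = expr.gene_row(gene_b)
    labeled = labels.labeled(expr.sample_ids)
    if not labeled:
        raise ValidationError("no labeled samples in matrix")
    idx = [expr.sample_ids.index(s) for s in labeled]
    in_mask = np.array([labels.assignments[s] == cluster for s in labeled])
    if not in_mask.any():
        raise ValidationError(f"cluster {cluster!r} has no labeled samples")
    if in_mask.all():
        raise ValidationError(f"cluster {cluster!r} has no out-of-cluster samples")
    a = va[idx]
    b = vb[idx]
    less = a < b
    diff = a - b
    p_in = float(less[in_mask].mean())
    p_out = float(less[~in_mask].mean())
    q = float(diff[in_mask].mean())
    r = float(diff[~in_mask].mean())
    return PairStats(gene_a, gene_b, cluster, p_in, p_out, p_in - p_out, q, r)


def pair_score(stats: PairStats) -> float:
    """Gene pair score |PD| * (-1 * Q * R); stored back into ``stats.score``."""
    stats.score = abs(stats.pd) * (-1.0 * stats.q * stats.r)
    return stats.score


def updated_pair_score(stats: PairStats, pd_val: float) -> float:
    """Cross-cohort score |PD| * |PD_val| * (-1 * Q * R).

    ``pd_val`` is the proportion difference of the same oriented pair in a
    second cohort. When its sign disagrees with the primary PD the score is
    zero: a pair whose direction flips across cohorts must not be up-ranked.
    """
    if not -1.0 <= pd_val <= 1.0:
        raise ValidationError(f"pd_val {pd_val} outside [-1, 1]")
    stats.pd_val = pd_val
    if stats.pd * pd_val < 0:
        stats.updated_score = 0.0
    else:
        stats.updated_score = abs(stats.pd) * abs(pd_val) * (-1.0 * stats.q * stats.r)
    return stats.updated_score


# ---------------------------------------------------------------------------
# Exhaustive ranking
# ---------------------------------------------------------------------------

def _pairwise_counts(
    X: np.ndarray, cluster_of: np.ndarray, n_clusters: int
) -> tuple[np.ndarray, np.ndarray]:
    """Count, per cluster and over all labeled samples, how often row i < row j.

    Returns (count_per_cluster, count_total) with shapes (k, G, G) and (G, G).
    Complexity is O(G^2 * S) but fully vectorized over the G x G plane.
    """
    n_genes, n_samples = X.shape
    per_cluster = np.zeros((n_clusters, n_genes, n_genes), dtype=np.int32)
    for s in range(n_samples):
        col = X[:, s]
        per_cluster[cluster_of[s]] += col[:, None] < col[None, :]
    return per_cluster, per_cluster.sum(axis=0)


def rank_pairs(
    expr: ExpressionMatrix,
    labels: ClusterLabeling,
    pd_min: float = 0.5,
    candidate_genes: list[str] | None = None,
    max_genes: int = 2000,
) -> dict[str, list[PairStats]]:
    """Score every unordered gene pair against every cluster and rank survivors.

    Each unordered pair contributes one oriented pair per cluster, oriented so
    that PD >= 0 inside that cluster (if both orientations give PD >= 0, which
    can only happen through ties, the larger PD wins, then gene-name order).
    Pairs with PD < ``pd_min`` are dropped. Survivors are sorted by score
    descending, ties broken by PD descending then by (gene_a, gene_b).

    With no candidate list and more than ``max_genes`` genes, the top
    ``max_genes`` by variance (over labeled samples) are used.
    """
    if candidate_genes is not None:
        missing = [g for g in candidate_genes if not expr.has_gene(g)]
        if missing:
            raise GeneLookupError(f"candidate genes not in matrix: {missing[:5]}")
        genes = list(candidate_genes)
    else:
        genes = list(expr.gene_ids)
    if len(genes) < 2:
        raise ValidationError("need at least 2 candidate genes")

    labeled = labels.labeled(expr.sample_ids)
    if not labeled:
        raise ValidationError("no labeled samples in matrix")
    col_idx = [expr._sample_index[s] for s in labeled]
    gi = np.array([expr._gene_index[g] for g in genes])
    X = expr.values[np.ix_(gi, col_idx)]

    if candidate_genes is None and len(genes) > max_genes:
        order = np.argsort(X.var(axis=1))[::-1][:max_genes]
        order.sort()
        X = X[order]
        genes = [genes[i] for i in order]

    present = [c for c in labels.label_set if any(labels.assignments[s] == c for s in labeled)]
    cidx = {c: k for k, c in enumerate(present)}
    cluster_of = np.array([cidx[labels.assignments[s]] for s in labeled])
    per_cluster, total = _pairwise_counts(X, cluster_of, len(present))

    n = len(labeled)
    mu = np.empty((len(present), len(genes)))
    n_in = np.empty(len(present), dtype=int)
    for c, k in cidx.items():
        mask = cluster_of == k
        n_in[k] = mask.sum()
        mu[k] = X[:, mask].mean(axis=1)
    mu_all_sum = X.sum(axis=1)

    iu, ju = np.triu_indices(len(genes), k=1)
    ranked: dict[str, list[PairStats]] = {}
    for c, k in cidx.items():
        nc, nt = int(n_in[k]), n - int(n_in[k])
        if nc == 0 or nt == 0:
            ranked[c] = []
            continue
        p_in_m = per_cluster[k] / nc
        p_out_m = (total - per_cluster[k]) / nt
        pd_m = p_in_m - p_out_m
        # canonical orientation: the one with the larger PD (>= 0 up to ties)
        pd_ij = pd_m[iu, ju]
        pd_ji = pd_m[ju, iu]
        use_ij = pd_ij >= pd_ji
        a_idx = np.where(use_ij, iu, ju)
        b_idx = np.where(use_ij, ju, iu)
        pd_c = np.where(use_ij, pd_ij, pd_ji)
        keep = pd_c >= pd_min
        if not keep.any():
            logger.warning("no pair passed pd_min=%.3g for cluster %s", pd_min, c)
            ranked[c] = []
            continue
        a_idx, b_idx, pd_c = a_idx[keep], b_idx[keep], pd_c[keep]
        mu_in = mu[k]
        mu_out = (mu_all_sum - mu_in * nc) / nt
        q = mu_in[a_idx] - mu_in[b_idx]
        r = mu_out[a_idx] - mu_out[b_idx]
        score = np.abs(pd_c) * (-1.0 * q * r)
        recs = [
            PairStats(
                genes[a_idx[m]],
                genes[b_idx[m]],
                c,
                float(per_cluster[k][a_idx[m], b_idx[m]] / nc),
                float((total[a_idx[m], b_idx[m]] - per_cluster[k][a_idx[m], b_idx[m]]) / nt),
                float(pd_c[m]),
                float(q[m]),
                float(r[m]),
                score=float(score[m]),
            )
            for m in range(len(a_idx))
        ]
        recs.sort(key=lambda st: (-st.score, -st.pd, st.gene_a, st.gene_b))
        ranked[c] = recs
    return ranked


# ---------------------------------------------------------------------------
# Greedy selection under a correlation cap
# ---------------------------------------------------------------------------

def select_features(
    ranked: dict[str, list[PairStats]],
    expr: ExpressionMatrix,
    labels: ClusterLabeling | None = None,
    k_per_cluster: int = 10,
    corr_max: float = 0.85,
) -> FeatureSet:
    """Walk each cluster's ranking top-down, keeping pairs under a correlation cap.

    A pair is accepted iff neither member gene's expression correlates
    (Pearson on log1p-transformed values, across labeled samples — all
    samples when ``labels`` is None) above ``corr_max`` with any gene
    already selected for that cluster. The log transform is the field's
    standard scale for expression correlation; on raw exponential-scale
    values the sample correlation is dominated by the few most extreme
    samples. Because a gene's self-correlation is 1, a gene can never be
    selected twice within a cluster. Selection stops at ``k_per_cluster``
    pairs or when the ranking is exhausted (with a warning).
    """
    if labels is not None:
        cols = labels.labeled(expr.sample_ids)
        sub = expr.select_samples(cols) if cols else expr
    else:
        sub = expr
    pairs: dict[str, list[tuple[str, str]]] = {}
    for cluster, recs in ranked.items():
        chosen: list[tuple[str, str]] = []
        chosen_rows: list[np.ndarray] = []
        for st in recs:
            if len(chosen) >= k_per_cluster:
                break
            rows = (
                np.log1p(sub.gene_row(st.gene_a)),
                np.log1p(sub.gene_row(st.gene_b)),
            )
            ok = True
            for row in rows:
                for prev in chosen_rows:
                    c = _pearson(row, prev)
                    if c > corr_max:
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                chosen.append((st.gene_a, st.gene_b))
                chosen_rows.extend(rows)
        if len(chosen) < k_per_cluster:
            logger.warning(
                "cluster %s: only %d of %d requested pairs available",
                cluster, len(chosen), k_per_cluster,
            )
        pairs[cluster] = chosen
    return FeatureSet(
        pairs,
        provenance={"k_per_cluster": k_per_cluster, "corr_max": corr_max},
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        # a constant gene carries no correlation signal; treat as redundant
        # only with another identical constant
        return 1.0 if np.array_equal(x, y) else 0.0
    return float(np.corrcoef(x, y)[0, 1])


def cross_platform_refine(
    feature_set: FeatureSet,
    expr_primary: ExpressionMatrix,
    expr_secondary: ExpressionMatrix,
    corr_min: float = 0.5,
) -> FeatureSet:
    """Drop pairs whose genes do not track across two platform views.

    For each gene in each selected pair, the Spearman correlation between its
    primary and secondary values over the matched samples (ids present in
    both matrices) is computed; a pair is dropped when either member falls
    below ``corr_min``. Rank correlation is used because the two platforms
    are related by monotone, not linear, distortion.
    """
    matched = [s for s in expr_primary.sample_ids if s in set(expr_secondary.sample_ids)]
    if len(matched) < 3:
        raise ValidationError(
            f"need at least 3 matched samples across platforms, got {len(matched)}"
        )
    p = expr_primary.select_samples(matched)
    s = expr_secondary.select_samples(matched)
    corr_cache: dict[str, float] = {}

    def gene_corr(g: str) -> float:
        if g not in corr_cache:
            rho = sstats.spearmanr(p.gene_row(g), s.gene_row(g)).statistic
            corr_cache[g] = -1.0 if np.isnan(rho) else float(rho)
        return corr_cache[g]

    kept: dict[str, list[tuple[str, str]]] = {}
    for cluster, plist in feature_set.pairs.items():
        out = []
        for a, b in plist:
            if gene_corr(a) >= corr_min and gene_corr(b) >= corr_min:
                out.append((a, b))
            else:
                logger.info("dropping pair (%s, %s) in %s: cross-platform corr "
                            "%.2f / %.2f < %.2f", a, b, cluster,
                            gene_corr(a), gene_corr(b), corr_min)
        kept[cluster] = out
    prov = dict(feature_set.provenance)
    prov["cross_platform_corr_min"] = corr_min
    return FeatureSet(kept, provenance=prov)
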