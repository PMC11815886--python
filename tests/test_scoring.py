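"""Pair statistics: hand-computed examples, oracle equivalence, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pairclass as pc
from pairclass.exceptions import ValidationError

from conftest import monotone_transform


def _matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pc.ExpressionMatrix(genes, samples, values)


def _labels(assignment):
    return pc.ClusterLabeling(assignment, sorted(set(assignment.values())))


class TestProportionDifference:
    def test_hand_computed_six_samples(self):
        # in-cluster (a,b) pairs (1,2),(0.5,3),(2,2.5); out (5,1),(4,2),(3,3.5)
        expr = _matrix(
            [[1, 0.5, 2, 5, 4, 3], [2, 3, 2.5, 1, 2, 3.5]], genes=["A", "B"]
        )
        labels = _labels({f"s{j}": ("in" if j < 3 else "out") for j in range(6)})
        st_ = pc.proportion_difference(expr, labels, "in", ("A", "B"))
        assert st_.p_in == 1.0
        assert st_.p_out == pytest.approx(1 / 3)
        assert st_.pd == pytest.approx(2 / 3)
        assert st_.q == pytest.approx(-4 / 3)
        assert st_.r == pytest.approx(11 / 6)
        assert pc.pair_score(st_) == pytest.approx(44 / 27)

    def test_uniform_ordering_gives_zero_pd(self):
        expr = _matrix([[1, 1, 1, 1], [2, 3, 2, 5]], genes=["A", "B"])
        labels = _labels({"s0": "x", "s1": "x", "s2": "y", "s3": "y"})
        st_ = pc.proportion_difference(expr, labels, "x", ("A", "B"))
        assert st_.p_in == st_.p_out == 1.0
        assert st_.pd == 0.0

    def test_ties_count_as_not_less(self):
        expr = _matrix([[2, 3, 4, 5], [2, 3, 4, 5]], genes=["A", "B"])
        labels = _labels({"s0": "x", "s1": "x", "s2": "y", "s3": "y"})
        st_ = pc.proportion_difference(expr, labels, "x", ("A", "B"))
        assert st_.p_in == st_.p_out == 0.0
        assert st_.pd == 0.0 and st_.q == 0.0 and st_.r == 0.0

    def test_empty_groups_error(self):
        expr = _matrix([[1, 2], [2, 1]], genes=["A", "B"])
        labels = pc.ClusterLabeling({"s0": "x", "s1": "y"}, ["x", "y", "z"])
        with pytest.raises(ValidationError):
            pc.proportion_difference(expr, labels, "z", ("A", "B"))


class TestScores:
    @given(
        pd_=st.floats(-1, 1), q=st.floats(-10, 10), r=st.floats(-10, 10)
    )
    @settings(max_examples=200, derandomize=True)
    def test_score_algebra(self, pd_, q, r):
        st_ = pc.PairStats("A", "B", "c", 0.5, 0.5, pd_, q, r)
        s = pc.pair_score(st_)
        assert s == abs(pd_) * (-1 * q * r)
        assert abs(s) <= abs(q * r) + 1e-12
        if pd_ == 0:
            assert s == 0
        if s > 0:
            assert q * r < 0 and pd_ != 0

    def test_updated_score_examples(self):
        st_ = pc.PairStats("A", "B", "c", 0, 0, 0.8, -1.0, 2.0)
        assert pc.updated_pair_score(st_, 0.7) == pytest.approx(1.12)
        assert pc.updated_pair_score(st_, 0.0) == 0.0
        # discordant direction across cohorts is zeroed, not magnitude-scored
        assert pc.updated_pair_score(st_, -0.7) == 0.0
        with pytest.raises(ValidationError):
            pc.updated_pair_score(st_, 1.5)


def naive_pair_stats(expr, labels, cluster, gene_a, gene_b):
    """Independent double-loop oracle for p_in/p_out/PD/Q/R."""
    n_in = n_out = c_in = c_out = 0
    s_in = s_out = 0.0
    for j, sid in enumerate(expr.sample_ids):
        if sid not in labels.assignments:
            continue
        a = expr.values[expr.gene_ids.index(gene_a), j]
        b = expr.values[expr.gene_ids.index(gene_b), j]
        if labels.assignments[sid] == cluster:
            n_in += 1
            c_in += a < b
            s_in += a - b
        else:
            n_out += 1
            c_out += a < b
            s_out += a - b
    return c_in / n_in, c_out / n_out, c_in / n_in - c_out / n_out, s_in / n_in, s_out / n_out


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rank_pairs_matches_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        expr = _matrix(rng.lognormal(2, 1, size=(15, 30)))
        labs = rng.choice(["c1", "c2", "c3"], 30)
        labels = _labels({f"s{j}": labs[j] for j in range(30)})
        ranked = pc.rank_pairs(expr, labels, pd_min=0.0)
        for cluster, recs in ranked.items():
            for st_ in recs[:40]:
                p_in, p_out, pd_, q, r = naive_pair_stats(
                    expr, labels, cluster, st_.gene_a, st_.gene_b
                )
                assert st_.p_in == pytest.approx(p_in, abs=1e-12)
                assert st_.p_out == pytest.approx(p_out, abs=1e-12)
                assert st_.pd == pytest.approx(pd_, abs=1e-12)
                assert st_.q == pytest.approx(q, abs=1e-9)
                assert st_.r == pytest.approx(r, abs=1e-9)

    def test_single_pair_matches_oracle(self):
        rng = np.random.default_rng(3)
        expr = _matrix(rng.lognormal(2, 1, size=(6, 20)))
        labels = _labels({f"s{j}": "c1" if j % 3 == 0 else "c2" for j in range(20)})
        st_ = pc.proportion_difference(expr, labels, "c1", ("g2", "g5"))
        p_in, p_out, pd_, q, r = naive_pair_stats(expr, labels, "c1", "g2", "g5")
        assert (st_.p_in, st_.p_out) == (p_in, p_out)
        assert st_.pd == pd_
        assert st_.q == pytest.approx(q) and st_.r == pytest.approx(r)


class TestInvariances:
    @pytest.mark.parametrize("seed", [0, 7])
    def test_monotone_invariance_of_rank_stats(self, seed):
        rng = np.random.default_rng(seed)
        expr = _matrix(rng.lognormal(2, 1, size=(10, 24)))
        labels = _labels({f"s{j}": "c1" if j < 8 else "c2" for j in range(24)})
        transformed = _matrix(monotone_transform(expr.values, rng))
        for pair in [("g0", "g1"), ("g3", "g9"), ("g4", "g7")]:
            a = pc.proportion_difference(expr, labels, "c1", pair)
            b = pc.proportion_difference(transformed, labels, "c1", pair)
            assert (a.p_in, a.p_out, a.pd) == (b.p_in, b.p_out, b.pd)

    def test_antisymmetry_without_ties(self):
        rng = np.random.default_rng(5)
        expr = _matrix(rng.lognormal(2, 1, size=(4, 30)))
        labels = _labels({f"s{j}": "c1" if j < 10 else "c2" for j in range(30)})
        fwd = pc.proportion_difference(expr, labels, "c1", ("g0", "g2"))
        rev = pc.proportion_difference(expr, labels, "c1", ("g2", "g0"))
        assert fwd.pd == pytest.approx(-rev.pd)
        assert fwd.p_in == pytest.approx(1 - rev.p_in)


class TestRanking:
    def test_impossible_pd_min_empties_all_clusters(self, small_cohort):
        ranked = pc.rank_pairs(small_cohort.expression, small_cohort.labels, pd_min=1.01)
        assert all(len(v) == 0 for v in ranked.values())

    def test_planted_pairs_rank_in_own_cluster(self, small_cohort):
        ranked = pc.rank_pairs(small_cohort.expression, small_cohort.labels)
        for cluster in small_cohort.labels.label_set:
            found = {
                frozenset((s.gene_a, s.gene_b)) for s in ranked[cluster]
            }
            for pair in small_cohort.truth.pairs_for(cluster):
                assert frozenset(pair) in found

    def test_planted_pair_scores_higher_in_own_cluster(self, small_cohort):
        # with >= 3 clusters a pair reversed only in its own cluster is
        # diluted everywhere else (the other clusters share its orientation)
        for cl, a, b, _, _ in small_cohort.truth.planted_pairs:
            own = pc.proportion_difference(
                small_cohort.expression, small_cohort.labels, cl, (a, b)
            )
            pc.pair_score(own)
            for other in small_cohort.labels.label_set:
                if other == cl:
                    continue
                cross = pc.proportion_difference(
                    small_cohort.expression, small_cohort.labels, other, (a, b)
                )
                pc.pair_score(cross)
                assert abs(own.pd) > abs(cross.pd)
                assert own.score > cross.score


class TestSelection:
    def test_shared_gene_blocks_second_pair(self):
        rng = np.random.default_rng(0)
        expr = _matrix(rng.lognormal(2, 1, size=(5, 20)))
        ranked = {
            "c1": [
                pc.PairStats("g0", "g1", "c1", 1, 0, 1, -1, 1, score=5.0),
                pc.PairStats("g0", "g2", "c1", 1, 0, 1, -1, 1, score=4.0),
                pc.PairStats("g3", "g4", "c1", 1, 0, 1, -1, 1, score=3.0),
            ]
        }
        fs = pc.select_features(ranked, expr, k_per_cluster=10)
        assert fs.pairs["c1"] == [("g0", "g1"), ("g3", "g4")]

    def test_exact_copy_gene_rejected(self):
        rng = np.random.default_rng(1)
        base = rng.lognormal(2, 1, size=(4, 20))
        values = np.vstack([base, base[1]])  # g4 is an exact copy of g1
        expr = _matrix(values, genes=["g0", "g1", "g2", "g3", "g4"])
        ranked = {
            "c1": [
                pc.PairStats("g0", "g1", "c1", 1, 0, 1, -1, 1, score=5.0),
                pc.PairStats("g4", "g2", "c1", 1, 0, 1, -1, 1, score=4.0),
                pc.PairStats("g2", "g3", "c1", 1, 0, 1, -1, 1, score=3.0),
            ]
        }
        fs = pc.select_features(ranked, expr, k_per_cluster=10)
        assert ("g4", "g2") not in fs.pairs["c1"]
        assert ("g2", "g3") in fs.pairs["c1"]

    def test_selected_set_respects_corr_cap(self, small_cohort, small_features):
        labeled = small_cohort.labels.labeled(small_cohort.expression.sample_ids)
        sub = small_cohort.expression.select_samples(labeled)
        for cluster, plist in small_features.pairs.items():
            genes = [g for p in plist for g in p]
            for i, g1 in enumerate(genes):
                for g2 in genes[:i]:
                    pair_mates = any(
                        set((g1, g2)) == set(p) for p in plist
                    )
                    if pair_mates:
                        continue  # cap applies between pairs, not within one
                    c = np.corrcoef(
                        np.log1p(sub.gene_row(g1)), np.log1p(sub.gene_row(g2))
                    )[0, 1]
                    assert c <= 0.85 + 1e-9


class TestCrossPlatformRefine:
    def test_monotone_secondary_drops_nothing(self, small_cohort, small_features):
        rng = np.random.default_rng(2)
        second = pc.ExpressionMatrix(
            list(small_cohort.expression.gene_ids),
            list(small_cohort.expression.sample_ids),
            monotone_transform(small_cohort.expression.values, rng),
        )
        refined = pc.cross_platform_refine(
            small_features, small_cohort.expression, second, corr_min=0.5
        )
        assert refined.pairs == small_features.pairs

    def test_noise_gene_pairs_dropped(self, small_cohort, small_features):
        rng = np.random.default_rng(3)
        victim = small_features.pairs[small_features.clusters[0]][0][0]
        values = small_cohort.expression.values.copy()
        values[small_cohort.expression.gene_position(victim)] = rng.lognormal(
            2, 1, values.shape[1]
        )
        second = pc.ExpressionMatrix(
            list(small_cohort.expression.gene_ids),
            list(small_cohort.expression.sample_ids),
            values,
        )
        refined = pc.cross_platform_refine(
            small_features, small_cohort.expression, second, corr_min=0.5
        )
        for plist in refined.pairs.values():
            assert all(victim not in p for p in plist)

    def test_empty_feature_set_passes_through(self, small_cohort):
        fs = pc.FeatureSet({"c1": []})
        out = pc.cross_platform_refine(
            fs, small_cohort.expression, small_cohort.expression, corr_min=0.5
        )
        assert out.pairs == {"c1": []}

    def test_too_few_matched_samples_error(self, small_cohort, small_features):
        second = small_cohort.expression.select_samples(
            small_cohort.expression.sample_ids[:2]
        )
        with pytest.raises(ValidationError):
            pc.cross_platform_refine(
                small_features, small_cohort.expression, second, corr_min=0.5
            )
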