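"""Rankers, rank-graph aggregation, PageRank, metrics and incremental selection."""

import math

import networkx as nx
import numpy as np
import pytest

from ctdselect import (
    FeatureRanking,
    aggregate_rankings,
    build_rank_graph,
    classification_metrics,
    incremental_select,
    mrmd_score,
    pagerank,
    rank_features,
)
from ctdselect.mrmd_ensemble import PageRankConvergenceError, RankingError
from conftest import make_matrix

# ---------------------------------------------------------------------------
# independent direct-formula oracles
# ---------------------------------------------------------------------------


def anova_f_oracle(x, y):
    """One-way F statistic: between-class over within-class mean squares."""
    groups = [x[y == c] for c in np.unique(y)]
    grand = x.mean()
    k, n = len(groups), len(x)
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return (ssb / (k - 1)) / (ssw / (n - k))


def chi2_oracle(x, y):
    """Feature-selection chi-square: per-class feature sums vs prior-expected."""
    classes = np.unique(y)
    observed = np.array([x[y == c].sum() for c in classes])
    expected = x.sum() * np.array([(y == c).mean() for c in classes])
    return float((((observed - expected) ** 2) / expected).sum())


def mrmd_oracle(X, y):
    """Literal evaluation of the rescaled |PCC| + mean-distance score."""
    n_feat = X.shape[1]
    corr, dist = np.zeros(n_feat), np.zeros(n_feat)
    for j in range(n_feat):
        xj = X[:, j]
        cx, cy = xj - xj.mean(), y - y.mean()
        corr[j] = abs((cx * cy).sum() / math.sqrt((cx**2).sum() * (cy**2).sum()))
        dist[j] = np.mean(
            [math.sqrt(((xj - X[:, k]) ** 2).sum()) for k in range(n_feat) if k != j]
        )

    def rescale(v):
        span = v.max() - v.min()
        return np.zeros_like(v) if span == 0 else (v - v.min()) / span

    return rescale(corr) + rescale(dist)


def entropy(labels):
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def mi_oracle(a, b):
    """Mutual information (nats) via H(a) + H(b) - H(a,b)."""
    joint = np.array([f"{x}|{y}" for x, y in zip(a, b)])
    return entropy(a) + entropy(b) - entropy(joint)


def discretize_oracle(x, bins=3):
    """Equal-frequency 3-binning by quantile thresholds (independent route)."""
    lo, hi = np.quantile(x, [1 / 3, 2 / 3])
    thresholds = sorted(set([lo, hi]))
    return np.array([sum(v > t for t in thresholds) for v in x])


def random_labeled_matrix(rng, n_samples=10, n_features=5):
    y = np.array([1] * (n_samples // 2) + [0] * (n_samples - n_samples // 2))
    X = rng.random((n_samples, n_features))
    return make_matrix(X, y)


# ---------------------------------------------------------------------------
# rankers
# ---------------------------------------------------------------------------


class TestRankerOracles:
    @pytest.mark.parametrize("trial", range(10))
    def test_anova_scores_match_direct_formula(self, trial):
        rng = np.random.default_rng(1000 + trial)
        m = random_labeled_matrix(rng)
        ranking = rank_features(m, "anova")
        expected = {
            name: anova_f_oracle(m.data[name].to_numpy(), m.y)
            for name in m.feature_names
        }
        for name, score in zip(ranking.ordered_features, ranking.scores):
            assert score == pytest.approx(expected[name], abs=1e-9)

    @pytest.mark.parametrize("trial", range(10))
    def test_chi2_scores_match_direct_formula(self, trial):
        rng = np.random.default_rng(2000 + trial)
        m = random_labeled_matrix(rng)
        ranking = rank_features(m, "chi2")
        expected = {
            name: chi2_oracle(m.data[name].to_numpy(), m.y)
            for name in m.feature_names
        }
        for name, score in zip(ranking.ordered_features, ranking.scores):
            assert score == pytest.approx(expected[name], abs=1e-9)

    @pytest.mark.parametrize("trial", range(10))
    def test_mrmd_scores_match_direct_formula(self, trial):
        rng = np.random.default_rng(3000 + trial)
        m = random_labeled_matrix(rng)
        expected = mrmd_oracle(m.X, m.y)
        assert np.allclose(mrmd_score(m), expected, atol=1e-9)


class TestRankerBehavior:
    def test_anova_label_copy_beats_constant_feature(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        X = np.column_stack([y.astype(float), np.full(6, 3.0)])
        m = make_matrix(X, y)
        ranking = rank_features(m, "anova")
        assert ranking.ordered_features[0] == "f1"

    def test_chi2_rejects_negative_values(self):
        m = make_matrix([[1.0, -1.0], [2.0, 0.5], [0.3, 0.1], [0.2, 0.9]], [1, 1, 0, 0])
        with pytest.raises(RankingError, match="nonnegative"):
            rank_features(m, "chi2")

    def test_single_class_labels_rejected(self):
        import pandas as pd

        from ctdselect import FeatureMatrix
        from ctdselect.seq_dataset import FeatureTableError

        df = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["a", "b"], columns=["f1", "f2"])
        with pytest.raises(FeatureTableError):
            FeatureMatrix(df, pd.Series([1, 1], index=["a", "b"]))

    def test_mrmd_identical_columns_get_symmetric_scores(self, rng):
        y = np.array([1, 1, 0, 0])
        col = rng.random(4)
        other = rng.random(4)
        m = make_matrix(np.column_stack([col, col, other]), y)
        scores = mrmd_score(m)
        assert scores[0] == pytest.approx(scores[1], abs=1e-12)
        ranking = rank_features(m, "mrmd")
        pos1 = ranking.ordered_features.index("f1")
        pos2 = ranking.ordered_features.index("f2")
        assert pos1 < pos2  # tie broken by name

    def test_mrmd_label_copy_has_maximal_correlation_term(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        X = np.column_stack([y.astype(float), [0.2, 0.8, 0.4, 0.7, 0.1, 0.9]])
        m = make_matrix(X, y)
        expected = mrmd_oracle(m.X, m.y)
        # the label copy owns the rescaled-correlation maximum (term = 1)
        assert np.allclose(mrmd_score(m), expected, atol=1e-12)
        assert expected[0] >= 1.0

    def test_mrmd_zero_variance_feature_warns(self):
        m = make_matrix([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0], [4.0, 5.0]], [1, 1, 0, 0])
        with pytest.warns(UserWarning, match="zero variance"):
            mrmd_score(m)

    def test_mrmr_penalizes_duplicated_feature(self, rng):
        y = np.array([1] * 15 + [0] * 15)
        f1 = y + rng.normal(scale=0.1, size=30)
        f2 = -y + rng.normal(scale=0.1, size=30)  # informative, distinct sign
        m = make_matrix(np.column_stack([f1, f2, f1]), y, names=["f1", "f2", "f3"])
        ranking = rank_features(m, "mrmr")
        first = ranking.ordered_features[0]
        assert first in ("f1", "f3")
        # the duplicate of the first pick is maximally redundant -> f2 second
        assert ranking.ordered_features[1] == "f2"

    def test_mrmr_order_matches_exhaustive_greedy_oracle(self, rng):
        y = np.array([1] * 10 + [0] * 10)
        X = rng.random((20, 4))
        X[:, 0] += y
        m = make_matrix(X, y)
        ranking = rank_features(m, "mrmr")

        disc = [discretize_oracle(X[:, j]) for j in range(4)]
        names = m.feature_names
        remaining, selected = list(range(4)), []
        while remaining:
            if not selected:
                crit = {j: mi_oracle(disc[j], y) for j in remaining}
            else:
                crit = {
                    j: mi_oracle(disc[j], y)
                    - np.mean([mi_oracle(disc[j], disc[s]) for s in selected])
                    for j in remaining
                }
            best = min(remaining, key=lambda j: (-crit[j], names[j]))
            selected.append(best)
            remaining.remove(best)
        assert ranking.ordered_features == [names[j] for j in selected]

    @pytest.mark.parametrize("method", ["lasso", "rfe", "mic"])
    def test_sequentialish_rankers_put_informative_feature_first(
        self, method, separable_matrix
    ):
        ranking = rank_features(separable_matrix, method, seed=0)
        assert sorted(ranking.ordered_features) == sorted(separable_matrix.feature_names)
        assert ranking.ordered_features[0] == "f1"

    def test_mic_fallback_is_flagged(self, separable_matrix):
        ranking = rank_features(separable_matrix, "mic")
        try:
            import minepy  # noqa: F401

            assert "minepy" in ranking.notes
        except ImportError:
            assert "fallback" in ranking.notes


# ---------------------------------------------------------------------------
# rank graph + pagerank
# ---------------------------------------------------------------------------


def ranking_of(method, order):
    return FeatureRanking(method, list(order), np.arange(len(order), 0, -1, dtype=float))


class TestRankGraph:
    def test_single_ranking_chain_edges(self):
        g = build_rank_graph([ranking_of("m1", ["a", "b", "c"])])
        assert g.edge_weight("c", "b") == 1
        assert g.edge_weight("b", "a") == 1
        assert g.edge_weight("a", "b") == 0

    def test_identical_rankings_accumulate_multiplicity(self):
        rankings = [ranking_of("m1", ["a", "b", "c"]), ranking_of("m2", ["a", "b", "c"])]
        g = build_rank_graph(rankings)
        assert g.edge_weight("c", "b") == 2 and g.edge_weight("b", "a") == 2

    def test_opposed_rankings_form_a_two_cycle(self):
        g = build_rank_graph([ranking_of("m1", ["a", "b"]), ranking_of("m2", ["b", "a"])])
        assert g.edge_weight("b", "a") == 1 and g.edge_weight("a", "b") == 1

    def test_total_edge_multiplicity_invariant(self, rng):
        names = [f"f{i}" for i in range(6)]
        rankings = [
            ranking_of(f"m{k}", rng.permutation(names).tolist()) for k in range(4)
        ]
        g = build_rank_graph(rankings)
        assert g.total_edge_multiplicity == 4 * (len(names) - 1)

    def test_empty_or_mismatched_rankings_rejected(self):
        with pytest.raises(ValueError):
            build_rank_graph([])
        with pytest.raises(ValueError, match="different feature set"):
            build_rank_graph([ranking_of("m1", ["a", "b"]), ranking_of("m2", ["a", "c"])])


class TestPageRank:
    def test_edgeless_graph_is_uniform(self):
        rankings = [ranking_of("m1", ["a", "b", "c", "d"])]
        g = build_rank_graph(rankings)
        g.graph.remove_edges_from(list(g.graph.edges))
        scores = pagerank(g)
        assert all(s == pytest.approx(0.25, abs=1e-9) for s in scores.values())

    def test_single_edge_favors_target(self):
        g = build_rank_graph([ranking_of("m1", ["b", "a"])])  # edge a -> b
        scores = pagerank(g)
        assert scores["b"] > scores["a"]
        # cross-check against the networkx implementation
        expected = nx.pagerank(g.graph, alpha=0.85, tol=1e-12, max_iter=1000)
        for node in scores:
            assert scores[node] == pytest.approx(expected[node], abs=1e-8)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_networkx_on_random_rank_graphs(self, trial):
        rng = np.random.default_rng(4000 + trial)
        names = [f"f{i}" for i in range(rng.integers(3, 9))]
        rankings = [
            ranking_of(f"m{k}", rng.permutation(names).tolist())
            for k in range(rng.integers(1, 6))
        ]
        g = build_rank_graph(rankings)
        scores = pagerank(g)
        assert sum(scores.values()) == pytest.approx(1.0, abs=1e-9)
        expected = nx.pagerank(g.graph, alpha=0.85, tol=1e-12, max_iter=1000)
        for node in scores:
            assert scores[node] == pytest.approx(expected[node], abs=1e-7)

    def test_unanimous_rankings_are_reproduced(self):
        order = ["f1", "f2", "f3", "f4", "f5"]
        rankings = [ranking_of(f"m{k}", order) for k in range(7)]
        agg_order, scores = aggregate_rankings(rankings)
        assert agg_order == order
        values = [scores[f] for f in order]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_nonconvergence_raises(self):
        g = build_rank_graph([ranking_of("m1", ["a", "b", "c"])])
        with pytest.raises(PageRankConvergenceError):
            pagerank(g, max_iter=1)

    def test_damping_out_of_range_rejected(self):
        g = build_rank_graph([ranking_of("m1", ["a", "b"])])
        with pytest.raises(ValueError, match="damping"):
            pagerank(g, damping=1.0)


# ---------------------------------------------------------------------------
# metrics + incremental selection
# ---------------------------------------------------------------------------


class TestClassificationMetrics:
    def test_perfect_predictions(self):
        y = np.array([1, 1, 0, 0, 1])
        m = classification_metrics(y, y, y.astype(float))
        assert (m.precision, m.recall, m.f1, m.mcc, m.auc) == (1, 1, 1, 1, 1)

    def test_symmetric_confusion_has_zero_mcc(self):
        truth = np.array([1, 1, 0, 0])
        pred = np.array([1, 0, 1, 0])  # TP=FP=TN=FN=1
        m = classification_metrics(truth, pred, pred.astype(float))
        assert m.mcc == pytest.approx(0.0, abs=1e-12)

    def test_confusion_counts_match_closed_forms(self):
        # TP=3, FP=1, FN=2, TN=4
        truth = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        pred = np.array([1, 1, 1, 0, 0, 1, 0, 0, 0, 0])
        m = classification_metrics(truth, pred, pred.astype(float))
        assert m.precision == pytest.approx(3 / 4, abs=1e-12)
        assert m.recall == pytest.approx(3 / 5, abs=1e-12)
        assert m.f1 == pytest.approx(2 * (3 / 4) * (3 / 5) / (3 / 4 + 3 / 5), abs=1e-12)
        assert m.mcc == pytest.approx((3 * 4 - 1 * 2) / math.sqrt(4 * 5 * 5 * 6), abs=1e-12)
        # Mann-Whitney AUC with tied scores: (3*4 + 0.5*(3*1 + 2*4)) / 25
        assert m.auc == pytest.approx(0.7, abs=1e-12)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            classification_metrics(np.ones(4), np.ones(4), np.ones(4))

    def test_zero_denominator_warns_and_returns_zero(self):
        truth = np.array([1, 1, 0, 0])
        pred = np.zeros(4, dtype=int)
        with pytest.warns(UserWarning, match="margin is zero"):
            m = classification_metrics(truth, pred, np.full(4, 0.5))
        assert m.precision == 0.0 and m.recall == 0.0 and m.f1 == 0.0


class TestIncrementalSelect:
    def test_separating_first_feature_is_chosen_alone(self, separable_matrix):
        order = ["f1", "f2", "f3", "f4", "f5"]
        result = incremental_select(separable_matrix, order, seed=0, n_estimators=30)
        assert result.chosen_prefix == ["f1"]
        assert result.prefix_metrics[1].f1 == pytest.approx(1.0)

    def test_exact_ties_resolve_to_shortest_prefix(self):
        y = np.array([1] * 10 + [0] * 10)
        X = np.column_stack([y, y, y]).astype(float)  # three identical perfect features
        m = make_matrix(X, y)
        result = incremental_select(m, ["f1", "f2", "f3"], seed=0, n_estimators=20)
        # every prefix separates perfectly, so all tie at f1=1.0
        assert all(v.f1 == pytest.approx(1.0) for v in result.prefix_metrics.values())
        assert result.chosen_prefix == ["f1"]

    def test_same_seed_reproduces_result_exactly(self, separable_matrix):
        order = ["f2", "f1", "f3", "f4", "f5"]
        r1 = incremental_select(separable_matrix, order, seed=7, n_estimators=30)
        r2 = incremental_select(separable_matrix, order, seed=7, n_estimators=30)
        assert r1.chosen_prefix == r2.chosen_prefix
        for k in r1.prefix_metrics:
            assert r1.prefix_metrics[k] == r2.prefix_metrics[k]

    def test_order_must_permute_feature_names(self, separable_matrix):
        from ctdselect.seq_dataset import FeatureTableError

        with pytest.raises(FeatureTableError, match="permutation"):
            incremental_select(separable_matrix, ["f1", "f2"], seed=0)

    def test_too_few_samples_per_class_for_folds(self, rng):
        m = make_matrix(rng.normal(size=(6, 2)), [1, 1, 1, 0, 0, 0])
        with pytest.raises(RankingError, match="5-fold"):
            incremental_select(m, ["f1", "f2"], folds=5, seed=0)

    def test_stride_still_evaluates_full_length(self, separable_matrix):
        order = ["f1", "f2", "f3", "f4", "f5"]
        result = incremental_select(
            separable_matrix, order, seed=0, n_estimators=20, stride=3
        )
        assert sorted(result.prefix_metrics) == [1, 4, 5]

    def test_signal_feature_always_recovered_across_seeds(self):
        # exactly one feature carries the class signal; ten independent draws
        for seed in range(10):
            rng = np.random.default_rng(5000 + seed)
            y = np.array([1] * 20 + [0] * 20)
            X = rng.normal(size=(40, 5))
            X[:, 2] = y + rng.normal(scale=0.05, size=40)
            m = make_matrix(X, y)
            rankings = [rank_features(m, meth, seed=seed) for meth in ("anova", "mic", "mrmd")]
            order, _ = aggregate_rankings(rankings)
            result = incremental_select(m, order, seed=seed, n_estimators=25)
            assert "f3" in result.chosen_prefix
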