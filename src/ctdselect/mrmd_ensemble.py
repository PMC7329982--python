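"""Ensemble feature selection: multi-ranker + PageRank aggregation + CV prefix search.

The selection engine works in three stages:

1. **Rank** the features of a labeled matrix with up to seven methods:
   ANOVA F, max-relevance-max-distance (MRMD), maximal information
   coefficient (MIC, with a documented discretized-mutual-information
   fallback), L1-logistic (lasso) coefficients, greedy mRMR, chi-square,
   and recursive feature elimination (RFE).
2. **Aggregate** the rankings into a directed graph — each ranking
   contributes one edge worse -> better per consecutive pair — and score
   nodes with PageRank (power iteration, uniform teleport, dangling mass
   redistributed uniformly). Features are ordered by descending score,
   ties broken lexicographically by name.
3. **Select** a prefix of the aggregated order by training a random-forest
   classifier under stratified k-fold cross-validation at every prefix
   length, recording precision/recall/F1/MCC/AUC, and keeping the shortest
   prefix maximizing the objective metric.

All randomness (fold assignment, forests, L1 solver) is governed by a
single seed, so a run is a pure function of (matrix, parameters, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE, chi2 as sk_chi2, f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    f1_score,
    matthews_corrcoef,
    mutual_info_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .seq_dataset import FeatureMatrix, FeatureTableError

RANKER_METHODS = ("anova", "mrmd", "mic", "lasso", "mrmr", "chi2", "rfe")

#: Metric names recorded at every prefix length.
METRIC_NAMES = ("precision", "recall", "f1", "mcc", "auc")

# Fixed hyperparameters (single documented operating point; see docs).
LASSO_C = 1.0
MRMR_BINS = 3
RF_N_ESTIMATORS = 100
PAGERANK_DAMPING = 0.85
PAGERANK_TOL = 1e-9
PAGERANK_MAX_ITER = 1000


class RankingError(ValueError):
    """Raised on invalid ranking inputs (degenerate labels, negative chi2 input...)."""


class PageRankConvergenceError(RuntimeError):
    """Raised when power iteration fails to reach the tolerance."""


@dataclass
class FeatureRanking:
    """One method's ordering of the features, best first.

    ``scores`` are nonincreasing along ``ordered_features``. For score-based
    methods they are the statistic values; for sequential methods (mRMR,
    RFE) they are descending rank scores (n, n-1, ..., 1), since the greedy
    criterion value itself is not monotone along the selection order.
    """

    method: str
    ordered_features: list[str]
    scores: np.ndarray
    notes: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.ordered_features) != len(self.scores):
            raise RankingError("ordered_features and scores length mismatch")
        if np.any(np.diff(self.scores) > 1e-12):
            raise RankingError(f"{self.method}: scores increase along the ranking")


@dataclass
class RankGraph:
    """Directed feature graph; edge weight = how often 'from' lost to 'to'."""

    graph: nx.DiGraph

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_weight(self, u: str, v: str) -> int:
        if self.graph.has_edge(u, v):
            return int(self.graph[u][v]["weight"])
        return 0

    @property
    def total_edge_multiplicity(self) -> int:
        return int(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))


@dataclass(frozen=True)
class Metrics:
    """Binary-classification summary: precision, recall, F1, MCC, ROC AUC."""

    precision: float
    recall: float
    f1: float
    mcc: float
    auc: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass
class SelectionResult:
    """Outcome of the incremental prefix search along an aggregated order."""

    aggregated_order: list[str]
    prefix_metrics: dict[int, Metrics]
    chosen_prefix: list[str]
    objective_metric: str

    @property
    def objective_value(self) -> float:
        return getattr(self.prefix_metrics[len(self.chosen_prefix)], self.objective_metric)


@dataclass
class EnsembleResult:
    """Full record of one ensemble selection run."""

    rankings: list[FeatureRanking]
    pagerank_scores: dict[str, float]
    selection: SelectionResult


# ---------------------------------------------------------------------------
# individual rankers
# ---------------------------------------------------------------------------


def _check_matrix(matrix: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    y = matrix.y
    if len(np.unique(y)) < 2:
        raise RankingError("ranking requires samples from both classes")
    counts = np.bincount(y)
    if counts.min() < 2:
        raise RankingError("ranking requires at least 2 samples per class")
    if matrix.n_features < 2:
        raise RankingError("ranking requires at least 2 features")
    return matrix.X, y


def _order_by_scores(
    names: Sequence[str], scores: np.ndarray, secondary: np.ndarray | None = None
) -> tuple[list[str], np.ndarray]:
    """Descending by score; ties by descending secondary, then name."""
    if secondary is None:
        secondary = np.zeros(len(names))
    idx = sorted(
        range(len(names)), key=lambda i: (-scores[i], -secondary[i], names[i])
    )
    return [names[i] for i in idx], scores[np.array(idx)]


def _discretize_equal_frequency(x: np.ndarray, bins: int = MRMR_BINS) -> np.ndarray:
    """Equal-frequency binning; constant columns collapse to a single bin."""
    qs = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(np.unique(qs), x, side="right")


def _mutual_information(x: np.ndarray, y: np.ndarray, bins: int = MRMR_BINS) -> float:
    """MI (nats) between a discretized feature and a discrete vector."""
    return float(mutual_info_score(_discretize_equal_frequency(x, bins), y))


def mrmd_score(matrix: FeatureMatrix) -> np.ndarray:
    """Max-relevance-max-distance score per feature.

    score(f) = rescaled |Pearson r(f, label)| + rescaled mean Euclidean
    distance from f's column to every other column; both terms min-max
    rescaled to [0,1] across features before summing (a degenerate term
    with zero spread contributes 0 for all features). A zero-variance
    feature gets correlation 0 (with a warning).
    """
    X, y = _check_matrix(matrix)
    n_feat = X.shape[1]
    corr = np.zeros(n_feat)
    for j in range(n_feat):
        col = X[:, j]
        if np.ptp(col) == 0:
            warnings.warn(
                f"feature {matrix.feature_names[j]!r} has zero variance; "
                "correlation term set to 0",
                stacklevel=2,
            )
            corr[j] = 0.0
        else:
            corr[j] = abs(stats.pearsonr(col, y)[0])
    dist = np.zeros(n_feat)
    for j in range(n_feat):
        others = [k for k in range(n_feat) if k != j]
        dist[j] = np.mean(
            [np.linalg.norm(X[:, j] - X[:, k]) for k in others]
        )

    def _rescale(v: np.ndarray) -> np.ndarray:
        span = v.max() - v.min()
        if span == 0:
            return np.zeros_like(v)
        return (v - v.min()) / span

    return _rescale(corr) + _rescale(dist)


def _rank_anova(matrix: FeatureMatrix, seed: int) -> FeatureRanking:
    X, y = _check_matrix(matrix)
    with warnings.catch_warnings():
        # constant features legitimately get F = 0; silence the advisories
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        f_stat, _ = f_classif(X, y)
    f_stat = np.nan_to_num(f_stat, nan=0.0, posinf=np.finfo(float).max)
    order, scores = _order_by_scores(matrix.feature_names, f_stat)
    return FeatureRanking("anova", order, scores)


def _rank_chi2(matrix: FeatureMatrix, seed: int) -> FeatureRanking:
    X, y = _check_matrix(matrix)
    if np.any(X < 0):
        raise RankingError("chi2 ranking requires nonnegative feature values")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        stat, _ = sk_chi2(X, y)
    stat = np.nan_to_num(stat, nan=0.0)
    order, scores = _order_by_scores(matrix.feature_names, stat)
    return FeatureRanking("chi2", order, scores)


def _rank_mrmd(matrix: FeatureMatrix, seed: int) -> FeatureRanking:
    scores = mrmd_score(matrix)
    order, ordered_scores = _order_by_scores(matrix.feature_names, scores)
    return FeatureRanking("mrmd", order, ordered_scores)


def _rank_mic(matrix: FeatureMatrix, seed: int) -> FeatureRanking:
    X, y = _check_matrix(matrix)
    try:  # pragma: no cover - exercised only where minepy is installed
        from minepy import MINE

        mine = MINE(alpha=0.6, c=15)
        scores = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            mine.compute_score(X[:, j], y.astype(float))
            scores[j] = mine.mic()
        notes = "mic: minepy MINE(alpha=0.6, c=15)"
    except ImportError:
        scores = np.array([_mutual_information(X[:, j], y) for j in range(X.shape[1])])
        notes = "mic fallback: equal-frequency discretized mutual information"
    order, ordered_scores = _order_by_scores(matrix.feature_names, scores)
    return FeatureRanking("mic", order, ordered_scores, notes=notes)


def _rank_lasso(matrix: FeatureMatrix, seed: int) -> FeatureRanking:
    X, y = _check_matrix(matrix)
    Xs = StandardScaler().fit_transform(X)
    model = LogisticRegression(
        l1_ratio=1.0, C=LASSO_C, solver="liblinear", random_state=seed, max_iter=1000
    )
    model.fit(Xs, y)
    coefs = np.abs(model.coef_.ravel())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        f_stat, _ = f_classif(X, y)
    f_stat = np.nan_to_num(f_stat, nan=0.0)
    # zero-coefficient ties resolved by univariate F, then name
    order, scores = _order_by_scores(matrix.feature_names, coefs, secondary=f_stat)
    return FeatureRanking("lasso", order, scores)


def _rank_mrmr(matrix: FeatureMatrix, seed: int) -> FeatureRanking:
    X, y = _check_matrix(matrix)
    names = matrix.feature_names
    n_feat = X.shape[1]
    disc = [_discretize_equal_frequency(X[:, j]) for j in range(n_feat)]
    relevance = np.array([float(mutual_info_score(d, y)) for d in disc])
    pair_mi = np.zeros((n_feat, n_feat))
    for j in range(n_feat):
        for k in range(j + 1, n_feat):
            pair_mi[j, k] = pair_mi[k, j] = float(mutual_info_score(disc[j], disc[k]))

    remaining = list(range(n_feat))
    selected: list[int] = []
    while remaining:
        if not selected:
            crit = {j: relevance[j] for j in remaining}
        else:
            crit = {
                j: relevance[j] - pair_mi[j, selected].mean() for j in remaining
            }
        best = min(remaining, key=lambda j: (-crit[j], names[j]))
        selected.append(best)
        remaining.remove(best)
    order = [names[j] for j in selected]
    scores = np.arange(n_feat, 0, -1, dtype=float)
    return FeatureRanking("mrmr", order, scores, notes="scores are rank positions")


def _rank_rfe(matrix: FeatureMatrix, seed: int) -> FeatureRanking:
    X, y = _check_matrix(matrix)
    base = RandomForestClassifier(
        n_estimators=RF_N_ESTIMATORS, random_state=seed, n_jobs=1
    )
    rfe = RFE(estimator=base, n_features_to_select=1, step=1)
    rfe.fit(X, y)
    # ranking_ == 1 is the last-surviving (best) feature
    scores = (X.shape[1] - rfe.ranking_ + 1).astype(float)
    order, ordered_scores = _order_by_scores(matrix.feature_names, scores)
    return FeatureRanking("rfe", order, ordered_scores, notes="scores are rank positions")


_RANKERS = {
    "anova": _rank_anova,
    "mrmd": _rank_mrmd,
    "mic": _rank_mic,
    "lasso": _rank_lasso,
    "mrmr": _rank_mrmr,
    "chi2": _rank_chi2,
    "rfe": _rank_rfe,
}


def rank_features(matrix: FeatureMatrix, method: str, seed: int = 0) -> FeatureRanking:
    """Rank all features of a labeled matrix with one method (best first)."""
    if method not in _RANKERS:
        raise ValueError(f"unknown ranking method {method!r}; choose from {RANKER_METHODS}")
    return _RANKERS[method](matrix, seed)


# ---------------------------------------------------------------------------
# rank aggregation
# ---------------------------------------------------------------------------


def build_rank_graph(rankings: Sequence[FeatureRanking]) -> RankGraph:
    """Accumulate each ranking's consecutive pairs into worse -> better edges."""
    if not rankings:
        raise ValueError("need at least one ranking")
    feature_set = set(rankings[0].ordered_features)
    g = nx.DiGraph()
    g.add_nodes_from(sorted(feature_set))
    for r in rankings:
        if set(r.ordered_features) != feature_set:
            raise ValueError(
                f"ranking {r.method!r} covers a different feature set"
            )
        for better, worse in zip(r.ordered_features, r.ordered_features[1:]):
            if g.has_edge(worse, better):
                g[worse][better]["weight"] += 1
            else:
                g.add_edge(worse, better, weight=1)
    return RankGraph(g)


def pagerank(
    rank_graph: RankGraph,
    damping: float = PAGERANK_DAMPING,
    tol: float = PAGERANK_TOL,
    max_iter: int = PAGERANK_MAX_ITER,
) -> dict[str, float]:
    """PageRank by power iteration with uniform teleport.

    Out-edge probabilities are proportional to edge multiplicities; the
    mass of dangling nodes (no out-edges) is redistributed uniformly.
    Scores sum to 1 within ``tol``. Raises on non-convergence.
    """
    if not 0 < damping < 1:
        raise ValueError(f"damping must be in (0, 1), got {damping}")
    nodes = sorted(rank_graph.graph.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty graph")
    index = {v: i for i, v in enumerate(nodes)}
    out_weight = np.zeros(n)
    edges: list[tuple[int, int, float]] = []
    for u, v, d in rank_graph.graph.edges(data=True):
        w = float(d["weight"])
        edges.append((index[u], index[v], w))
        out_weight[index[u]] += w
    dangling = out_weight == 0

    p = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        new = np.full(n, (1.0 - damping) / n)
        dangling_mass = p[dangling].sum()
        new += damping * dangling_mass / n
        for ui, vi, w in edges:
            new[vi] += damping * p[ui] * w / out_weight[ui]
        residual = np.abs(new - p).sum()
        p = new
        if residual < tol:
            return {v: float(p[index[v]]) for v in nodes}
    raise PageRankConvergenceError(
        f"PageRank did not converge in {max_iter} iterations (residual {residual:.3e})"
    )


def aggregate_rankings(
    rankings: Sequence[FeatureRanking],
    damping: float = PAGERANK_DAMPING,
    tol: float = PAGERANK_TOL,
    max_iter: int = PAGERANK_MAX_ITER,
) -> tuple[list[str], dict[str, float]]:
    """Build the rank graph, score it with PageRank, and order features.

    Returns (aggregated order best-first, PageRank scores). Ties in score
    are broken lexicographically by feature name.
    """
    graph = build_rank_graph(rankings)
    scores = pagerank(graph, damping=damping, tol=tol, max_iter=max_iter)
    order = sorted(scores, key=lambda f: (-scores[f], f))
    return order, scores


# ---------------------------------------------------------------------------
# evaluation & incremental selection
# ---------------------------------------------------------------------------


def classification_metrics(
    truth: np.ndarray, predictions: np.ndarray, scores: np.ndarray
) -> Metrics:
    """Precision, recall, F1, MCC and rank-based (Mann-Whitney) ROC AUC.

    ``scores`` are continuous classifier outputs for the positive class
    (used only for AUC). Zero-denominator metrics are defined as 0 with a
    warning; single-class truth is an error because MCC and AUC are then
    undefined.
    """
    truth = np.asarray(truth)
    predictions = np.asarray(predictions)
    scores = np.asarray(scores, dtype=float)
    if not (len(truth) == len(predictions) == len(scores)):
        raise ValueError("truth, predictions and scores must have equal length")
    if len(np.unique(truth)) < 2:
        raise ValueError("MCC and AUC are undefined for single-class truth")
    tp = int(np.sum((truth == 1) & (predictions == 1)))
    fp = int(np.sum((truth == 0) & (predictions == 1)))
    fn = int(np.sum((truth == 1) & (predictions == 0)))
    tn = int(np.sum((truth == 0) & (predictions == 0)))
    if min(tp + fp, tp + fn, tn + fp, tn + fn) == 0:
        warnings.warn(
            "a confusion-matrix margin is zero; affected metric(s) defined as 0",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return Metrics(
            precision=float(precision_score(truth, predictions, zero_division=0)),
            recall=float(recall_score(truth, predictions, zero_division=0)),
            f1=float(f1_score(truth, predictions, zero_division=0)),
            mcc=float(matthews_corrcoef(truth, predictions)),
            auc=float(roc_auc_score(truth, scores)),
        )


def incremental_select(
    matrix: FeatureMatrix,
    order: Sequence[str],
    folds: int = 5,
    objective: str = "f1",
    seed: int = 0,
    n_estimators: int = RF_N_ESTIMATORS,
    stride: int = 1,
) -> SelectionResult:
    """Evaluate growing prefixes of ``order`` by cross-validated random forests.

    For each prefix length (1, 1+stride, ... and always the full length) a
    random forest is trained under stratified k-fold CV; the five metrics
    are computed from the pooled out-of-fold predictions. The chosen
    subset is the shortest prefix maximizing ``objective``.
    """
    if objective not in METRIC_NAMES:
        raise ValueError(f"objective must be one of {METRIC_NAMES}, got {objective!r}")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if sorted(order) != sorted(matrix.feature_names):
        raise FeatureTableError("order must be a permutation of the matrix's feature names")
    y = matrix.y
    class_counts = np.bincount(y)
    if class_counts.min() < folds:
        raise RankingError(
            f"stratified {folds}-fold CV needs >= {folds} samples per class "
            f"(got {class_counts.tolist()})"
        )
    X_full = matrix.data.loc[:, list(order)].to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X_full, y))

    lengths = list(range(1, len(order) + 1, stride))
    if lengths[-1] != len(order):
        lengths.append(len(order))

    prefix_metrics: dict[int, Metrics] = {}
    for k in lengths:
        X = X_full[:, :k]
        pred = np.empty_like(y)
        prob = np.empty(len(y), dtype=float)
        for train, test in splits:
            clf = RandomForestClassifier(
                n_estimators=n_estimators, random_state=seed, n_jobs=1
            )
            clf.fit(X[train], y[train])
            pred[test] = clf.predict(X[test])
            pos_col = int(np.where(clf.classes_ == 1)[0][0])
            prob[test] = clf.predict_proba(X[test])[:, pos_col]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prefix_metrics[k] = classification_metrics(y, pred, prob)

    best_k = max(
        prefix_metrics,
        key=lambda k: (getattr(prefix_metrics[k], objective), -k),
    )
    return SelectionResult(
        aggregated_order=list(order),
        prefix_metrics=prefix_metrics,
        chosen_prefix=list(order[:best_k]),
        objective_metric=objective,
    )


def ensemble_select(
    matrix: FeatureMatrix,
    methods: Sequence[str] = RANKER_METHODS,
    damping: float = PAGERANK_DAMPING,
    folds: int = 5,
    objective: str = "f1",
    seed: int = 0,
    n_estimators: int = RF_N_ESTIMATORS,
    stride: int = 1,
) -> EnsembleResult:
    """Run the full engine: rank with every method, aggregate, select a prefix."""
    rankings = [rank_features(matrix, m, seed=seed) for m in methods]
    order, scores = aggregate_rankings(rankings, damping=damping)
    selection = incremental_select(
        matrix,
        order,
        folds=folds,
        objective=objective,
        seed=seed,
        n_estimators=n_estimators,
        stride=stride,
    )
    return EnsembleResult(rankings=rankings, pagerank_scores=scores, selection=selection)
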