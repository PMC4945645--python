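"""Two-round random-forest discrimination of centrality profiles.

Round 1: leave-one-out (LOO) classification on all N per-node centrality
scores; in each fold the features (ROIs) are ranked by the forest's mean
decrease in Gini impurity and the ranks are summed over folds, giving an
overall discriminative ranking (lower summed rank = more discriminative).

Round 2: LOO classification restricted to the top-k features of that
ranking; a grid scan over the replica-coupling weight D and k selects the
most accurate configuration.

Hubs are the nodes in the top fraction (default 5%) of group-averaged
centrality; the Jaccard index measures the overlap between hub sets and
discriminative-feature sets.

Forest defaults: 700 trees, at most 5 terminal nodes per tree, 2 candidate
variables per split.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from .centrality import CentralityProfile, multiplex_pagerank
from .connectivity import LayerNetwork
from .multiplex import assemble_multiplex

__all__ = [
    "RF_DEFAULTS",
    "FeatureRanking",
    "ClassificationReport",
    "HubSet",
    "profiles_to_matrix",
    "loo_feature_ranking",
    "topk_classification",
    "scan_hyperparameters",
    "identify_hubs",
    "jaccard_index",
]

RF_DEFAULTS: dict = {
    "n_estimators": 700,
    "max_leaf_nodes": 5,
    "max_features": 2,
}


@dataclass
class FeatureRanking:
    """Summed per-fold mean-decrease-Gini ranks (rank 1 = most important)."""

    summed_ranks: np.ndarray
    n_folds: int

    def top_features(self, k: int) -> np.ndarray:
        """Indices of the k most discriminative features (stable on ties)."""
        if not 1 <= k <= self.summed_ranks.size:
            raise ValueError("k out of range")
        return np.argsort(self.summed_ranks, kind="stable")[:k]


@dataclass
class ClassificationReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    confusion: dict
    top_k: int
    D: float | None
    seed: int
    per_seed_accuracy: list[float] = field(default_factory=list)


@dataclass
class HubSet:
    nodes: list[int]
    fraction: float
    fully_tied: bool = False


def profiles_to_matrix(profiles: list[CentralityProfile]) -> np.ndarray:
    """Stack per-subject centrality profiles into a subjects x nodes matrix."""
    return np.vstack([p.profile for p in profiles])


def _check_cohort(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape[0] != y.size:
        raise ValueError("feature matrix and labels disagree on cohort size")
    if x.shape[0] < 4:
        raise ValueError("need at least 4 subjects for leave-one-out analysis")
    if np.unique(y).size != 2:
        raise ValueError("both class labels must be present")


def _forest(rf_params: dict | None, seed: int) -> RandomForestClassifier:
    params = dict(RF_DEFAULTS)
    if rf_params:
        params.update(rf_params)
    return RandomForestClassifier(random_state=seed, **params)


def loo_feature_ranking(
    features: np.ndarray | list[CentralityProfile],
    labels,
    rf_params: dict | None = None,
    seed: int = 0,
) -> FeatureRanking:
    """Leave-one-out Gini-importance ranking summed over folds.

    One forest is trained per left-out subject; within each fold features are
    ranked by mean decrease in Gini impurity (rank 1 = highest importance,
    ties get average ranks) and ranks are summed across folds.
    """
    x = features if isinstance(features, np.ndarray) else profiles_to_matrix(features)
    y = np.asarray(labels)
    _check_cohort(x, y)
    rng = np.random.default_rng(seed)
    fold_seeds = rng.integers(2**31, size=x.shape[0])
    summed = np.zeros(x.shape[1])
    for i in range(x.shape[0]):
        mask = np.ones(x.shape[0], dtype=bool)
        mask[i] = False
        clf = _forest(rf_params, int(fold_seeds[i]))
        clf.fit(x[mask], y[mask])
        summed += rankdata(-clf.feature_importances_, method="average")
    return FeatureRanking(summed_ranks=summed, n_folds=x.shape[0])


def _loo_predict(
    x: np.ndarray, y: np.ndarray, rf_params: dict | None, seed: int
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    fold_seeds = rng.integers(2**31, size=x.shape[0])
    preds = np.empty(x.shape[0], dtype=y.dtype)
    for i in range(x.shape[0]):
        mask = np.ones(x.shape[0], dtype=bool)
        mask[i] = False
        clf = _forest(rf_params, int(fold_seeds[i]))
        clf.fit(x[mask], y[mask])
        preds[i] = clf.predict(x[i : i + 1])[0]
    return preds


def _indicators(y: np.ndarray, preds: np.ndarray, positive) -> tuple[float, float, float, float, dict]:
    pos = y == positive
    tp = int(((preds == positive) & pos).sum())
    tn = int(((preds != positive) & ~pos).sum())
    fp = int(((preds == positive) & ~pos).sum())
    fn = int(((preds != positive) & pos).sum())
    acc = (tp + tn) / y.size
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    prec = tp / (tp + fp) if tp + fp else float("nan")
    return acc, sens, spec, prec, {"tp": tp, "tn": tn, "fp": fp, "fn": fn}


def topk_classification(
    features: np.ndarray | list[CentralityProfile],
    labels,
    ranking: FeatureRanking,
    top_k: int,
    rf_params: dict | None = None,
    seed: int = 0,
    n_repeats: int = 5,
    D: float | None = None,
) -> ClassificationReport:
    """Leave-one-out classification on the top-k ranked features.

    Forest stochasticity is tamed by repeating the full LOO under
    ``n_repeats`` master seeds and averaging the statistical indicators;
    confusion counts come from the first repeat.  The positive class is the
    larger of the two label values.
    """
    x = features if isinstance(features, np.ndarray) else profiles_to_matrix(features)
    y = np.asarray(labels)
    _check_cohort(x, y)
    cols = ranking.top_features(top_k)
    xk = x[:, cols]
    positive = np.max(np.unique(y))
    rng = np.random.default_rng(seed)
    repeat_seeds = rng.integers(2**31, size=n_repeats)
    accs, senss, specs, precs = [], [], [], []
    confusion = None
    for rs in repeat_seeds:
        preds = _loo_predict(xk, y, rf_params, int(rs))
        acc, sens, spec, prec, conf = _indicators(y, preds, positive)
        accs.append(acc)
        senss.append(sens)
        specs.append(spec)
        precs.append(prec)
        if confusion is None:
            confusion = conf
    def _nanmean(vals):
        vals = np.asarray(vals, dtype=float)
        ok = np.isfinite(vals)
        return float(vals[ok].mean()) if ok.any() else float("nan")

    return ClassificationReport(
        accuracy=float(np.mean(accs)),
        sensitivity=_nanmean(senss),
        specificity=_nanmean(specs),
        precision=_nanmean(precs),
        confusion=confusion,
        top_k=top_k,
        D=D,
        seed=seed,
        per_seed_accuracy=[float(a) for a in accs],
    )


def scan_hyperparameters(
    subject_layers: list[list[LayerNetwork]],
    labels,
    D_grid,
    k_grid,
    rf_params: dict | None = None,
    seed: int = 0,
    n_repeats: int = 1,
    pagerank_kwargs: dict | None = None,
) -> tuple[tuple[float, int], ClassificationReport, list[ClassificationReport]]:
    """Grid scan over replica coupling D and feature count k.

    For each D, per-subject multiplex centrality profiles are recomputed and
    both classification rounds are run for every k.  Returns the best
    (D, k), its report, and the full report grid; ties in accuracy are broken
    toward smaller k, then smaller D.
    """
    D_grid = list(D_grid)
    k_grid = list(k_grid)
    if not D_grid or not k_grid:
        raise ValueError("D and k grids must be non-empty")
    pagerank_kwargs = pagerank_kwargs or {}
    y = np.asarray(labels)
    reports: list[ClassificationReport] = []
    best = None
    for D in D_grid:
        profiles = [
            multiplex_pagerank(assemble_multiplex(layers, D), **pagerank_kwargs)
            for layers in subject_layers
        ]
        x = profiles_to_matrix(profiles)
        ranking = loo_feature_ranking(x, y, rf_params=rf_params, seed=seed)
        for k in k_grid:
            rep = topk_classification(
                x, y, ranking, top_k=k, rf_params=rf_params, seed=seed,
                n_repeats=n_repeats, D=D,
            )
            reports.append(rep)
            key = (-rep.accuracy, k, D)
            if best is None or key < best[0]:
                best = (key, (float(D), int(k)), rep)
    return best[1], best[2], reports


def identify_hubs(
    group_profiles: list[CentralityProfile], fraction: float = 0.05
) -> HubSet:
    """Nodes in the top ``fraction`` of group-averaged centrality.

    The hub count is round-half-up of fraction * N.  Ties at the cutoff are
    resolved toward the lowest node id; a fully tied (constant) mean profile
    is flagged.
    """
    if not group_profiles:
        raise ValueError("need at least one profile")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    mean_profile = np.mean([p.profile for p in group_profiles], axis=0)
    n = mean_profile.size
    n_hubs = math.floor(fraction * n + 0.5)
    if n_hubs < 1:
        raise ValueError(f"fraction {fraction} selects no nodes out of {n}")
    order = np.lexsort((np.arange(n), -mean_profile))
    fully_tied = bool(np.ptp(mean_profile) == 0)
    if fully_tied:
        warnings.warn("all centralities equal: hub set is the first node ids")
    return HubSet(nodes=sorted(int(i) for i in order[:n_hubs]),
                  fraction=fraction, fully_tied=fully_tied)


def jaccard_index(a, b) -> float:
    """|a ∩ b| / |a ∪ b|; two empty sets give 0 by convention (with warning)."""
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        warnings.warn("Jaccard index of two empty sets: 0 by convention")
        return 0.0
    return len(sa & sb) / len(union)
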