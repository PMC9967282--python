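"""Conventional feature-selection baselines.

All baselines fit on the training split only and return exactly ``k``
feature names with their scores, so that downstream evaluation is uniform
across methods:

- ``random``: seeded uniform subset;
- ``pca_pc1``: rank features by |loading| on the first principal component
  of the z-scored features (no projection is performed — the original
  columns are kept);
- ``chi2``: chi-squared statistic on features min-max scaled to [0, 1];
- ``mutual_info``: mutual information with the label (k-NN estimator);
- ``rfe_tree``: recursive feature elimination with a decision tree,
  eliminating one feature per round.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.feature_selection import RFE, chi2, mutual_info_classif
from sklearn.preprocessing import MinMaxScaler, StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix

__all__ = ["BaselineSpec", "BASELINE_METHODS", "select_baseline"]

BASELINE_METHODS = ("random", "pca_pc1", "chi2", "mutual_info", "rfe_tree")


@dataclass
class BaselineSpec:
    method: str
    k: int
    seed: int = 0
    mi_n_neighbors: int = 3  # neighbour count of the MI estimator

    def __post_init__(self) -> None:
        if self.method not in BASELINE_METHODS:
            raise ValueError(f"unknown baseline method {self.method!r}; "
                             f"choose from {BASELINE_METHODS}")
        if self.k < 1:
            raise ValueError("k must be >= 1")


def select_baseline(train_features: FeatureMatrix,
                    spec: BaselineSpec) -> tuple[list[str], dict[str, float]]:
    """Select ``k`` features on the training split with a baseline method.

    Returns the selected names (ranked by decreasing score) and a
    name -> score mapping.  Deterministic given ``spec.seed``.
    """
    d0 = train_features.n_features
    if spec.k > d0:
        raise ValueError(f"k={spec.k} exceeds feature count {d0}")
    X = train_features.values
    y = train_features.labels
    names = train_features.feature_names
    rng = np.random.default_rng(spec.seed)

    if spec.method == "random":
        idx = np.sort(rng.choice(d0, size=spec.k, replace=False))
        scores = np.zeros(d0)
        scores[idx] = 1.0
    elif spec.method == "pca_pc1":
        Xz = StandardScaler().fit_transform(X)
        pca = PCA(n_components=1, random_state=spec.seed)
        pca.fit(Xz)
        scores = np.abs(pca.components_[0])
        idx = np.argsort(-scores, kind="stable")[:spec.k]
    elif spec.method == "chi2":
        Xs = MinMaxScaler().fit_transform(X)
        stat, _ = chi2(Xs, y)
        scores = np.nan_to_num(stat, nan=0.0)
        idx = np.argsort(-scores, kind="stable")[:spec.k]
    elif spec.method == "mutual_info":
        scores = mutual_info_classif(X, y, n_neighbors=spec.mi_n_neighbors,
                                     random_state=spec.seed)
        idx = np.argsort(-scores, kind="stable")[:spec.k]
    else:  # rfe_tree
        tree = DecisionTreeClassifier(random_state=spec.seed)
        rfe = RFE(tree, n_features_to_select=spec.k, step=1)
        rfe.fit(X, y)
        # ranking_: 1 for selected, larger = eliminated earlier
        scores = 1.0 / rfe.ranking_
        idx = np.flatnonzero(rfe.support_)

    ranked = sorted(map(int, idx), key=lambda i: (-scores[i], i))
    selected = [names[i] for i in ranked]
    return selected, {names[i]: float(scores[i]) for i in ranked}
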