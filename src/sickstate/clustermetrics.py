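"""Internal clustering validity: does feature selection sharpen the
separation of sickness states?

Two indices are reported for the condition-labeled intensity matrix before
and after feature selection: the mean silhouette (cohesion vs separation,
in [-1, 1]) and the Calinski-Harabasz variance-ratio criterion
(between-cluster over within-cluster dispersion). A stochastic 2-D
embedding is provided for display only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics
from sklearn.manifold import TSNE


def _check_labels(X, labels):
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if len(labels) != X.shape[0]:
        raise ValueError("labels length does not match number of rows")
    k = np.unique(labels).size
    return X, labels, k


def silhouette(X, labels) -> float:
    """Mean silhouette coefficient under Euclidean distance.

    Singleton clusters contribute s = 0.
    """
    X, labels, k = _check_labels(X, labels)
    if k < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    if X.shape[0] < 3:
        raise ValueError("silhouette requires at least 3 points")
    return float(skmetrics.silhouette_score(X, labels, metric="euclidean"))


def calinski_harabasz(X, labels) -> float:
    """Variance-ratio criterion [between-SS/(k-1)] / [within-SS/(n-k)].

    Zero within-cluster dispersion (all clusters internally coincident) is
    degenerate — returns +inf to signal infinite separation.
    """
    X, labels, k = _check_labels(X, labels)
    n = X.shape[0]
    if k < 2 or k >= n:
        raise ValueError("calinski_harabasz requires 2 <= k < n")
    within = 0.0
    for c in np.unique(labels):
        Xi = X[labels == c]
        within += float(np.sum((Xi - Xi.mean(axis=0)) ** 2))
    if within <= 0:
        return math.inf
    return float(skmetrics.calinski_harabasz_score(X, labels))


@dataclass
class ClusterMetricReport:
    silhouette: float
    calinski_harabasz: float
    tag: str  # "full" | "selected"

    def to_dict(self) -> dict:
        return {
            "tag": self.tag,
            "silhouette": self.silhouette,
            "calinski_harabasz": self.calinski_harabasz,
        }


def compare_feature_sets(X_full, X_selected, labels) -> pd.DataFrame:
    """Both indices on the full and selected feature sets, plus deltas.

    Rows: full, selected, delta (selected - full).
    """
    X_full = np.asarray(X_full, float)
    X_selected = np.asarray(X_selected, float)
    if X_full.shape[0] != X_selected.shape[0]:
        raise ValueError("full and selected matrices must share their rows")
    full = ClusterMetricReport(silhouette(X_full, labels), calinski_harabasz(X_full, labels), "full")
    sel = ClusterMetricReport(
        silhouette(X_selected, labels), calinski_harabasz(X_selected, labels), "selected"
    )
    out = pd.DataFrame([full.to_dict(), sel.to_dict()]).set_index("tag")
    out.loc["delta"] = out.loc["selected"] - out.loc["full"]
    return out


def embed_2d(X, seed: int = 0, perplexity: float | None = None) -> np.ndarray:
    """Neighbor-preserving stochastic 2-D embedding (t-SNE), display only.

    Deterministic under a fixed seed. Requires n >= 5.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("embedding input must be finite")
    n = X.shape[0]
    if n < 5:
        raise ValueError("embed_2d requires at least 5 points")
    if perplexity is None:
        perplexity = min(30.0, max(2.0, (n - 1) / 3.0 - 1e-9))
    ts = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=int(seed) % (2**31 - 1),
    )
    return ts.fit_transform(X)
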