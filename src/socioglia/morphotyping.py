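"""Morphotype grouping of neurons from 13-feature vectors.

Neurons are grouped two ways, both on z-scored features:

* agglomerative hierarchical clustering with average ("between-groups")
  linkage on squared Euclidean distances, cut to a user-chosen number of
  flat clusters;
* principal-axis factor analysis of the feature correlation matrix —
  iterated-communality principal axis extraction, factors retained while
  their eigenvalue exceeds 1, varimax rotation, regression-method factor
  scores — followed by a complex/simple split of each neuron on the
  factor most aligned with total arbor length.

Both are exposed as scikit-learn style estimators so they compose with
pipelines and model selection; the module-level functions are thin
wrappers for one-shot use.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "standardize",
    "MorphotypeClustering",
    "PrincipalAxisFactorAnalysis",
    "ComplexSimpleClassifier",
    "hierarchical_clusters",
    "factor_analysis",
    "classify_complex",
    "varimax",
]


def standardize(X, ddof: int = 1) -> np.ndarray:
    """Column z-scores with sample SD; constant columns map to zeros."""
    X = np.asarray(X, float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("need a 2D matrix with at least two rows")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    const = sd == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant column(s) z-scored to zeros")
        sd = np.where(const, 1.0, sd)
    return (X - mu) / sd


class MorphotypeClustering(ClusterMixin, BaseEstimator):
    """Average-linkage hierarchical clustering on squared Euclidean distances.

    Features are z-scored internally (so clustering is invariant to affine
    rescaling of any column). Fitted attributes: ``linkage_`` (the scipy
    merge tree, heights on the squared-distance scale) and ``labels_``
    (flat clusters, 0-based, obtained by cutting to ``n_clusters``).
    """

    def __init__(self, n_clusters: int = 2, scale: bool = True):
        self.n_clusters = n_clusters
        self.scale = scale

    def fit(self, X, y=None) -> "MorphotypeClustering":
        X = np.asarray(X, float)
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_clusters > len(X):
            raise ValueError("n_clusters exceeds the number of rows")
        Z = standardize(X) if self.scale else X
        d2 = pdist(Z, metric="sqeuclidean")
        self.linkage_ = linkage(d2, method="average")
        self.labels_ = fcluster(self.linkage_, t=self.n_clusters,
                                criterion="maxclust") - 1
        return self


def hierarchical_clusters(z: np.ndarray, k: int,
                          scale: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Merge tree and flat labels for an (already z-scored) matrix."""
    est = MorphotypeClustering(n_clusters=k, scale=scale).fit(z)
    return est.linkage_, est.labels_


# ---------------------------------------------------------------------------
# Principal-axis factor analysis
# ---------------------------------------------------------------------------

def varimax(loadings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation; returns (rotated loadings, rotation matrix)."""
    from statsmodels.multivariate.factor_rotation import rotate_factors

    L = np.asarray(loadings, float)
    if L.shape[1] < 2:
        return L.copy(), np.eye(L.shape[1])
    L_rot, R = rotate_factors(L, "varimax")
    return L_rot, R


class PrincipalAxisFactorAnalysis(TransformerMixin, BaseEstimator):
    """Principal-axis factoring with varimax rotation and regression scores.

    The number of factors defaults to the number of eigenvalues of the
    sample correlation matrix above 1 (the Kaiser rule). Communalities
    are initialized from squared multiple correlations and iterated to
    convergence. ``transform`` returns regression-method factor scores of
    (internally standardized) observations.

    Fitted attributes
    -----------------
    n_factors_ : retained factor count.
    loadings_ : (p, k) varimax-rotated loading matrix.
    eigenvalues_ : eigenvalues of the sample correlation matrix.
    variance_explained_ : percent of total variance per rotated factor.
    cumulative_variance_ : running sum of ``variance_explained_``.
    communalities_ : final per-feature communalities.
    """

    def __init__(self, n_factors: int | None = None, rotate: bool = True,
                 max_iter: int = 200, tol: float = 1e-6):
        self.n_factors = n_factors
        self.rotate = rotate
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None) -> "PrincipalAxisFactorAnalysis":
        X = np.asarray(X, float)
        n, p = X.shape
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        if np.any(self.scale_ == 0):
            bad = list(np.flatnonzero(self.scale_ == 0))
            raise ValueError(f"constant column(s) {bad}: correlation undefined")
        Z = (X - self.mean_) / self.scale_
        R = np.corrcoef(Z, rowvar=False)
        # exactly duplicated features make the model ill-posed
        off = R - np.eye(p)
        dup = np.argwhere(np.abs(off) >= 1.0 - 1e-10)
        if len(dup):
            i, j = sorted(dup[0].tolist())
            raise ValueError(
                f"singular correlation matrix: columns {i} and {j} are "
                "duplicated (|r| = 1)")
        cond = np.linalg.cond(R)
        if cond > 1e10:
            # linear dependencies among 3+ features (for these skeleton
            # features n_branches = n_branch_points + n_tips holds exactly);
            # communalities and scores then use the pseudoinverse
            _, _, vt = np.linalg.svd(R)
            worst = sorted(np.argsort(np.abs(vt[-1]))[-3:].tolist())
            warnings.warn(
                f"rank-deficient correlation matrix (columns {worst} "
                "linearly dependent); using pseudoinverse")
        eig = np.sort(np.linalg.eigvalsh(R))[::-1]
        self.eigenvalues_ = eig
        k = int(np.sum(eig > 1.0)) if self.n_factors is None else self.n_factors
        k = max(k, 1)
        self.n_factors_ = k

        # iterated principal axis extraction
        Rinv = np.linalg.pinv(R, hermitian=True)
        diag = np.clip(np.diag(Rinv), 1e-12, None)
        h2 = np.clip(1.0 - 1.0 / diag, 0.0, 1.0)  # squared multiple correlations
        L = None
        for _ in range(self.max_iter):
            Rr = R.copy()
            np.fill_diagonal(Rr, h2)
            vals, vecs = np.linalg.eigh(Rr)
            idx = np.argsort(vals)[::-1][:k]
            lam = np.clip(vals[idx], 0.0, None)
            L = vecs[:, idx] * np.sqrt(lam)
            h2_new = np.sum(L**2, axis=1)
            if np.max(np.abs(h2_new - h2)) < self.tol:
                h2 = h2_new
                break
            h2 = h2_new
        # deterministic sign: largest-magnitude loading positive per factor
        for j in range(k):
            m = np.argmax(np.abs(L[:, j]))
            if L[m, j] < 0:
                L[:, j] = -L[:, j]
        if self.rotate and k > 1:
            L, self.rotation_ = varimax(L)
            for j in range(k):
                m = np.argmax(np.abs(L[:, j]))
                if L[m, j] < 0:
                    L[:, j] = -L[:, j]
        else:
            self.rotation_ = np.eye(k)
        # order factors by explained variance, descending
        ssq = np.sum(L**2, axis=0)
        order = np.argsort(ssq)[::-1]
        L = L[:, order]
        ssq = ssq[order]
        self.loadings_ = L
        self.communalities_ = h2
        self.variance_explained_ = 100.0 * ssq / p
        self.cumulative_variance_ = np.cumsum(self.variance_explained_)
        self.correlation_ = R
        # regression (Thurstone) score weights: R^-1 L
        self.score_weights_ = Rinv @ L
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "loadings_")
        Z = (np.asarray(X, float) - self.mean_) / self.scale_
        return Z @ self.score_weights_


def factor_analysis(z: np.ndarray, n_factors: int | None = None
                    ) -> PrincipalAxisFactorAnalysis:
    """Fit the factor model; factor count by the eigenvalue-above-1 rule."""
    return PrincipalAxisFactorAnalysis(n_factors=n_factors).fit(z)


# ---------------------------------------------------------------------------
# Complex / simple classification
# ---------------------------------------------------------------------------

def _gmm_split(x: np.ndarray) -> float:
    """Decision boundary of a 1D two-component Gaussian mixture.

    Components are initialized at the score quartiles (deterministic);
    the threshold is the lowest score whose posterior favors the upper
    component. Unlike an equal-variance split this places the boundary
    at the density crossing, which matters when the simple class is much
    more dispersed than the complex one.
    """
    from sklearn.mixture import GaussianMixture

    xs = np.sort(np.asarray(x, float))
    if xs[0] == xs[-1]:
        return float(xs[-1])
    gm = GaussianMixture(
        n_components=2, covariance_type="full", random_state=0,
        means_init=[[np.percentile(xs, 25)], [np.percentile(xs, 75)]],
    ).fit(xs[:, None])
    upper = int(np.argmax(gm.means_.ravel()))
    grid = np.linspace(xs[0], xs[-1], 2001)
    post = gm.predict_proba(grid[:, None])
    above = grid[post[:, upper] > 0.5]
    return float(above[0]) if len(above) else float(xs[-1])


def _variance_minimizing_split(x: np.ndarray) -> float:
    """Threshold of the 2-class 1D split minimizing within-class variance."""
    xs = np.sort(np.asarray(x, float))
    n = len(xs)
    if n < 2 or xs[0] == xs[-1]:
        return float(xs[-1])  # degenerate: everything below/equal -> one class
    best_cost, best_thr = np.inf, xs[0]
    csum = np.cumsum(xs)
    csq = np.cumsum(xs**2)
    for i in range(1, n):  # split between i-1 and i
        n1, n2 = i, n - i
        s1, s2 = csum[i - 1], csum[-1] - csum[i - 1]
        q1, q2 = csq[i - 1], csq[-1] - csq[i - 1]
        cost = (q1 - s1**2 / n1) + (q2 - s2**2 / n2)
        if cost < best_cost - 1e-15:
            best_cost = cost
            best_thr = 0.5 * (xs[i - 1] + xs[i])
    return float(best_thr)


class ComplexSimpleClassifier(BaseEstimator):
    """Label neurons complex vs simple from their factor scores.

    The "complexity" factor is the one whose loading on a designated
    feature (total arbor length by default) is largest in magnitude;
    neurons whose score on it exceeds the threshold are *complex*. The
    default threshold is data-driven: a two-class 1D clustering of the
    score. ``method='gmm'`` (default) uses a two-component Gaussian
    mixture and thresholds at the posterior crossing, which stays in the
    between-class gap even when the simple class is far more dispersed
    than the complex one; ``method='otsu'`` minimizes within-class
    variance. An explicit ``threshold`` overrides both.
    """

    def __init__(self, length_feature_index: int = 0,
                 threshold: float | None = None, method: str = "gmm"):
        self.length_feature_index = length_feature_index
        self.threshold = threshold
        self.method = method

    def fit(self, scores: np.ndarray, model: PrincipalAxisFactorAnalysis
            ) -> "ComplexSimpleClassifier":
        scores = np.asarray(scores, float)
        load = model.loadings_[self.length_feature_index]
        self.complexity_factor_ = int(np.argmax(np.abs(load)))
        s = scores[:, self.complexity_factor_]
        # orient so that larger score = longer arbor
        self.sign_ = 1.0 if load[self.complexity_factor_] >= 0 else -1.0
        s = self.sign_ * s
        if self.threshold is not None:
            self.threshold_ = self.threshold
        elif self.method == "gmm":
            self.threshold_ = _gmm_split(s)
        elif self.method == "otsu":
            self.threshold_ = _variance_minimizing_split(s)
        else:
            raise ValueError("method must be 'gmm' or 'otsu'")
        return self

    def predict(self, scores: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "threshold_")
        s = self.sign_ * np.asarray(scores, float)[:, self.complexity_factor_]
        return np.where(s > self.threshold_, "complex", "simple")


def classify_complex(model: PrincipalAxisFactorAnalysis, scores: np.ndarray,
                     threshold: float | None = None,
                     length_feature_index: int = 0) -> np.ndarray:
    clf = ComplexSimpleClassifier(length_feature_index=length_feature_index,
                                  threshold=threshold).fit(scores, model)
    return clf.predict(scores)
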