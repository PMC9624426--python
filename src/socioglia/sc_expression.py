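"""Subclustering and differential expression of immune-cell count matrices.

Mirrors the standard single-cell workflow applied to the mpeg1+ immune
compartment: library-size normalization to 10,000 counts per cell with
log1p, per-gene z-scaling, truncated SVD to a small number of principal
components (4 by default), a k-nearest-neighbor graph in PC space with
shared-nearest-neighbor (Jaccard) edge weights, and modularity-based
community detection at resolution 1.25 with a fixed seed. Downstream:

* dot-plot statistics (percent of cluster cells expressing, mean scaled
  expression) for the 75-gene microglial fingerprint;
* a fingerprint score per cluster (mean expressing fraction over the
  fingerprint genes) that flags microglial clusters, formalizing the
  observation that microglial clusters express most of the fingerprint
  in most cells while macrophage clusters do not;
* within-cluster condition markers: two-sided Wilcoxon rank-sum on the
  log-normalized layer with Bonferroni adjustment, for genes expressed
  in at least 10% of cells in either condition;
* per-cluster condition composition with a chi-square homogeneity test.
"""

from __future__ import annotations

import warnings

import anndata as ad
import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import TruncatedSVD
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "normalize_and_scale",
    "GraphCommunityClustering",
    "subcluster",
    "fingerprint_dotstats",
    "identify_microglia",
    "condition_markers",
    "condition_composition",
]

TARGET_SUM = 10_000.0


def _counts(adata: ad.AnnData) -> np.ndarray:
    X = adata.layers.get("counts", adata.X)
    return X.toarray() if sp.issparse(X) else np.asarray(X, float)


def normalize_and_scale(adata: ad.AnnData, target_sum: float = TARGET_SUM,
                        max_value: float | None = None) -> ad.AnnData:
    """Add 'lognorm' (library-size 10k + log1p) and 'scaled' (per-gene z) layers.

    Cells with zero total counts are dropped with a warning. Returns the
    (possibly subset) AnnData with both layers attached.
    """
    counts = _counts(adata)
    totals = counts.sum(axis=1)
    keep = totals > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} cell(s) with zero counts")
        adata = adata[keep].copy()
        counts = counts[keep]
        totals = totals[keep]
    norm = counts / totals[:, None] * target_sum
    lognorm = np.log1p(norm)
    mu = lognorm.mean(axis=0)
    sd = lognorm.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    scaled = (lognorm - mu) / sd
    if max_value is not None:
        scaled = np.clip(scaled, -max_value, max_value)
    adata.layers["lognorm"] = lognorm
    adata.layers["scaled"] = scaled
    return adata


class GraphCommunityClustering(ClusterMixin, BaseEstimator):
    """PCA -> SNN graph -> modularity communities, scikit-learn style.

    ``fit(X)`` expects the scaled expression matrix (cells x genes);
    ``labels_`` holds the community of each cell. The kNN graph is
    weighted by the Jaccard overlap of neighborhoods (shared nearest
    neighbors) and partitioned with the RB-configuration modularity
    quality at the given ``resolution`` and fixed ``seed``, so identical
    inputs give identical labels.
    """

    def __init__(self, n_pcs: int = 4, resolution: float = 1.25,
                 k_neighbors: int = 20, seed: int = 0, prune: float = 1 / 15):
        self.n_pcs = n_pcs
        self.resolution = resolution
        self.k_neighbors = k_neighbors
        self.seed = seed
        self.prune = prune

    def fit(self, X, y=None) -> "GraphCommunityClustering":
        X = np.asarray(X, float)
        n = len(X)
        if n <= self.k_neighbors:
            raise ValueError("fewer cells than k_neighbors")
        if self.n_pcs > min(X.shape):
            raise ValueError("n_pcs exceeds matrix rank bound")
        svd = TruncatedSVD(n_components=self.n_pcs, random_state=0)
        pcs = svd.fit_transform(X)
        self.pcs_ = pcs
        self.explained_variance_ratio_ = svd.explained_variance_ratio_

        nn = NearestNeighbors(n_neighbors=self.k_neighbors).fit(pcs)
        knn = nn.kneighbors_graph(pcs, mode="connectivity")  # includes self? no
        # neighborhood sets include the cell itself, as in SNN practice
        knn = knn.tolil()
        knn.setdiag(1)
        knn = knn.tocsr()
        # Jaccard SNN weights: |Ni & Nj| / |Ni | Nj|
        inter = (knn @ knn.T).toarray()
        size = np.asarray(knn.sum(axis=1)).ravel()
        union = size[:, None] + size[None, :] - inter
        with np.errstate(divide="ignore", invalid="ignore"):
            jac = np.where(union > 0, inter / union, 0.0)
        np.fill_diagonal(jac, 0.0)
        jac[jac < self.prune] = 0.0
        sources, targets = np.nonzero(np.triu(jac))
        weights = jac[sources, targets]
        g = igraph.Graph(n=n, edges=list(zip(sources.tolist(), targets.tolist())),
                         edge_attrs={"weight": weights.tolist()})
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition,
            weights="weight", resolution_parameter=self.resolution,
            seed=self.seed, n_iterations=-1)
        self.labels_ = np.asarray(part.membership, dtype=np.int64)
        return self


def subcluster(adata: ad.AnnData, n_pcs: int = 4, resolution: float = 1.25,
               k_neighbors: int = 20, seed: int = 0) -> np.ndarray:
    """Cluster cells on the scaled layer; labels stored in obs['cluster']."""
    if "scaled" not in adata.layers:
        adata = normalize_and_scale(adata)
    est = GraphCommunityClustering(n_pcs=n_pcs, resolution=resolution,
                                   k_neighbors=k_neighbors, seed=seed)
    est.fit(adata.layers["scaled"])
    adata.obs["cluster"] = pd.Categorical(est.labels_.astype(str))
    return est.labels_


def fingerprint_dotstats(adata: ad.AnnData, labels: np.ndarray,
                         genes: list[str]) -> pd.DataFrame:
    """Per (cluster, gene): % of cells expressing and mean scaled expression."""
    if "scaled" not in adata.layers:
        raise ValueError("run normalize_and_scale first")
    labels = np.asarray(labels)
    present = [g for g in genes if g in adata.var_names]
    missing = sorted(set(genes) - set(present))
    if missing:
        warnings.warn(f"{len(missing)} fingerprint gene(s) absent, skipped: "
                      f"{missing[:5]}...")
    counts = _counts(adata)
    scaled = adata.layers["scaled"]
    gidx = [adata.var_names.get_loc(g) for g in present]
    rows = []
    for cl in np.unique(labels):
        in_cl = labels == cl
        if not in_cl.any():
            raise ValueError(f"empty cluster {cl}")
        pct = 100.0 * (counts[np.ix_(in_cl, gidx)] > 0).mean(axis=0)
        mean_scaled = scaled[np.ix_(in_cl, gidx)].mean(axis=0)
        for g, p, m in zip(present, pct, mean_scaled):
            rows.append({"cluster": cl, "gene": g, "pct_expressing": float(p),
                         "mean_scaled": float(m)})
    return pd.DataFrame(rows)


def identify_microglia(dotstats: pd.DataFrame, min_score: float = 0.5
                       ) -> tuple[set, pd.Series]:
    """Fingerprint score per cluster and the set of clusters at/above cutoff.

    The score is the mean expressing *fraction* over the fingerprint genes,
    so a cluster in which every cell expresses every fingerprint gene
    scores 1. Raising ``min_score`` can only shrink the flagged set.
    """
    scores = (dotstats.groupby("cluster")["pct_expressing"].mean() / 100.0)
    flagged = set(scores.index[scores >= min_score])
    return flagged, scores


def condition_markers(adata: ad.AnnData, labels: np.ndarray, cluster,
                      group_a: str = "GF", group_b: str = "CVZ",
                      groupby: str = "condition", min_pct: float = 0.1
                      ) -> pd.DataFrame:
    """Within-cluster condition markers by two-sided Wilcoxon rank-sum.

    Genes expressed in at least ``min_pct`` of cells in either condition
    are tested on the log-normalized layer; p-values are Bonferroni
    adjusted over the tested genes; the log2 fold change compares mean
    normalized expression (pseudocount 1), positive = higher in
    ``group_a``.
    """
    if "lognorm" not in adata.layers:
        raise ValueError("run normalize_and_scale first")
    labels = np.asarray(labels)
    in_cl = labels == cluster
    cond = adata.obs[groupby].to_numpy()
    a_mask = in_cl & (cond == group_a)
    b_mask = in_cl & (cond == group_b)
    if a_mask.sum() < 3 or b_mask.sum() < 3:
        raise ValueError(
            f"cluster {cluster} needs >=3 cells in each of {group_a}/{group_b}")
    counts = _counts(adata)
    lognorm = adata.layers["lognorm"]
    norm = np.expm1(lognorm)

    pct_a = (counts[a_mask] > 0).mean(axis=0)
    pct_b = (counts[b_mask] > 0).mean(axis=0)
    tested = np.flatnonzero((pct_a >= min_pct) | (pct_b >= min_pct))
    if tested.size == 0:
        return pd.DataFrame(columns=["gene", "p", "p_adj", "log2fc",
                                     f"pct_{group_a}", f"pct_{group_b}"])
    la = lognorm[np.ix_(a_mask, tested)]
    lb = lognorm[np.ix_(b_mask, tested)]
    stat, p = scipy.stats.mannwhitneyu(la, lb, alternative="two-sided",
                                       axis=0, method="asymptotic")
    p_adj = np.minimum(p * tested.size, 1.0)
    mean_a = norm[np.ix_(a_mask, tested)].mean(axis=0)
    mean_b = norm[np.ix_(b_mask, tested)].mean(axis=0)
    lfc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    out = pd.DataFrame({
        "gene": adata.var_names[tested],
        "p": p,
        "p_adj": p_adj,
        "log2fc": lfc,
        f"pct_{group_a}": 100.0 * pct_a[tested],
        f"pct_{group_b}": 100.0 * pct_b[tested],
    })
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def condition_composition(labels: np.ndarray, condition: np.ndarray
                          ) -> tuple[pd.DataFrame, dict]:
    """Per-cluster condition fractions plus a chi-square homogeneity test."""
    labels = np.asarray(labels)
    condition = np.asarray(condition)
    if labels.shape != condition.shape:
        raise ValueError("labels and condition must align")
    tab = pd.crosstab(labels, condition)
    frac = tab.div(tab.sum(axis=1), axis=0)
    chi2, p, dof, _ = scipy.stats.chi2_contingency(tab.to_numpy())
    return frac, {"chi2": float(chi2), "p": float(p), "dof": int(dof)}
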