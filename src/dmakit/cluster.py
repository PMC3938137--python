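"""Hierarchical clustering, k-means, and probabilistic PCA.

The heat-map display pipeline follows common microarray practice: gene
rows are log2-transformed and mean-centered before distances are computed,
so the dendrogram and heat map show relative expression patterns rather
than absolute intensity.  PPCA is the one stage that tolerates missing
values: it fits the isotropic-noise Gaussian factor model

    x = W z + mu + eps,   z ~ N(0, I_q),   eps ~ N(0, sigma^2 I_d)

by EM, integrating both the latent scores and any missing coordinates in
the E-step, which keeps the observed-data log-likelihood non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .io import ExpressionDataset

__all__ = [
    "LinkageTree",
    "PpcaModel",
    "hierarchical_cluster",
    "kmeans_cluster",
    "fit_ppca",
    "project_scores",
]


@dataclass
class LinkageTree:
    """Merge history of an agglomerative clustering.

    ``merges`` is the scipy linkage matrix (left, right, height, size) with
    leaves 0..n-1 and internal nodes n..2n-2.  ``leaf_order`` is the
    deterministic display order: at every merge the subtree containing the
    smaller minimum leaf index goes left.
    """

    merges: np.ndarray
    labels: list[str]
    leaf_order: list[int]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]


def _deterministic_leaf_order(merges: np.ndarray, n: int) -> list[int]:
    leaves: dict[int, list[int]] = {i: [i] for i in range(n)}
    for k, (left, right, _h, _size) in enumerate(merges):
        a, b = leaves.pop(int(left)), leaves.pop(int(right))
        if min(b) < min(a):
            a, b = b, a
        leaves[n + k] = a + b
    (order,) = leaves.values()
    return order


def hierarchical_cluster(data: ExpressionDataset, axis: str = "genes",
                         metric: str = "euclidean", linkage: str = "average",
                         center_genes: bool = True) -> LinkageTree:
    """Agglomerative clustering of genes or samples.

    With ``center_genes`` each gene row is log2-transformed then
    mean-centered before distances (the heat-map display convention); the
    same transformed matrix is used whether genes or samples are clustered.
    ``metric`` is euclidean or correlation (1 - Pearson r); ``linkage`` is
    single, complete or average.  A constant row under the correlation
    metric has no defined correlation and raises an error naming the row.
    """
    if axis not in ("genes", "samples"):
        raise ValueError("axis must be 'genes' or 'samples'")
    if metric not in ("euclidean", "correlation"):
        raise ValueError("metric must be 'euclidean' or 'correlation'")
    if linkage not in ("single", "complete", "average"):
        raise ValueError("linkage must be single, complete or average")
    if data.has_missing():
        raise ValueError("clustering does not accept missing values; "
                         "impute (e.g. via PPCA) first")
    x = data.intensities.to_numpy(dtype=float)
    if center_genes:
        if (x <= 0).any():
            raise ValueError("log2 centering requires strictly positive intensities")
        x = np.log2(x)
        x = x - x.mean(axis=1, keepdims=True)
    if axis == "genes":
        items, labels = x, data.probe_ids
    else:
        items, labels = x.T, data.sample_ids
    if len(labels) < 2:
        raise ValueError(f"need >=2 {axis} to cluster")
    if metric == "correlation":
        flat = items.std(axis=1) == 0
        if flat.any():
            bad = labels[int(np.where(flat)[0][0])]
            raise ValueError(
                f"constant row {bad!r} has no defined correlation distance"
            )
    dists = pdist(items, metric=metric)
    merges = hierarchy.linkage(dists, method=linkage)
    order = _deterministic_leaf_order(merges, len(labels))
    return LinkageTree(merges, list(labels), order)


def heatmap_matrix(data: ExpressionDataset, tree: LinkageTree,
                   center_genes: bool = True) -> pd.DataFrame:
    """Gene x sample matrix in dendrogram leaf order, transformed the same
    way as the clustering input (log2, mean-centered rows by default)."""
    x = data.intensities.to_numpy(dtype=float)
    if center_genes:
        x = np.log2(x)
        x = x - x.mean(axis=1, keepdims=True)
    frame = pd.DataFrame(x, index=data.probe_ids, columns=data.sample_ids)
    if tree.labels == data.probe_ids:
        frame = frame.iloc[tree.leaf_order]
    elif tree.labels == data.sample_ids:
        frame = frame.iloc[:, tree.leaf_order]
    else:
        raise ValueError("tree labels do not match the dataset")
    return frame


def kmeans_cluster(data: ExpressionDataset, k: int, seed: int = 0,
                   n_restarts: int = 10, axis: str = "genes",
                   center_rows: bool = False,
                   log2_transform: bool = False) -> pd.Series:
    """Lloyd k-means on expression rows (or columns), best of ``n_restarts``
    by within-cluster sum of squares, deterministic given ``seed``.

    With ``log2_transform`` and ``center_rows`` items are clustered by
    expression *profile shape* (log2, mean-centered rows) rather than
    absolute intensity — the usual choice when splitting rising from
    falling expression waves.  Returns a Series mapping item label ->
    cluster id in 1..k.  Empty clusters are re-seeded internally
    (scikit-learn relocates the centroid to the point farthest from its
    center) rather than crashing.
    """
    if data.has_missing():
        raise ValueError("k-means does not accept missing values")
    x = data.intensities.to_numpy(dtype=float)
    if log2_transform:
        if (x <= 0).any():
            raise ValueError("log2 transform requires positive intensities")
        x = np.log2(x)
    labels = data.probe_ids if axis == "genes" else data.sample_ids
    if axis == "samples":
        x = x.T
    if center_rows:
        x = x - x.mean(axis=1, keepdims=True)
    if k > len(labels):
        raise ValueError(f"k={k} exceeds the number of items ({len(labels)})")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed,
                algorithm="lloyd")
    assignment = km.fit_predict(x) + 1
    return pd.Series(assignment, index=labels, name="cluster")


@dataclass
class PpcaModel:
    """Fitted probabilistic PCA: loadings W (feature x component), mean
    vector, isotropic noise variance sigma^2, posterior-mean scores
    (sample x component) and the per-iteration log-likelihood trace."""

    loadings: np.ndarray
    mean: np.ndarray
    sigma2: float
    scores: np.ndarray
    loglik_trace: list[float]
    sample_ids: list[str]
    feature_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def _ppca_loglik(x: np.ndarray, obs: np.ndarray, w: np.ndarray,
                 mu: np.ndarray, sigma2: float) -> float:
    """Observed-data log-likelihood, per-sample over observed coordinates.

    Uses the q x q identity log|C_O| = (d_O - q) log s2 + log|M_O| with
    M_O = W_O'W_O + s2 I and the matching Woodbury quadratic form.
    """
    n, d = x.shape
    q = w.shape[1]
    if obs.all():
        y = x - mu
        s = (y.T @ y) / n
        m = w.T @ w + sigma2 * np.eye(q)
        _sign, logdet_m = np.linalg.slogdet(m)
        logdet_c = (d - q) * np.log(sigma2) + logdet_m
        # tr(C^-1 S) via Woodbury: C^-1 = (I - W M^-1 W') / s2
        tr_cinv_s = (np.trace(s) - np.trace(np.linalg.solve(m, w.T @ s @ w))
                     ) / sigma2
        return float(-0.5 * n * (d * np.log(2 * np.pi) + logdet_c + tr_cinv_s))
    total = 0.0
    for i in range(n):
        o = obs[i]
        d_o = int(o.sum())
        y = x[i, o] - mu[o]
        w_o = w[o]
        m = w_o.T @ w_o + sigma2 * np.eye(q)
        sign, logdet_m = np.linalg.slogdet(m)
        logdet_c = (d_o - q) * np.log(sigma2) + logdet_m
        alpha = np.linalg.solve(m, w_o.T @ y)
        quad = (y @ y - y @ (w_o @ alpha)) / sigma2
        total += -0.5 * (d_o * np.log(2 * np.pi) + logdet_c + quad)
    return total


def fit_ppca(data: ExpressionDataset, n_components: int, max_iter: int = 1000,
             tol: float = 1e-9, seed: int = 0) -> PpcaModel:
    """Fit PPCA by EM; samples are observations, probes are features.

    Missing intensity cells are treated as latent coordinates in the
    E-step, so the fit (and hence the 2-D projections) works on incomplete
    matrices.  The mean vector is fixed at the per-feature mean of the
    observed entries — the exact MLE for complete data — and EM then runs
    over (W, sigma^2), which keeps the log-likelihood trace non-decreasing.
    Iteration stops when the relative log-likelihood change drops below
    ``tol`` or after ``max_iter`` iterations.
    """
    x = data.intensities.to_numpy(dtype=float).T  # samples x features
    n, d = x.shape
    q = int(n_components)
    if not 0 < q < min(n, d):
        raise ValueError("n_components must satisfy 0 < q < min(n_samples, n_features)")
    obs = ~np.isnan(x)
    if not obs.any(axis=0).all():
        bad = data.probe_ids[int(np.where(~obs.any(axis=0))[0][0])]
        raise ValueError(f"feature {bad!r} is missing in every sample")
    if not obs.any(axis=1).all():
        bad = data.sample_ids[int(np.where(~obs.any(axis=1))[0][0])]
        raise ValueError(f"sample {bad!r} has no observed feature")

    mu = np.nanmean(x, axis=0)
    rng = np.random.default_rng(seed)
    w = rng.normal(scale=0.01, size=(d, q))
    resid = np.where(obs, x - mu, 0.0)
    sigma2 = float((resid ** 2).sum() / obs.sum())
    sigma2 = max(sigma2, 1e-12)

    complete = bool(obs.all())
    trace: list[float] = []
    ez = np.zeros((n, q))
    for _ in range(max_iter):
        trace.append(_ppca_loglik(x, obs, w, mu, sigma2))
        if len(trace) >= 2:
            prev, cur = trace[-2], trace[-1]
            if abs(cur - prev) <= tol * (abs(prev) + 1e-12):
                break
        if complete:
            y = x - mu
            m = w.T @ w + sigma2 * np.eye(q)
            minv = np.linalg.inv(m)
            ez = y @ w @ minv                                # n x q
            sum_ezz = n * sigma2 * minv + ez.T @ ez          # q x q
            sum_yz = y.T @ ez                                # d x q
            w_new = sum_yz @ np.linalg.inv(sum_ezz)
            sigma2 = float(
                ((y ** 2).sum()
                 - 2 * np.sum(w_new * sum_yz)
                 + np.sum((w_new.T @ w_new) * sum_ezz)) / (n * d)
            )
            w = w_new
        else:
            sum_ezz = np.zeros((q, q))
            sum_yz = np.zeros((d, q))
            e_y = np.zeros((n, d))       # E[y_i] (centered)
            e_y2_sum = 0.0               # sum_i E[||y_i||^2]
            cov_z = np.zeros((n, q, q))
            for i in range(n):
                o = obs[i]
                y_o = x[i, o] - mu[o]
                w_o = w[o]
                m = w_o.T @ w_o + sigma2 * np.eye(q)
                minv = np.linalg.inv(m)
                ez_i = minv @ (w_o.T @ y_o)
                covz = sigma2 * minv
                ezz = covz + np.outer(ez_i, ez_i)
                ez[i] = ez_i
                cov_z[i] = covz
                sum_ezz += ezz
                # E[y z'] rows: observed -> y_o ez', missing -> W_m E[zz']
                eyz = np.empty((d, q))
                eyz[o] = np.outer(y_o, ez_i)
                w_m = w[~o]
                eyz[~o] = w_m @ ezz
                sum_yz += eyz
                e_y[i, o] = y_o
                e_y[i, ~o] = w_m @ ez_i
                # E[||y||^2]: observed squared + missing mean^2 + variance
                var_m = np.einsum("ij,jk,ik->i", w_m, covz, w_m) + sigma2
                e_y2_sum += float(y_o @ y_o + (e_y[i, ~o] ** 2).sum()
                                  + var_m.sum())
            w_new = sum_yz @ np.linalg.inv(sum_ezz)
            sigma2 = float(
                (e_y2_sum - 2 * np.sum(w_new * sum_yz)
                 + np.sum((w_new.T @ w_new) * sum_ezz)) / (n * d)
            )
            w = w_new
        sigma2 = max(sigma2, 1e-12)

    # final posterior-mean scores under the fitted model
    scores = np.empty((n, q))
    for i in range(n):
        o = obs[i]
        w_o = w[o]
        m = w_o.T @ w_o + sigma2 * np.eye(q)
        scores[i] = np.linalg.solve(m, w_o.T @ (x[i, o] - mu[o]))
    return PpcaModel(w, mu, sigma2, scores, trace,
                     list(data.sample_ids), list(data.probe_ids))


def project_scores(model: PpcaModel, labels: dict[str, str] | None = None
                   ) -> pd.DataFrame:
    """Two-dimensional embedding table (sample, PC1, PC2, label) from the
    first two components' posterior scores."""
    if model.n_components < 2:
        raise ValueError("projection needs a model with >=2 components")
    labels = labels or {}
    return pd.DataFrame({
        "sample": model.sample_ids,
        "PC1": model.scores[:, 0],
        "PC2": model.scores[:, 1],
        "label": [labels.get(s, "") for s in model.sample_ids],
    })
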