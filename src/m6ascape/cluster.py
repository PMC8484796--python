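"""Resampling-based consensus clustering and PCA validation.

Samples are clustered repeatedly on random subsamples (agglomerative Ward
on Euclidean distance over per-gene z-scored expression); the fraction of
runs in which two samples co-cluster, among runs where both were drawn,
forms the consensus matrix.  The number of clusters is chosen by PAC (the
proportion of ambiguous consensus entries), with the consensus-CDF
delta-area reported as a secondary diagnostic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix
from .stats import km_estimate

logger = logging.getLogger(__name__)

__all__ = ["ConsensusResult", "PCACoords", "consensus_cluster", "select_k",
           "pca_embed", "orient_cluster_names"]


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, labels and model-selection statistics."""

    sample_ids: list[str]
    consensus: dict[int, np.ndarray]          # k -> samples x samples matrix
    labels: dict[int, np.ndarray]             # k -> integer labels in 1..k
    cluster_consensus: dict[int, np.ndarray]  # k -> per-cluster mean consensus
    pac: dict[int, float]
    delta_area: dict[int, float]
    params: dict = field(default_factory=dict)

    def labels_series(self, k: int) -> pd.Series:
        return pd.Series(self.labels[k], index=self.sample_ids, name=f"k{k}")


@dataclass
class PCACoords:
    coords: pd.DataFrame                       # samples x components
    explained_variance_ratio: np.ndarray


def _zscore_genes(values: pd.DataFrame) -> np.ndarray:
    X = values.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    keep = sd[:, 0] > 0
    if not keep.all():
        logger.warning("consensus_cluster: %d constant gene(s) dropped", (~keep).sum())
    return (X[keep] - mu[keep]) / sd[keep]


def _ward_labels(X_samples: np.ndarray, k: int) -> np.ndarray:
    Z = linkage(X_samples, method="ward")
    return fcluster(Z, t=k, criterion="maxclust")


def consensus_cluster(
    expr: ExpressionMatrix,
    k_range: list[int] | range = range(2, 7),
    reps: int = 1000,
    subsample: float = 0.8,
    seed: int = 0,
    zscore: bool = True,
) -> ConsensusResult:
    """Consensus clustering of samples over the genes of *expr*.

    For each repetition a fraction *subsample* of samples is drawn without
    replacement and Ward-clustered at each k; the consensus matrix entry is
    co-cluster count / co-sample count.  Final labels at each k come from
    average-linkage clustering of 1 - consensus.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not 0.0 < subsample <= 1.0:
        raise ValueError("subsample must lie in (0, 1]")
    ks = sorted(set(int(k) for k in k_range))
    n = len(expr.sample_ids)
    if any(k < 2 or k >= n for k in ks):
        raise ValueError(f"every k must satisfy 2 <= k <= n-1 (n={n})")

    X = _zscore_genes(expr.values) if zscore else expr.values.to_numpy(dtype=float)
    S = X.T  # samples x genes
    rng = np.random.default_rng(seed)
    m = int(np.ceil(subsample * n))

    co_cluster = {k: np.zeros((n, n)) for k in ks}
    co_sample = np.zeros((n, n))
    for _ in range(reps):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        co_sample[np.ix_(idx, idx)] += 1
        sub = S[idx]
        Z = linkage(sub, method="ward")
        for k in ks:
            lab = fcluster(Z, t=k, criterion="maxclust")
            for c in np.unique(lab):
                members = idx[lab == c]
                co_cluster[k][np.ix_(members, members)] += 1

    if (co_sample == 0).any():
        raise ValueError(
            "some sample pairs were never co-sampled; increase reps or subsample")

    consensus: dict[int, np.ndarray] = {}
    labels: dict[int, np.ndarray] = {}
    cluster_cons: dict[int, np.ndarray] = {}
    pac: dict[int, float] = {}
    areas: dict[int, float] = {}
    for k in ks:
        M = co_cluster[k] / co_sample
        np.fill_diagonal(M, 1.0)
        M = (M + M.T) / 2.0
        consensus[k] = M
        D = 1.0 - M
        np.fill_diagonal(D, 0.0)
        Zf = linkage(squareform(D, checks=False), method="average")
        lab = fcluster(Zf, t=k, criterion="maxclust")
        labels[k] = lab
        cc = np.array([
            M[np.ix_(lab == c, lab == c)][np.triu_indices((lab == c).sum(), 1)].mean()
            if (lab == c).sum() > 1 else 1.0
            for c in range(1, k + 1)
        ])
        cluster_cons[k] = cc
        tri = M[np.triu_indices(n, 1)]
        pac[k] = float(((tri > 0.1) & (tri < 0.9)).mean())
        # area under the empirical consensus CDF
        xs = np.sort(tri)
        cdf_area = float(np.trapezoid(np.arange(1, xs.size + 1) / xs.size, xs))
        areas[k] = cdf_area
    delta = {}
    prev = None
    for k in ks:
        if prev is None or prev == 0:
            delta[k] = areas[k]
        else:
            delta[k] = (areas[k] - prev) / prev
        prev = areas[k]

    return ConsensusResult(
        sample_ids=expr.sample_ids,
        consensus=consensus, labels=labels, cluster_consensus=cluster_cons,
        pac=pac, delta_area=delta,
        params={"reps": reps, "subsample": subsample, "seed": seed,
                "distance": "euclidean", "linkage": "ward", "zscore": zscore})


def select_k(result: ConsensusResult) -> tuple[int, dict]:
    """Choose k as argmin PAC (ties -> smaller k); flag unstable solutions.

    Returns (k, diagnostics) where diagnostics carries PAC and delta-area
    per k and an ``unstable`` flag set when even the best PAC exceeds 0.5.
    """
    ks = sorted(result.pac)
    if len(ks) == 1:
        warnings.warn("select_k: single k evaluated; returning it", stacklevel=2)
        k = ks[0]
    else:
        k = min(ks, key=lambda kk: (result.pac[kk], kk))
    diagnostics = {
        "pac": dict(result.pac),
        "delta_area": dict(result.delta_area),
        "unstable": bool(result.pac[k] > 0.5),
    }
    return k, diagnostics


def pca_embed(expr: ExpressionMatrix, n_components: int = 2) -> PCACoords:
    """Gene-centered PCA of samples via SVD.

    Sign convention: within each component the largest-magnitude gene
    loading is made positive, so embeddings are reproducible across runs.
    """
    X = expr.values.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_components > min(n_genes, n_samples):
        raise ValueError("n_components exceeds matrix rank bound")
    Xc = X - X.mean(axis=1, keepdims=True)
    if np.allclose(Xc, 0.0):
        raise ValueError("constant expression matrix has no principal components")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    for j in range(n_components):
        i_max = np.argmax(np.abs(U[:, j]))
        if U[i_max, j] < 0:
            U[:, j] *= -1
            Vt[j] *= -1
    var = s ** 2
    evr = var / var.sum()
    coords = pd.DataFrame(
        (Vt[:n_components].T * s[:n_components]),
        index=expr.sample_ids,
        columns=[f"PC{j + 1}" for j in range(n_components)])
    return PCACoords(coords, evr[:n_components])


def orient_cluster_names(
    labels: pd.Series,
    clinical=None,
) -> pd.Series:
    """Map integer cluster labels to letters, "A" first.

    With clinical data, "A" is the better-survival cluster (higher
    Kaplan-Meier median, log-rank orientation as in the source study);
    otherwise clusters are lettered by size, descending.
    """
    labels = pd.Series(labels)
    uniq = sorted(labels.unique())
    if clinical is not None:
        clin = clinical.df.set_index("sample_id").loc[labels.index]
        med = {}
        for c in uniq:
            mask = (labels == c).to_numpy()
            t = clin.loc[mask, "os_time"].to_numpy()
            e = clin.loc[mask, "os_event"].to_numpy()
            km = km_estimate(t, e)
            med[c] = km.median if np.isfinite(km.median) else float(t.mean() + 1e9)
        order = sorted(uniq, key=lambda c: -med[c])
    else:
        order = sorted(uniq, key=lambda c: -(labels == c).sum())
    letter = {c: chr(ord("A") + i) for i, c in enumerate(order)}
    return labels.map(letter)
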