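"""Single-sample gene-set scoring and over-representation analysis.

Two per-sample scoring variants are provided.  ``ssgsea``: within each
sample genes are ranked by expression (ties averaged) and the enrichment
score is the summed difference between the weighted in-set running ECDF
(weights |rank|^alpha, normalized to 1 over the set) and the unweighted
out-of-set running ECDF.  ``gsva``: a Gaussian-kernel CDF is computed per
gene across samples, genes are re-ranked per sample on a symmetric rank
statistic, and the score is the signed maximum deviation of the same
random walk.  ORA is the upper-tail hypergeometric test with BH control.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExpressionMatrix, GeneSetCollection
from .stats import bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["ScoreMatrix", "score_gene_sets", "ora_hypergeometric"]


class ScoreMatrix:
    """set_names x sample_ids enrichment scores with method metadata."""

    def __init__(self, values: pd.DataFrame, method: str, params: dict):
        if not np.isfinite(values.to_numpy()).all():
            raise ValueError("non-finite enrichment scores")
        self.values = values
        self.method = method
        self.params = params

    @property
    def set_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def _running_es(order: np.ndarray, weight: np.ndarray, in_set: np.ndarray,
                statistic: str) -> float:
    """Random-walk enrichment over a ranked gene list.

    order: gene indices from best to worst rank.  weight: per-gene weights
    |rank statistic|^alpha.  statistic: 'sum' (ssGSEA, sum of running
    differences) or 'maxdev' (GSVA, signed maximum deviation).
    """
    w = weight[order]
    hit = in_set[order]
    w_hit = np.where(hit, w, 0.0)
    denom_in = w_hit.sum()
    if denom_in == 0:
        return 0.0
    p_in = np.cumsum(w_hit) / denom_in
    n_out = (~hit).sum()
    if n_out == 0:
        return 0.0
    p_out = np.cumsum(~hit) / n_out
    diff = p_in - p_out
    if statistic == "sum":
        return float(diff.sum())
    i = int(np.argmax(np.abs(diff)))
    return float(diff[i])


def score_gene_sets(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    method: str = "ssgsea",
    alpha: float = 0.25,
    normalize: bool = False,
    kernel_bandwidth_factor: float = 4.0,
    min_set_size: int = 1,
) -> ScoreMatrix:
    """Score every gene set in every sample.

    Sets are intersected with the matrix genes; sets retaining fewer than
    *min_set_size* genes are skipped with a warning.  ``normalize`` divides
    the whole score matrix by its (max - min) range.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if method not in ("ssgsea", "gsva"):
        raise ValueError(f"unknown scoring method {method!r}")
    if len(sets) == 0:
        raise ValueError("empty gene set collection")
    usable = sets.restricted_to(expr.gene_ids, min_size=min_set_size)
    if len(usable) == 0:
        raise ValueError(
            f"no gene set retains >= {min_set_size} genes on this matrix")

    X = expr.values.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}

    if method == "ssgsea":
        # per-sample descending ranks (average ties): best gene -> rank n_genes
        ranks = sps.rankdata(X, axis=0, method="average")
        stat = ranks  # |z-rank| statistic: the descending rank value itself
        orders = np.argsort(-X, axis=0, kind="stable")
    else:
        sd = X.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        h = sd / kernel_bandwidth_factor
        kcdf = np.empty_like(X)
        for g in range(n_genes):
            # Gaussian-kernel CDF of each sample's value across the cohort
            z = (X[g][:, None] - X[g][None, :]) / h[g]
            kcdf[g] = sps.norm.cdf(z).mean(axis=1)
        r = sps.rankdata(kcdf, axis=0, method="average")
        stat = np.abs(n_genes / 2.0 - r)  # symmetric rank statistic
        orders = np.argsort(-kcdf, axis=0, kind="stable")

    weights = np.abs(stat) ** alpha
    statistic = "sum" if method == "ssgsea" else "maxdev"

    out = np.zeros((len(usable), n_samples))
    for si, (name, genes) in enumerate(usable):
        in_set = np.zeros(n_genes, dtype=bool)
        in_set[[gene_pos[g] for g in genes]] = True
        for j in range(n_samples):
            out[si, j] = _running_es(orders[:, j], weights[:, j], in_set, statistic)

    values = pd.DataFrame(out, index=list(usable.sets), columns=expr.sample_ids)
    if normalize:
        rng_ = values.to_numpy().max() - values.to_numpy().min()
        if rng_ > 0:
            values = values / rng_
    return ScoreMatrix(values, method,
                       {"alpha": alpha, "normalize": normalize})


def ora_hypergeometric(
    query: list[str],
    universe: list[str],
    sets: GeneSetCollection,
) -> pd.DataFrame:
    """Over-representation of *query* genes in each set.

    Upper-tail hypergeometric p for an overlap at least as large as
    observed, BH-adjusted across sets.  Query genes outside the universe
    are dropped with a warning.
    """
    if not query:
        raise ValueError("empty query gene list")
    uni = list(dict.fromkeys(universe))
    uni_set = set(uni)
    q = list(dict.fromkeys(query))
    outside = [g for g in q if g not in uni_set]
    if outside:
        logger.warning("ora: %d query genes outside universe dropped: %s",
                       len(outside), outside[:5])
        q = [g for g in q if g in uni_set]
    if not q:
        raise ValueError("no query genes remain inside the universe")
    N, n = len(uni), len(q)
    rows = []
    for name, genes in sets:
        members = [g for g in genes if g in uni_set]
        K = len(members)
        k = len(set(members) & set(q))
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(sps.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set_name": name, "overlap": k, "set_size": K,
                     "query_size": n, "universe_size": N, "p": min(p, 1.0)})
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    return table.sort_values("p", kind="stable").reset_index(drop=True)
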