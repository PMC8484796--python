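"""Multi-cohort merging and empirical-Bayes batch correction.

The correction is the parametric location/scale model: per-gene
standardization against a batch-size-weighted grand mean and pooled
variance, Normal prior on per-batch gene locations and Inverse-Gamma prior
on per-batch gene scales (hyperparameters by method of moments), iterated
posterior updates to convergence, then back-transformation.  No reference
batch: all batches are shrunk toward the grand model, and no biological
covariates enter (cluster labels are unknown at correction time).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["BatchModel", "merge_cohorts", "combat_adjust"]


@dataclass
class BatchModel:
    """Fitted EB batch-adjustment parameters."""

    grand_mean: pd.Series                  # per-gene alpha-hat
    pooled_var: pd.Series                  # per-gene sigma-hat^2
    gamma_star: pd.DataFrame               # batches x genes, EB-shrunk locations
    delta2_star: pd.DataFrame              # batches x genes, EB-shrunk variances
    hyper: dict                            # per-batch gamma_bar, tau2_bar, lambda, theta
    iterations: int
    converged: bool


def merge_cohorts(
    matrices: list[ExpressionMatrix], cohort_names: list[str]
) -> ExpressionMatrix:
    """Column-concatenate cohorts on the intersection of their gene sets.

    Each sample receives its cohort name as batch label.  Sample ids must be
    disjoint across cohorts.
    """
    if len(matrices) < 2:
        raise ValueError("merge_cohorts needs >= 2 matrices")
    if len(cohort_names) != len(matrices):
        raise ValueError("one cohort name per matrix required")
    genes = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        genes &= set(m.gene_ids)
    if not genes:
        raise ValidationError("empty gene intersection across cohorts")
    ordered = [g for g in matrices[0].gene_ids if g in genes]
    logger.info("merge_cohorts: %d genes in common across %d cohorts",
                len(ordered), len(matrices))
    all_samples: set[str] = set()
    for m in matrices:
        overlap = all_samples & set(m.sample_ids)
        if overlap:
            raise ValidationError(f"sample ids duplicated across cohorts: {sorted(overlap)[:5]}")
        all_samples |= set(m.sample_ids)
    values = pd.concat([m.values.loc[ordered] for m in matrices], axis=1)
    batch = pd.Series(
        np.concatenate([[name] * len(m.sample_ids)
                        for m, name in zip(matrices, cohort_names)]),
        index=values.columns, name="batch")
    return ExpressionMatrix(values, batch)


def _moments_inverse_gamma(d2: np.ndarray) -> tuple[float, float]:
    """Method-of-moments Inverse-Gamma(lambda, theta) hyperparameters."""
    m = float(np.mean(d2))
    v = float(np.var(d2, ddof=1)) if d2.size > 1 else 0.0
    if v <= 0:
        # flat-ish prior when batch variances are (near) identical
        return 2.0 + 1e6, m * (1.0 + 1e6)
    lam = (2.0 * v + m * m) / v
    theta = (m * v + m ** 3) / v
    return lam, theta


def combat_adjust(
    expr: ExpressionMatrix,
    batch: pd.Series | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[ExpressionMatrix, BatchModel]:
    """Remove additive/multiplicative batch effects by EB shrinkage.

    Returns the corrected matrix (same shape, ids and ordering) and the
    fitted :class:`BatchModel`.  With a single batch the input is returned
    unchanged.
    """
    if batch is None:
        batch = expr.batch
    if batch is None:
        raise ValueError("no batch labels supplied")
    batch = pd.Series(batch).reindex(expr.values.columns)
    if batch.isna().any():
        raise ValidationError("batch labels do not cover all samples")

    X = expr.values.to_numpy(dtype=float)
    genes = expr.values.index
    levels = list(pd.unique(batch))
    n_per = {b: int((batch == b).sum()) for b in levels}
    for b, nb in n_per.items():
        if nb < 2:
            raise ValidationError(f"batch {b!r} has a single sample; cannot estimate scale")
    if len(levels) == 1:
        model = BatchModel(
            grand_mean=expr.values.mean(axis=1),
            pooled_var=expr.values.var(axis=1, ddof=1),
            gamma_star=pd.DataFrame(0.0, index=levels, columns=genes),
            delta2_star=pd.DataFrame(1.0, index=levels, columns=genes),
            hyper={}, iterations=0, converged=True)
        return ExpressionMatrix(expr.values.copy(), expr.batch), model

    masks = {b: (batch == b).to_numpy() for b in levels}
    n_total = X.shape[1]

    # grand model: batch-size-weighted per-gene mean, pooled within-batch
    # residual variance (batch locations removed before pooling)
    batch_means = np.stack([X[:, masks[b]].mean(axis=1) for b in levels])  # B x G
    weights = np.array([n_per[b] / n_total for b in levels])
    alpha = weights @ batch_means
    resid = X.copy()
    for bi, b in enumerate(levels):
        resid[:, masks[b]] -= batch_means[bi][:, None]
    sigma2 = (resid ** 2).mean(axis=1)
    zero = sigma2 <= 0
    if zero.any():
        raise ValidationError(
            f"zero pooled variance for gene(s) {list(genes[zero])[:5]}")
    Z = (X - alpha[:, None]) / np.sqrt(sigma2)[:, None]

    gamma_star = np.zeros((len(levels), X.shape[0]))
    delta2_star = np.ones_like(gamma_star)
    hyper: dict = {}
    iters_used = 0
    converged = True
    for bi, b in enumerate(levels):
        Zb = Z[:, masks[b]]
        nb = n_per[b]
        g_hat = Zb.mean(axis=1)
        d2_hat = Zb.var(axis=1, ddof=1)
        gamma_bar = float(g_hat.mean())
        tau2_bar = float(g_hat.var(ddof=1))
        lam, theta = _moments_inverse_gamma(d2_hat)
        hyper[b] = {"gamma_bar": gamma_bar, "tau2_bar": tau2_bar,
                    "lambda": lam, "theta": theta}
        g_star = g_hat.copy()
        d2_star = d2_hat.copy()
        it = 0
        for it in range(1, max_iter + 1):
            g_new = (nb * tau2_bar * g_hat + d2_star * gamma_bar) / (
                nb * tau2_bar + d2_star)
            ss = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            d2_new = (theta + 0.5 * ss) / (nb / 2.0 + lam - 1.0)
            change = max(np.abs(g_new - g_star).max(), np.abs(d2_new - d2_star).max())
            g_star, d2_star = g_new, d2_new
            if change < tol:
                break
        else:
            converged = False
            logger.warning("combat_adjust: batch %s did not converge in %d iterations",
                           b, max_iter)
        iters_used = max(iters_used, it)
        gamma_star[bi] = g_star
        delta2_star[bi] = d2_star

    adjusted = Z.copy()
    for bi, b in enumerate(levels):
        adjusted[:, masks[b]] = (
            (Z[:, masks[b]] - gamma_star[bi][:, None])
            / np.sqrt(delta2_star[bi])[:, None]
        )
    corrected = adjusted * np.sqrt(sigma2)[:, None] + alpha[:, None]
    # re-anchor each gene's overall mean: batch correction moves batches
    # relative to one another, never the grand location
    corrected += (X.mean(axis=1) - corrected.mean(axis=1))[:, None]

    out = pd.DataFrame(corrected, index=genes, columns=expr.values.columns)
    model = BatchModel(
        grand_mean=pd.Series(alpha, index=genes),
        pooled_var=pd.Series(sigma2, index=genes),
        gamma_star=pd.DataFrame(gamma_star, index=levels, columns=genes),
        delta2_star=pd.DataFrame(delta2_star, index=levels, columns=genes),
        hyper=hyper, iterations=iters_used, converged=converged)
    return ExpressionMatrix(out, expr.batch if expr.batch is not None else batch), model
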