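"""The m6Ascore prognostic signature.

Pipeline: differential expression between modification patterns with an
empirical-Bayes moderated t (variance shrinkage toward a scaled
inverse-chi-square prior), redundancy removal by random-forest out-of-bag
mean-decrease-accuracy importance, a per-gene univariate Cox survival
filter, partition of the surviving genes by the sign of their Cox
coefficient into sets X (risk) and Y (protective), and the per-sample score

    m6Ascore = scale( sum_{g in X} e_g  -  sum_{g in Y} e_g )

with the cohort median splitting samples into high/low score groups.
:class:`M6aScoreModel` wraps the chain statsmodels-style: construct from
data, ``fit()`` returns an :class:`M6aScoreResults` carrying estimates,
diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import digamma, polygamma
from sklearn.tree import DecisionTreeClassifier

from .io import ClinicalTable, ExpressionMatrix
from .stats import bh_adjust, cox_fit, km_estimate, logrank_test

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureModel",
    "ScoreVector",
    "moderated_t_de",
    "filter_degs",
    "rf_importance_select",
    "prognostic_filter",
    "partition_by_sign",
    "m6a_score",
    "median_split",
    "M6aScoreModel",
    "M6aScoreResults",
]


# ---------------------------------------------------------------------------
# moderated t


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on a monotone function)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif / x) < 1e-10:
            break
    return x


def moderated_t_de(
    expr: ExpressionMatrix,
    labels: pd.Series,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Two-group moderated t with EB variance shrinkage.

    Per gene the pooled variance s_g^2 (d_g = n1 + n2 - 2 df) is shrunk to
    s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g), with the prior df d0 and
    location s0^2 estimated by method of moments on log s_g^2.  The
    moderated t has d0 + d_g degrees of freedom.  ``d0_override=0`` recovers
    the ordinary pooled-variance t exactly.

    Returns rows (gene, log2FC, t, p, adj_p); log2FC = mean(group2) -
    mean(group1) on the log2-scale matrix.
    """
    labels = pd.Series(labels).reindex(expr.sample_ids)
    if labels.isna().any():
        raise ValueError("labels do not cover all samples")
    groups = list(pd.unique(labels))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    m1 = (labels == groups[0]).to_numpy()
    m2 = (labels == groups[1]).to_numpy()
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples")
    if expr.shape[0] < 10 and d0_override is None:
        raise ValueError("need >= 10 genes to estimate the variance prior")

    X = expr.values.to_numpy(dtype=float)
    mean1 = X[:, m1].mean(axis=1)
    mean2 = X[:, m2].mean(axis=1)
    var1 = X[:, m1].var(axis=1, ddof=1)
    var2 = X[:, m2].var(axis=1, ddof=1)
    d = n1 + n2 - 2
    s2 = ((n1 - 1) * var1 + (n2 - 1) * var2) / d
    if (s2 <= 0).all():
        raise ValueError("all genes have zero variance")

    if d0_override is not None and d0_override == 0:
        d0, s02 = 0.0, 0.0
    else:
        d0, s02 = _fit_variance_prior(s2, d)
        if d0_override is not None:
            d0 = float(d0_override)

    if d0 == 0:
        s2_tilde = s2.copy()
        df = np.full_like(s2, d)
    elif np.isinf(d0):
        s2_tilde = np.full_like(s2, s02)
        df = np.full_like(s2, np.inf)
    else:
        s2_tilde = (d0 * s02 + d * s2) / (d0 + d)
        df = np.full_like(s2, d0 + d)

    diff = mean2 - mean1
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    table = pd.DataFrame({
        "gene": expr.gene_ids, "log2FC": diff, "t": t, "p": p,
    })
    table["adj_p"] = bh_adjust(table["p"].to_numpy())
    table.attrs["d0"] = d0
    table.attrs["s0_squared"] = s02
    table.attrs["contrast"] = f"{groups[1]} - {groups[0]}"
    return table


def _fit_variance_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square prior.

    Works on log s_g^2, matching the classic moderated-t hyperparameter
    estimator; genes with zero sample variance are excluded from the fit.
    """
    s2_pos = s2[s2 > 0]
    z = np.log(s2_pos)
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(polygamma(1, d / 2.0))
    if evar <= 0:
        return float("inf"), float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s02 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


def filter_degs(
    de: pd.DataFrame, adj_p_max: float = 0.05, lfc_min: float = 0.5
) -> list[str]:
    """Genes with adj_p strictly below *adj_p_max* AND |log2FC| strictly
    above *lfc_min*."""
    mask = (de["adj_p"] < adj_p_max) & (de["log2FC"].abs() > lfc_min)
    return list(de.loc[mask, "gene"])


# ---------------------------------------------------------------------------
# random-forest redundancy removal


def rf_importance_select(
    expr: ExpressionMatrix,
    labels: pd.Series,
    n_trees: int = 500,
    seed: int = 0,
    keep_rule: str = "positive_importance",
    top_n: int | None = None,
) -> pd.DataFrame:
    """Rank genes by out-of-bag mean decrease in accuracy.

    A bagged forest of CART trees (bootstrap per tree, sqrt(p) features per
    split) is grown on samples x genes; each gene's importance is the mean,
    over trees, of the drop in that tree's out-of-bag accuracy when the
    gene's values are permuted among the out-of-bag samples.  Returns the
    importance table sorted descending with a ``kept`` column applying
    *keep_rule* ('positive_importance' or 'top_n').
    """
    if n_trees < 50:
        warnings.warn("rf_importance_select: n_trees < 50 gives noisy importances",
                      stacklevel=2)
    labels = pd.Series(labels).reindex(expr.sample_ids)
    if labels.isna().any():
        raise ValueError("labels do not cover all samples")
    y, class_names = pd.factorize(labels)
    if len(class_names) < 2:
        raise ValueError("labels contain a single class")
    if expr.shape[0] < 2:
        raise ValueError("need >= 2 genes")
    X = expr.values.to_numpy(dtype=float).T  # samples x genes
    n, p = X.shape
    rng = np.random.default_rng(seed)
    drops = np.zeros(p)
    counts = np.zeros(p)
    for t in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeClassifier(
            max_features="sqrt",
            random_state=int(rng.integers(0, 2 ** 31 - 1)),
        )
        tree.fit(X[boot], y[boot])
        if oob.size == 0:
            continue
        X_oob = X[oob]
        y_oob = y[oob]
        acc = (tree.predict(X_oob) == y_oob).mean()
        perm = rng.permutation(oob.size)
        for j in range(p):
            Xp = X_oob.copy()
            Xp[:, j] = X_oob[perm, j]
            acc_perm = (tree.predict(Xp) == y_oob).mean()
            drops[j] += acc - acc_perm
            counts[j] += 1
    importance = np.divide(drops, counts, out=np.zeros(p), where=counts > 0)
    table = pd.DataFrame({"gene": expr.gene_ids, "importance": importance})
    table = table.sort_values("importance", ascending=False,
                              kind="stable").reset_index(drop=True)
    if keep_rule == "positive_importance":
        table["kept"] = table["importance"] > 0
    elif keep_rule == "top_n":
        if top_n is None:
            raise ValueError("top_n keep_rule needs top_n")
        table["kept"] = np.arange(len(table)) < top_n
    else:
        raise ValueError(f"unknown keep_rule {keep_rule!r}")
    return table


# ---------------------------------------------------------------------------
# survival filter and score


@dataclass
class SignatureModel:
    """Selected signature genes with their Cox statistics and scale."""

    genes: pd.DataFrame                      # gene, importance, beta, hr, p
    X: list[str] = field(default_factory=list)
    Y: list[str] = field(default_factory=list)
    scale_mean: float = float("nan")
    scale_sd: float = float("nan")
    median: float = float("nan")
    alpha_surv: float = 0.05

    @property
    def fitted_scale(self) -> bool:
        return np.isfinite(self.scale_mean) and np.isfinite(self.scale_sd)


@dataclass
class ScoreVector:
    """Per-sample m6Ascore with high/low group labels."""

    scores: pd.Series
    groups: pd.Series
    median: float


def prognostic_filter(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    genes: list[str],
    alpha_surv: float = 0.05,
    importance: pd.DataFrame | None = None,
) -> SignatureModel:
    """Keep genes whose continuous expression predicts survival (Cox p < alpha).

    One univariate Cox PH fit per gene; beta, HR and Wald p are stored.
    Genes whose fit fails (e.g. separation) are dropped with a warning.
    """
    missing = set(genes) - set(expr.gene_ids)
    if missing:
        raise ValueError(f"genes not in matrix: {sorted(missing)[:5]}")
    clin = clinical.aligned_to(expr.sample_ids)
    time = clin.df["os_time"].to_numpy()
    event = clin.df["os_event"].to_numpy()
    imp = (importance.set_index("gene")["importance"]
           if importance is not None else None)
    rows = []
    for g in genes:
        x = expr.values.loc[g].to_numpy()
        try:
            fit = cox_fit(time, event, pd.DataFrame({g: x}))
        except ValueError as exc:
            logger.warning("prognostic_filter: Cox fit failed for %s (%s)", g, exc)
            continue
        row = fit.summary.loc[g]
        rows.append({"gene": g,
                     "importance": float(imp[g]) if imp is not None and g in imp else np.nan,
                     "beta": float(row["beta"]), "hr": float(row["hr"]),
                     "p": float(row["p"])})
    table = pd.DataFrame(rows, columns=["gene", "importance", "beta", "hr", "p"])
    kept = table[table["p"] < alpha_surv].reset_index(drop=True)
    if kept.empty:
        raise ValueError(
            "no gene passes the survival filter; review alpha_surv or the DEG set")
    return SignatureModel(genes=kept, alpha_surv=alpha_surv)


def partition_by_sign(model: SignatureModel) -> tuple[list[str], list[str]]:
    """Split signature genes by the sign of their Cox coefficient.

    X = {beta > 0} (risk side), Y = {beta < 0} (protective side); a beta of
    exactly zero is a degenerate input and raises.
    """
    zero = model.genes["beta"] == 0
    if zero.any():
        raise ValueError(
            f"zero Cox coefficient for {list(model.genes.loc[zero, 'gene'])}: "
            "sign partition undefined")
    model.X = list(model.genes.loc[model.genes["beta"] > 0, "gene"])
    model.Y = list(model.genes.loc[model.genes["beta"] < 0, "gene"])
    return model.X, model.Y


def m6a_score(
    expr: ExpressionMatrix,
    model: SignatureModel,
    mode: str = "sum",
    standardize_genes: bool = False,
) -> ScoreVector:
    """Per-sample score scale(sum X - sum Y), z-scaled on the training cohort.

    In training mode (model scale parameters unset) the mean/sd (n-1
    denominator) are fitted and stored; in application mode the stored
    parameters are reused so scores are comparable across cohorts.
    ``mode='pca'`` replaces the raw sum with the first principal-component
    projection of the signature genes (sign-aligned with sum X - sum Y).
    """
    needed = model.X + model.Y
    if not needed:
        raise ValueError("signature model has no genes")
    missing = set(needed) - set(expr.gene_ids)
    if missing:
        raise ValueError(f"signature genes missing from matrix: {sorted(missing)[:5]}")
    V = expr.values.loc[needed]
    if standardize_genes:
        sd = V.std(axis=1, ddof=1)
        if (sd == 0).any():
            raise ValueError("zero-variance signature gene under standardization")
        V = V.sub(V.mean(axis=1), axis=0).div(sd, axis=0)
    contrast = np.sum([V.loc[g] for g in model.X], axis=0) if model.X else 0.0
    if model.Y:
        contrast = contrast - np.sum([V.loc[g] for g in model.Y], axis=0)
    raw = pd.Series(np.asarray(contrast, dtype=float), index=expr.sample_ids)
    if mode == "pca":
        Xc = V.to_numpy() - V.to_numpy().mean(axis=1, keepdims=True)
        _u, _s, vt = np.linalg.svd(Xc, full_matrices=False)
        pc1 = pd.Series(vt[0] * _s[0], index=expr.sample_ids)
        if np.corrcoef(pc1, raw)[0, 1] < 0:
            pc1 = -pc1
        raw = pc1
    elif mode != "sum":
        raise ValueError(f"unknown score mode {mode!r}")
    if not model.fitted_scale:
        model.scale_mean = float(raw.mean())
        sd = float(raw.std(ddof=1))
        if sd == 0:
            raise ValueError("all samples share one raw score; cannot scale")
        model.scale_sd = sd
    scores = (raw - model.scale_mean) / model.scale_sd
    groups, median = median_split_series(scores, None if np.isnan(model.median) else model.median)
    if np.isnan(model.median):
        model.median = median
    return ScoreVector(scores, groups, median)


def median_split_series(
    scores: pd.Series, median: float | None = None
) -> tuple[pd.Series, float]:
    """Label samples 'high' (score > median) or 'low' (score <= median)."""
    if len(scores) < 2 and median is None:
        raise ValueError("median split needs >= 2 samples")
    if median is None:
        median = float(np.median(scores))
    groups = pd.Series(np.where(scores > median, "high", "low"),
                       index=scores.index, name="score_group")
    if (groups == "low").all():
        warnings.warn("median_split: all samples fall in the low group", stacklevel=2)
    return groups, median


def median_split(scores: ScoreVector) -> pd.Series:
    """Group labels for a fitted :class:`ScoreVector` (strict-above-median)."""
    groups, _ = median_split_series(scores.scores, scores.median)
    return groups


# ---------------------------------------------------------------------------
# statsmodels-style wrapper


class M6aScoreModel:
    """Derive the m6Ascore signature from a cohort with cluster labels.

    Parameters
    ----------
    expr : ExpressionMatrix
        Log2-scale expression, batch-corrected if multi-cohort.
    cluster_labels : Series
        Modification-pattern labels (two groups) per sample.
    clinical : ClinicalTable
        Overall survival per sample.
    de_adj_p, de_lfc : float
        DEG thresholds (strict inequalities).
    alpha_surv : float
        Per-gene Cox survival filter threshold.
    n_trees : int
        Forest size for the redundancy-removal importance.
    score_mode : str
        'sum' (scale(sum X - sum Y)) or 'pca' (PC1 projection).
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        cluster_labels: pd.Series,
        clinical: ClinicalTable,
        de_adj_p: float = 0.05,
        de_lfc: float = 0.5,
        alpha_surv: float = 0.05,
        n_trees: int = 500,
        keep_rule: str = "positive_importance",
        top_n: int | None = None,
        score_mode: str = "sum",
        standardize_genes: bool = False,
    ):
        self.expr = expr
        self.cluster_labels = pd.Series(cluster_labels).reindex(expr.sample_ids)
        if self.cluster_labels.isna().any():
            raise ValueError("cluster labels do not cover all samples")
        self.clinical = clinical.aligned_to(expr.sample_ids)
        self.de_adj_p = de_adj_p
        self.de_lfc = de_lfc
        self.alpha_surv = alpha_surv
        self.n_trees = n_trees
        self.keep_rule = keep_rule
        self.top_n = top_n
        self.score_mode = score_mode
        self.standardize_genes = standardize_genes

    @classmethod
    def from_cohort(cls, cohort, cluster_labels=None, **kwargs) -> "M6aScoreModel":
        """Build from a :class:`~m6ascape.synthetic.SyntheticCohort`."""
        labels = cluster_labels if cluster_labels is not None else cohort.cluster_labels
        return cls(cohort.expression, labels, cohort.clinical, **kwargs)

    def fit(self, seed: int = 0) -> "M6aScoreResults":
        de = moderated_t_de(self.expr, self.cluster_labels)
        degs = filter_degs(de, self.de_adj_p, self.de_lfc)
        if not degs:
            raise ValueError("no differentially expressed genes at the thresholds")
        deg_expr = self.expr.subset_genes(degs)
        importance = rf_importance_select(
            deg_expr, self.cluster_labels, n_trees=self.n_trees, seed=seed,
            keep_rule=self.keep_rule, top_n=self.top_n)
        kept_genes = list(importance.loc[importance["kept"], "gene"])
        if not kept_genes:
            raise ValueError("random forest kept no genes")
        model = prognostic_filter(
            self.expr, self.clinical, kept_genes, self.alpha_surv, importance)
        partition_by_sign(model)
        score = m6a_score(self.expr, model, mode=self.score_mode,
                          standardize_genes=self.standardize_genes)
        return M6aScoreResults(self, de, degs, importance, model, score)


class M6aScoreResults:
    """Fitted m6Ascore signature: gene sets, scores, groups, diagnostics."""

    def __init__(self, model_spec, de_table, degs, importance, model, score):
        self.model_spec = model_spec
        self.de_table = de_table
        self.degs = degs
        self.importance = importance
        self.model: SignatureModel = model
        self.score: ScoreVector = score

    @property
    def scores(self) -> pd.Series:
        return self.score.scores

    @property
    def groups(self) -> pd.Series:
        return self.score.groups

    def predict(self, expr: ExpressionMatrix) -> ScoreVector:
        """Score a new cohort with the stored scale parameters and median."""
        return m6a_score(expr, self.model, mode=self.model_spec.score_mode,
                         standardize_genes=self.model_spec.standardize_genes)

    def survival_contrast(self) -> dict:
        """Log-rank test and Cox HR of the high vs low score groups."""
        clin = self.model_spec.clinical.df
        time = clin["os_time"].to_numpy()
        event = clin["os_event"].to_numpy()
        groups = self.groups.to_numpy()
        lr = logrank_test(time, event, groups)
        fit = cox_fit(time, event,
                      pd.DataFrame({"high_score": (groups == "high").astype(float)}))
        row = fit.summary.loc["high_score"]
        return {"logrank_p": lr.p, "hr": float(row["hr"]),
                "hr_ci": (float(row["ci_low"]), float(row["ci_high"])),
                "cox_p": float(row["p"])}

    def km_curves(self) -> dict:
        clin = self.model_spec.clinical.df
        out = {}
        for g in ("high", "low"):
            mask = (self.groups == g).to_numpy()
            out[g] = km_estimate(clin.loc[mask, "os_time"].to_numpy(),
                                 clin.loc[mask, "os_event"].to_numpy())
        return out

    def summary(self) -> pd.DataFrame:
        """Per-gene summary of the fitted signature (set, beta, HR, p)."""
        g = self.model.genes.copy()
        g["set"] = np.where(g["beta"] > 0, "X (risk)", "Y (protective)")
        return g[["gene", "set", "importance", "beta", "hr", "p"]].reset_index(drop=True)

    def __repr__(self) -> str:
        sc = self.survival_contrast()
        return (f"<M6aScoreResults: {len(self.model.X)} X genes, "
                f"{len(self.model.Y)} Y genes, {len(self.scores)} samples, "
                f"high-vs-low HR {sc['hr']:.2f}>")
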