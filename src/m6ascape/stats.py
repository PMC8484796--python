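"""Survival and hypothesis-testing backend shared by every pipeline stage.

Cox proportional hazards (Efron tie handling), Kaplan-Meier product-limit
curves and the log-rank test are provided through lifelines; rank-sum,
Fisher exact and correlation tests through scipy; Benjamini-Hochberg
adjustment through statsmodels; ROC/AUC through scikit-learn.  All tests
are two-sided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "CoxFit",
    "KMCurve",
    "TestResult",
    "cox_fit",
    "km_estimate",
    "logrank_test",
    "rank_sum_test",
    "fisher_exact",
    "bh_adjust",
    "correlate",
    "roc_auc",
]


@dataclass
class CoxFit:
    """Cox PH fit: per-covariate beta, HR=exp(beta), Wald 95% CI and p."""

    summary: pd.DataFrame          # index: covariate; columns: beta, hr, ci_low, ci_high, se, p
    log_likelihood: float
    converged: bool
    ties: str = "efron"

    def __getitem__(self, covariate: str) -> pd.Series:
        return self.summary.loc[covariate]


@dataclass
class KMCurve:
    """Product-limit survival estimate."""

    times: np.ndarray              # event/censor times where the curve is defined
    survival: np.ndarray           # S(t), non-increasing from 1.0
    n_at_risk: np.ndarray
    median: float = float("nan")


@dataclass
class TestResult:
    statistic: float
    p: float
    method: str
    effect: dict = field(default_factory=dict)


def cox_fit(
    time: np.ndarray,
    event: np.ndarray,
    covariates: pd.DataFrame | np.ndarray,
) -> CoxFit:
    """Fit a Cox proportional-hazards model (Efron ties, Wald inference).

    Raises on constant covariates and on fits that fail to converge
    (e.g. monotone likelihood from perfect separation).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 1:
        raise ValueError("Cox fit requires at least one event")
    if not isinstance(covariates, pd.DataFrame):
        covariates = pd.DataFrame(np.atleast_2d(np.asarray(covariates, dtype=float).T).T)
        covariates.columns = [f"x{i}" for i in range(covariates.shape[1])]
    covariates = covariates.reset_index(drop=True).astype(float)
    if not np.isfinite(covariates.to_numpy()).all():
        raise ValueError("covariates must be finite")
    const = covariates.nunique() <= 1
    if const.any():
        raise ValueError(f"constant covariate(s): {list(covariates.columns[const])}")
    df = covariates.copy()
    df["_time"] = time
    df["_event"] = event
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except Exception as exc:  # lifelines raises ConvergenceError on separation
        raise ValueError(f"Cox fit did not converge: {exc}") from exc
    s = cph.summary
    out = pd.DataFrame({
        "beta": s["coef"],
        "hr": np.exp(s["coef"]),
        "ci_low": np.exp(s["coef"] - 1.959963984540054 * s["se(coef)"]),
        "ci_high": np.exp(s["coef"] + 1.959963984540054 * s["se(coef)"]),
        "se": s["se(coef)"],
        "p": s["p"],
    })
    out.index = list(covariates.columns)
    return CoxFit(out, float(cph.log_likelihood_), True)


def km_estimate(time: np.ndarray, event: np.ndarray) -> KMCurve:
    """Kaplan-Meier product-limit estimator."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty survival data")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    # n at risk just before each tabulated time
    n_at_risk = np.array([(time >= t).sum() for t in times])
    return KMCurve(times, surv, n_at_risk, float(kmf.median_survival_time_))


def logrank_test(time: np.ndarray, event: np.ndarray, groups: np.ndarray) -> TestResult:
    """k-sample log-rank test (chi-square with k-1 df)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("log-rank test needs >= 2 groups")
    if (counts == 0).any():
        raise ValueError("empty group in log-rank test")
    res = multivariate_logrank_test(time, groups, event)
    return TestResult(float(res.test_statistic), float(res.p_value), "logrank",
                      {"df": len(labels) - 1})


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when both samples are small (n1+n2 <= 20) and
    tie-free; normal approximation with tie and continuity correction
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank-sum test needs non-empty samples")
    pooled = np.concatenate([x, y])
    exact = (x.size + y.size <= 20) and (np.unique(pooled).size == pooled.size)
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=not exact,
    )
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      "wilcoxon-rank-sum", {"exact": exact})


def fisher_exact(table: np.ndarray) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 count table.

    p sums, over tables with the observed margins, the probabilities not
    exceeding that of the observed table; the effect is the sample odds
    ratio.
    """
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("fisher_exact expects a 2x2 table")
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        if (table < 0).any() or not np.allclose(table, np.round(table)):
            raise ValueError("counts must be non-negative integers")
        table = table.astype(int)
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return TestResult(float(odds), float(p), "fisher-exact", {"odds_ratio": float(odds)})


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlate(
    x: np.ndarray, M: pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Correlate *x* against every column of *M*.

    Returns a table (name, r, p); zero-variance columns are skipped with a
    warning.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("correlation needs >= 3 observations")
    if not isinstance(M, pd.DataFrame):
        M = pd.DataFrame(np.atleast_2d(np.asarray(M, dtype=float).T).T)
    rows = []
    fn = sps.pearsonr if method == "pearson" else sps.spearmanr
    for name in M.columns:
        col = M[name].to_numpy(dtype=float)
        if np.ptp(col) == 0 or np.ptp(x) == 0:
            logger.warning("correlate: column %s has zero variance; skipped", name)
            continue
        r, p = fn(x, col)
        rows.append({"name": name, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows, columns=["name", "r", "p"])


def roc_auc(score: np.ndarray, labels: np.ndarray) -> tuple[float, pd.DataFrame]:
    """ROC curve and AUC (Mann-Whitney U / (n1*n0), ties count 0.5)."""
    score = np.asarray(score, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC needs both classes present")
    u = sps.mannwhitneyu(score[labels == 1], score[labels == 0],
                         alternative="two-sided", method="asymptotic").statistic
    auc = float(u) / (n1 * n0)
    fpr, tpr, thr = roc_curve(labels, score)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return auc, curve
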