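"""Regulator-level descriptive statistics.

Mutation and CNV frequency summaries, tumor-vs-normal (or any two-group)
expression comparison with BH-starred Wilcoxon tests, the regulator
correlation network annotated with prognostic roles, and Cox-table
summarization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CNVCallTable, ExpressionMatrix, MutationTable
from .stats import bh_adjust, rank_sum_test

logger = logging.getLogger(__name__)

__all__ = [
    "FrequencyTable",
    "CoxTable",
    "NetworkTable",
    "mutation_frequencies",
    "cnv_frequencies",
    "two_group_expression_test",
    "regulator_network",
    "summarize_cox_table",
    "star_code",
]


@dataclass
class FrequencyTable:
    """Per-gene alteration frequencies plus the overall altered fraction."""

    per_gene: pd.DataFrame       # gene_id, n_altered, n_total, frequency, ...
    n_samples_altered: int
    n_samples: int

    @property
    def overall_fraction(self) -> float:
        return self.n_samples_altered / self.n_samples if self.n_samples else 0.0


@dataclass
class CoxTable:
    """Univariate Cox summary rows per gene with the alpha used downstream."""

    rows: pd.DataFrame           # gene, hazard_ratio, ci_low, ci_high, p_value
    alpha: float = 0.05

    def __post_init__(self) -> None:
        r = self.rows
        bad = (r["ci_low"] > r["hazard_ratio"]) | (r["hazard_ratio"] > r["ci_high"])
        if bad.any():
            raise ValueError(f"CI does not bracket HR for {list(r.loc[bad, 'gene'])[:5]}")
        if ((r["p_value"] < 0) | (r["p_value"] > 1)).any():
            raise ValueError("p values outside [0, 1]")


@dataclass
class NetworkTable:
    """Correlation edges between regulators plus node prognostic roles."""

    edges: pd.DataFrame          # gene_a, gene_b, r, p, q, sign
    nodes: pd.DataFrame          # gene, role in {risk, protective, ns}, category


def star_code(p: np.ndarray) -> list[str]:
    """Significance stars at 0.05 / 0.01 / 0.001 / 0.0001."""
    out = []
    for v in np.asarray(p, dtype=float):
        if v < 0.0001:
            out.append("****")
        elif v < 0.001:
            out.append("***")
        elif v < 0.01:
            out.append("**")
        elif v < 0.05:
            out.append("*")
        else:
            out.append("ns")
    return out


def mutation_frequencies(
    mut: MutationTable, all_samples: list[str], genes: list[str]
) -> FrequencyTable:
    """Fraction of samples carrying >= 1 mutation per gene.

    The denominator is every assayed sample (mutated or not); a sample with
    several records in one gene counts once.  The most frequent variant
    classification per gene is reported alongside.
    """
    if not genes:
        raise ValueError("empty gene list")
    if not all_samples:
        raise ValueError("empty sample list")
    n_total = len(all_samples)
    sample_set = set(all_samples)
    rec = mut.records[mut.records["sample_id"].isin(sample_set)
                      & mut.records["gene_id"].isin(genes)]
    rows = []
    for g in genes:
        sub = rec[rec["gene_id"] == g]
        carriers = sub["sample_id"].nunique()
        top_class = (sub["variant_classification"].mode().iloc[0]
                     if len(sub) else "")
        rows.append({"gene_id": g, "n_altered": int(carriers), "n_total": n_total,
                     "frequency": carriers / n_total, "top_classification": top_class})
    altered_any = rec["sample_id"].nunique()
    return FrequencyTable(pd.DataFrame(rows), int(altered_any), n_total)


def cnv_frequencies(cnv: CNVCallTable) -> FrequencyTable:
    """Per-gene gain and loss frequencies among samples with any call."""
    if len(cnv) == 0:
        raise ValueError("empty CNV table")
    rec = cnv.records
    rows = []
    for g, sub in rec.groupby("gene_id", sort=True):
        n = len(sub)
        n_gain = int((sub["call"] == "gain").sum())
        n_loss = int((sub["call"] == "loss").sum())
        rows.append({"gene_id": g, "n_total": n,
                     "n_gain": n_gain, "gain_frequency": n_gain / n,
                     "n_loss": n_loss, "loss_frequency": n_loss / n,
                     "n_altered": n_gain + n_loss,
                     "frequency": (n_gain + n_loss) / n})
    altered = rec[rec["call"] != "neutral"]["sample_id"].nunique()
    return FrequencyTable(pd.DataFrame(rows), int(altered),
                          int(rec["sample_id"].nunique()))


def two_group_expression_test(
    expr: ExpressionMatrix, labels: pd.Series
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum between two sample groups.

    Returns (gene, median_diff, p, adj_p, stars); stars follow the
    ns/*/**/***/**** convention on BH-adjusted p.
    """
    labels = pd.Series(labels).reindex(expr.sample_ids)
    if labels.isna().any():
        raise ValueError("labels do not cover all samples")
    groups = list(pd.unique(labels))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    m1 = (labels == groups[0]).to_numpy()
    m2 = (labels == groups[1]).to_numpy()
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each group needs >= 2 samples")
    X = expr.values.to_numpy(dtype=float)
    rows = []
    for gi, g in enumerate(expr.gene_ids):
        x, y = X[gi, m1], X[gi, m2]
        res = rank_sum_test(x, y)
        rows.append({"gene": g,
                     "median_diff": float(np.median(y) - np.median(x)),
                     "p": res.p})
    table = pd.DataFrame(rows)
    table["adj_p"] = bh_adjust(table["p"].to_numpy())
    table["stars"] = star_code(table["adj_p"].to_numpy())
    return table


def regulator_network(
    expr: ExpressionMatrix,
    cox: CoxTable,
    r_threshold: float = 0.3,
    roles: dict[str, str] | None = None,
    method: str = "spearman",
) -> NetworkTable:
    """Pairwise regulator co-expression network with prognostic annotation.

    Edges keep pairs with |r| >= r_threshold and BH-adjusted correlation
    p < 0.05; nodes are 'risk' (HR > 1, p < alpha), 'protective'
    (HR < 1, p < alpha) or 'ns' from the Cox table.
    """
    genes = [g for g in expr.gene_ids]
    missing = set(genes) - set(cox.rows["gene"])
    if missing:
        raise ValueError(f"Cox table does not cover genes: {sorted(missing)[:5]}")
    X = expr.values.to_numpy(dtype=float)
    keep = []
    for gi, g in enumerate(genes):
        if np.ptp(X[gi]) == 0:
            logger.warning("regulator_network: constant gene %s skipped", g)
        else:
            keep.append(gi)
    corr_fn = sps.spearmanr if method == "spearman" else sps.pearsonr
    pairs = []
    for a_i in range(len(keep)):
        for b_i in range(a_i + 1, len(keep)):
            gi, gj = keep[a_i], keep[b_i]
            r, p = corr_fn(X[gi], X[gj])
            pairs.append({"gene_a": genes[gi], "gene_b": genes[gj],
                          "r": float(r), "p": float(p)})
    edges = pd.DataFrame(pairs)
    if len(edges):
        edges["q"] = bh_adjust(edges["p"].to_numpy())
        edges["sign"] = np.where(edges["r"] >= 0, "positive", "negative")
        edges = edges[(edges["r"].abs() >= r_threshold) & (edges["q"] < 0.05)]
        edges = edges.reset_index(drop=True)
    cox_idx = cox.rows.set_index("gene")
    node_rows = []
    for g in genes:
        hr = cox_idx.loc[g, "hazard_ratio"]
        p = cox_idx.loc[g, "p_value"]
        if p < cox.alpha:
            role = "risk" if hr > 1 else "protective"
        else:
            role = "ns"
        node_rows.append({"gene": g, "role": role,
                          "category": (roles or {}).get(g, "")})
    return NetworkTable(edges, pd.DataFrame(node_rows))


def summarize_cox_table(
    cox: CoxTable, alpha: float = 0.05
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Rows with p < alpha, partitioned into risk (HR>1) / protective (HR<1).

    Rows are returned ordered by p ascending (deterministic).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    sig = cox.rows[cox.rows["p_value"] < alpha].sort_values(
        "p_value", kind="stable").reset_index(drop=True)
    risk = list(sig.loc[sig["hazard_ratio"] > 1, "gene"])
    protective = list(sig.loc[sig["hazard_ratio"] < 1, "gene"])
    return sig, risk, protective
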