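"""End-to-end orchestration: simulate/load -> correct -> landscape ->
cluster -> enrich -> signature -> survival associations.

A :class:`PipelineConfig` (YAML or dict) names either real input files or a
simulation block — never both — plus stage parameters and a mandatory seed.
Every stage writes TSV outputs; a JSON run manifest records parameters,
seed and the SHA-256 checksum of every file, so a rerun with the same
config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .cluster import consensus_cluster, orient_cluster_names, pca_embed, select_k
from .enrichment import score_gene_sets
from .io import (
    ClinicalTable,
    ExpressionMatrix,
    harmonize_samples,
    read_clinical,
    read_expression,
    read_gmt,
    read_maf,
    read_cnv,
    write_expression,
)
from .landscape import (
    CoxTable,
    cnv_frequencies,
    mutation_frequencies,
    regulator_network,
    summarize_cox_table,
    two_group_expression_test,
)
from .preprocess import combat_adjust, merge_cohorts
from .signature import M6aScoreModel
from .stats import cox_fit, fisher_exact, km_estimate, logrank_test, rank_sum_test, roc_auc
from .synthetic import SimulationConfig, default_signature_gmt, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (exactly one data source)."""

    seed: int
    out_dir: str
    simulation: dict | None = None
    inputs: dict | None = None               # expression: [paths], cohort_names, clinical, gmt, maf, cnv
    k_range: tuple[int, int] = (2, 6)
    reps: int = 1000
    subsample: float = 0.8
    de_adj_p: float = 0.05
    de_lfc: float = 0.5
    alpha_surv: float = 0.05
    n_trees: int = 500
    score_mode: str = "sum"
    enrich_method: str = "ssgsea"
    tide_responder_threshold: float = 0.0
    regulator_panel: list[str] = field(default_factory=datasets.regulator_panel)

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("config must name exactly one of simulation or inputs")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None,
                  out_dir: str | None = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if seed is not None:
            raw["seed"] = seed
        if out_dir is not None:
            raw["out_dir"] = out_dir
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kwargs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            "k_range": list(config.k_range), "reps": config.reps,
            "subsample": config.subsample, "de_adj_p": config.de_adj_p,
            "de_lfc": config.de_lfc, "alpha_surv": config.alpha_surv,
            "n_trees": config.n_trees, "score_mode": config.score_mode,
            "enrich_method": config.enrich_method,
        },
        "stages": [],
        "complete": False,
    }
    stage = "setup"
    try:
        # -- data acquisition -------------------------------------------------
        stage = "acquire"
        if config.simulation is not None:
            sim_cfg = SimulationConfig(**{**config.simulation, "seed": config.seed})
            cohort = simulate_cohort(sim_cfg)
            expr, clinical = cohort.expression, cohort.clinical
            mutations, cnv = cohort.mutations, cohort.cnv
            gene_sets = default_signature_gmt(sim_cfg)
            truth_path = out / "truth.json"
            truth_path.write_text(json.dumps({
                "cluster": {s: int(c) for s, c in cohort.cluster_labels.items()},
                "beta_cluster": cohort.truth["beta_cluster"],
                "batch": cohort.truth["batch"],
            }, indent=0, sort_keys=True))
        else:
            inp = config.inputs
            mats = [read_expression(p) for p in inp["expression"]]
            names = list(inp.get("cohort_names",
                                 [f"COHORT{i+1}" for i in range(len(mats))]))
            if len(mats) > 1:
                expr = merge_cohorts(mats, names)
            else:
                expr = mats[0]
            clinical = read_clinical(inp["clinical"])
            expr, clinical = harmonize_samples(expr, clinical)
            mutations = read_maf(inp["maf"]) if inp.get("maf") else None
            cnv = read_cnv(inp["cnv"]) if inp.get("cnv") else None
            gene_sets = read_gmt(inp["gmt"]) if inp.get("gmt") else None
        manifest["stages"].append(stage)

        # -- batch correction --------------------------------------------------
        stage = "preprocess"
        if expr.batch is not None and expr.batch.nunique() > 1:
            expr, _batch_model = combat_adjust(expr)
        write_expression(expr, out / "expression_corrected.tsv")
        manifest["stages"].append(stage)

        panel = [g for g in config.regulator_panel if g in expr.gene_ids]
        if len(panel) < 2:
            raise ValueError("fewer than 2 regulator-panel genes in the matrix")
        reg_expr = expr.subset_genes(panel)

        # -- landscape ---------------------------------------------------------
        stage = "landscape"
        if mutations is not None and len(mutations):
            freq = mutation_frequencies(mutations, expr.sample_ids,
                                        sorted(mutations.records["gene_id"].unique()))
            _write(freq.per_gene, out / "mutation_freq.tsv", index=False)
        if cnv is not None and len(cnv):
            cfreq = cnv_frequencies(cnv)
            _write(cfreq.per_gene, out / "cnv_freq.tsv", index=False)
        clin = clinical.aligned_to(expr.sample_ids).df
        cox_rows = []
        for g in panel:
            try:
                fit = cox_fit(clin["os_time"].to_numpy(), clin["os_event"].to_numpy(),
                              pd.DataFrame({g: reg_expr.values.loc[g].to_numpy()}))
                row = fit.summary.loc[g]
                cox_rows.append({"gene": g, "hazard_ratio": row["hr"],
                                 "ci_low": row["ci_low"], "ci_high": row["ci_high"],
                                 "p_value": row["p"]})
            except ValueError:
                logger.warning("landscape: Cox fit failed for %s", g)
        cox_table = CoxTable(pd.DataFrame(cox_rows), alpha=0.05)
        _write(cox_table.rows, out / "regulator_cox.tsv", index=False)
        sig, _risk, _prot = summarize_cox_table(cox_table, 0.05)
        _write(sig, out / "regulator_cox_significant.tsv", index=False)
        net = regulator_network(reg_expr, cox_table,
                                roles=datasets.regulator_categories())
        _write(net.edges, out / "network_edges.tsv", index=False)
        _write(net.nodes, out / "network_nodes.tsv", index=False)
        manifest["stages"].append(stage)

        # -- consensus clustering ---------------------------------------------
        stage = "cluster"
        kmin, kmax = config.k_range
        result = consensus_cluster(reg_expr, range(kmin, kmax + 1),
                                   reps=config.reps, subsample=config.subsample,
                                   seed=config.seed)
        k, diagnostics = select_k(result)
        labels_int = result.labels_series(k)
        labels = orient_cluster_names(labels_int, clinical)
        labels.name = "m6a_cluster"
        labels.to_frame().to_csv(out / "labels.tsv", sep="\t", index_label="sample_id")
        coords = pca_embed(reg_expr, 2)
        _write(coords.coords.round(6), out / "pca.tsv", index_label="sample_id")
        (out / "diagnostics.json").write_text(json.dumps(
            {"chosen_k": k, **{kk: vv for kk, vv in diagnostics.items()}},
            indent=0, sort_keys=True, default=float))
        lr = logrank_test(clin["os_time"].to_numpy(), clin["os_event"].to_numpy(),
                          labels.to_numpy())
        manifest["cluster_logrank_p"] = lr.p
        de_reg = two_group_expression_test(reg_expr, labels) if k == 2 else None
        if de_reg is not None:
            _write(de_reg, out / "de_regulators.tsv", index=False)
        manifest["stages"].append(stage)

        # -- enrichment --------------------------------------------------------
        stage = "enrich"
        score_mat = None
        if gene_sets is not None and len(gene_sets):
            score_mat = score_gene_sets(expr, gene_sets, method=config.enrich_method)
            _write(score_mat.values.round(8), out / "enrichment_scores.tsv",
                   index_label="set_name")
        manifest["stages"].append(stage)

        # -- signature ---------------------------------------------------------
        stage = "signature"
        model = M6aScoreModel(expr, labels, clinical,
                              de_adj_p=config.de_adj_p, de_lfc=config.de_lfc,
                              alpha_surv=config.alpha_surv, n_trees=config.n_trees,
                              score_mode=config.score_mode)
        res = model.fit(seed=config.seed)
        _write(res.de_table.round(10), out / "degs.tsv", index=False)
        _write(res.importance.round(10), out / "rf_importance.tsv", index=False)
        (out / "signature_model.json").write_text(json.dumps({
            "X": res.model.X, "Y": res.model.Y,
            "betas": {r["gene"]: round(r["beta"], 10)
                      for _, r in res.model.genes.iterrows()},
            "scale_mean": round(res.model.scale_mean, 10),
            "scale_sd": round(res.model.scale_sd, 10),
            "median": round(res.model.median, 10),
        }, indent=0, sort_keys=True))
        scores_df = pd.DataFrame({"m6a_score": res.scores.round(10),
                                  "score_group": res.groups})
        scores_df.to_csv(out / "scores.tsv", sep="\t", index_label="sample_id")
        manifest["stages"].append(stage)

        # -- survival and associations ----------------------------------------
        stage = "survival"
        contrast = res.survival_contrast()
        manifest["score_logrank_p"] = contrast["logrank_p"]
        manifest["score_hr"] = contrast["hr"]
        km_rows = []
        for grp, km in res.km_curves().items():
            for t, s, r in zip(km.times, km.survival, km.n_at_risk):
                km_rows.append({"group": grp, "time": t, "survival": s, "n_at_risk": r})
        _write(pd.DataFrame(km_rows), out / "km_highlow.tsv", index=False)
        assoc: dict = dict(contrast)
        groups = res.groups
        if "tide_score" in clin.columns:
            tide = clin.set_index("sample_id")["tide_score"].reindex(groups.index)
            hi, lo = tide[groups == "high"], tide[groups == "low"]
            assoc["tide_wilcoxon_p"] = rank_sum_test(hi, lo).p
            responder = (tide < config.tide_responder_threshold).astype(int)
            auc, curve = roc_auc(res.scores.to_numpy(), responder.to_numpy())
            assoc["tide_auc"] = auc
            _write(curve.round(8), out / "roc_curve.tsv", index=False)
        for col in ("kras_mut", "tp53_mut"):
            if col in clin.columns:
                v = clin.set_index("sample_id")[col].reindex(groups.index)
                table = np.array([
                    [int(((groups == "high") & (v == 1)).sum()),
                     int(((groups == "high") & (v == 0)).sum())],
                    [int(((groups == "low") & (v == 1)).sum()),
                     int(((groups == "low") & (v == 0)).sum())],
                ])
                assoc[f"{col}_fisher_p"] = fisher_exact(table).p
        if score_mat is not None:
            from .stats import correlate
            corr = correlate(res.scores.to_numpy(),
                             score_mat.values.T, method="pearson")
            _write(corr.round(8), out / "score_pathway_corr.tsv", index=False)
        (out / "associations.json").write_text(
            json.dumps({k2: (round(v, 10) if isinstance(v, float) else v)
                        for k2, v in assoc.items()}, indent=0, sort_keys=True))
        manifest["stages"].append(stage)
        manifest["complete"] = True
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=0,
                                                      sort_keys=True, default=float))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["checksums"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=0,
                                                  sort_keys=True, default=float))
    return manifest
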