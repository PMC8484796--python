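# m6ascape

Expression-defined **m6A modification patterns** and the **m6Ascore**
prognostic signature for pancreatic-cancer transcriptomics.

N6-methyladenosine (m6A) is the most abundant internal mRNA modification;
it is deposited, removed and read by a panel of 21 regulator genes
(writers such as METTL3/METTL14/WTAP/KIAA1429, erasers FTO/ALKBH5, and
readers including the YTHDF/YTHDC families, HNRNPC, IGF2BP1, ELAVL1).
Tumours differ systematically in how this machinery is expressed, and those
differences track survival and the immune microenvironment.  `m6ascape`
implements the full analysis a translational group would run on bulk
expression cohorts:

1. **Cohort merging and batch correction** — empirical-Bayes location/scale
   adjustment (ComBat-style) of the gene × sample matrix across cohorts.
2. **Regulator landscape** — mutation and CNV frequencies, tumour-vs-normal
   Wilcoxon comparisons, a prognosis-annotated co-expression network, and
   univariate Cox summaries for the 21-gene panel.
3. **Modification-pattern discovery** — resampling consensus clustering
   (Ward/Euclidean, 1,000 reps by default) of samples on the regulator
   panel, with PAC-based selection of the number of clusters k and PCA
   validation.
4. **Single-sample enrichment** — ssGSEA (rank-weighted running-ECDF
   difference) and a GSVA-style kernel-CDF variant for immune-cell and
   pathway activity, plus hypergeometric over-representation for DEG → KEGG.
5. **The m6Ascore** — moderated-t DEGs between patterns, random-forest
   out-of-bag mean-decrease-accuracy redundancy removal, a per-gene Cox
   survival filter, partition of surviving genes by coefficient sign into
   sets X (risk) and Y (protective), and the per-sample score

   ```
   m6Ascore_j = scale( Σ_{g∈X} e_gj − Σ_{g∈Y} e_gj )
   ```

   with the cohort median splitting samples into high/low groups.
6. **Downstream statistics** — Kaplan–Meier/log-rank, uni/multivariate Cox
   (Efron ties), rank-sum and Fisher tests, Benjamini–Hochberg control,
   score–pathway correlation and ROC/AUC against externally supplied TIDE
   immunotherapy-response scores.

Because the original cohorts (TCGA PAAD, ICGC PACA, GEO) require large or
controlled downloads, the package ships a fully specified **synthetic-cohort
generator** that plants the structure every stage assumes — two latent
regulator clusters, cohort batch effects, cluster-linked proportional-hazards
survival, pathway activations, and per-gene mutation/CNV frequencies — so
the entire pipeline is testable offline and every claim in the test suite is
checked against ground truth.

## Worked example

```python
from m6ascape import (SimulationConfig, simulate_cohort, combat_adjust,
                      consensus_cluster, select_k, M6aScoreModel)
from m6ascape.cluster import orient_cluster_names
from m6ascape.datasets import regulator_panel

cohort = simulate_cohort(SimulationConfig(n_samples=100, seed=42))
corrected, _ = combat_adjust(cohort.expression)
regs = corrected.subset_genes(regulator_panel())

consensus = consensus_cluster(regs, range(2, 5), reps=100, seed=42)
k, diag = select_k(consensus)
clusters = orient_cluster_names(consensus.labels_series(k), cohort.clinical)
print("chosen k:", k, " PAC:", {kk: round(v, 3) for kk, v in diag["pac"].items()})

results = M6aScoreModel(corrected, clusters, cohort.clinical, n_trees=200).fit(seed=42)
print(results.summary().head(4).round(4).to_string(index=False))
contrast = results.survival_contrast()
print("high vs low m6Ascore: HR = %.2f (%.2f-%.2f), log-rank p = %.2g"
      % (contrast["hr"], *contrast["hr_ci"], contrast["logrank_p"]))
```

prints

```
chosen k: 2  PAC: {2: 0.0, 3: 0.409, 4: 0.455}
     gene      set  importance   beta     hr      p
HNRNPA2B1 X (risk)      0.0440 0.1311 1.1401 0.0233
     WTAP X (risk)      0.0322 0.1755 1.1919 0.0025
   YTHDF1 X (risk)      0.0299 0.2074 1.2304 0.0004
   YTHDC2 X (risk)      0.0251 0.1720 1.1877 0.0018
high vs low m6Ascore: HR = 2.02 (1.41-2.89), log-rank p = 9.1e-05
```

PAC (proportion of ambiguous consensus entries) is 0 at k = 2: the two
planted modification patterns are perfectly resampling-stable.  The fitted
signature's `summary()` lists each selected gene with its random-forest
importance and univariate Cox statistics; genes with β > 0 enter set X.
The median split of the resulting score recovers the planted doubled hazard
(true HR = 2) with HR = 2.02.

The same pipeline runs from the shell:

```bash
m6ascape run-all --config configs/demo.yaml --out demo_out
```

which writes per-stage TSVs (labels, enrichment scores, DEGs, signature
model, KM curves, associations) plus a `manifest.json` whose checksums are
byte-identical across reruns with the same config and seed.

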