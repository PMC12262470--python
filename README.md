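# nephrosig

Cell-type-resolved signatures of drug-induced nephrotoxicity.

Drug-induced acute kidney injury is hard to predict partly because the
transcriptional response to a nephrotoxic drug may be confined to a small
kidney cell subpopulation. Bulk RNA-seq averages over the kidney's cellular
heterogeneity, so a perturbation restricted to, say, a 2.6%-prevalence
stromal compartment is diluted ~40-fold before any per-gene test sees it.
`nephrosig` is a tested, reusable pipeline for studying exactly this
problem on fully synthetic data:

1. **Synthetic data** — annotated kidney-like scRNA-seq count matrices
   (negative binomial with dropout; 4 abstract cell types — Nephron 82.4%,
   Endothelium 7.8%, Immune 7.1%, Stroma 2.6% — partitioned into 32
   detailed subtypes; multi-donor replicate structure) and drug→target→
   toxicity databases (215 nephrotoxic : 641 non-nephrotoxic by default)
   in which the toxicity label can be coupled to marker genes of
   "susceptible" cell types with controllable strength.
2. **Preprocessing** — cell QC (UMI ≥ 500, genes ≥ 250,
   log₁₀ genes/log₁₀ UMI > 0.85), gene QC (detected in ≥ 10 cells),
   LogNormalize, and VST-based highly variable gene ranking.
3. **Power simulation** — subsample 10% of cells preserving prevalences,
   multiply the expression of a response-rate fraction of one cell type's
   cells by (1 + effect), pseudo-bulk to donor-level profiles, and run
   per-gene Welch t-tests at p < 2.5×10⁻⁶ (0.05 Bonferroni over 20,000
   genes). Power = significant genes / total genes. A cell-level mode
   quantifies what the pseudo-bulk averaging destroys.
4. **Drug scoring** — drug2cell-style composite: score(cell, drug) = mean
   log-normalized expression of the drug's target genes in that cell,
   natural-log transformed, then averaged per cell type.
5. **Signatures** — per cell type, Welch t-test of mean logged scores,
   nephrotoxic vs non-nephrotoxic drugs; logFC = difference of group means
   (so FC = e^logFC), exponentiated t-based 95% CI, Benjamini–Hochberg
   correction within each abstraction level.
6. **Classification** — drug toxicity from cell-type score features
   (logistic regression, SVM, random forest, extra trees, gradient
   boosting, XGBoost, a soft-voting ensemble, and an MLP) under stratified
   5-fold cross-validation with bootstrap AUROC CIs.
7. **Bulk arm** — LINCS-style replicate collapsing and per-gene toxic vs
   non-toxic differential expression with BH FDR.

## Worked example

Embed a toxicity signal in the Stroma compartment and recover it:

```python
import nephrosig as ns

specs = ns.abstract_cell_type_specs(2000)
cfg = ns.SyntheticConfig(n_cells=1500, n_genes=2000, n_donors=6,
                         target_sparsity=0.9, seed=42, cell_type_specs=specs)
adata = ns.generate_cell_matrix(cfg)
qc = ns.QCThresholds(min_umi=60, min_genes_per_cell=30,
                     min_log10_genes_per_umi=0.5, min_cells_per_gene=5)
lognorm = ns.log_normalize(ns.qc_filter(adata, qc))

db = ns.generate_drug_db(
    215, 641, ns.SignalSpec(frozenset({"Stroma"}), 0.6),
    ns.gene_universe(2000), seed=43, cell_type_specs=specs)
T, ids, tox = ns.build_target_matrix(db, list(lognorm.var_names))
scores = ns.log_transform_scores(ns.score_cells(lognorm, T, ids, tox))
table = ns.aggregate_by_cell_type(scores, "abstract4")

for r in ns.compare_groups(table):
    print(f"{r.cell_type:<12} t={r.t_statistic:+6.2f} FC={r.fold_change:5.3f} "
          f"p={r.p_value:.2e} q={r.corrected_p:.2e}")

feats = ns.build_feature_table(table, "abstract4")
rep = ns.cross_validate(feats, "extra_trees", k=5, seed=7)
print(f"extra_trees AUROC={rep.auroc:.3f} "
      f"(95% CI {rep.auroc_ci_lower:.3f}-{rep.auroc_ci_upper:.3f}), "
      f"sens={rep.sensitivity:.3f}, spec={rep.specificity:.3f}")
```

prints

```
Stroma       t=+34.52 FC=16533.008 p=1.65e-131 q=6.60e-131
Nephron      t=-10.96 FC=0.049 p=5.66e-25 q=1.13e-24
Endothelium  t=-10.83 FC=0.048 p=1.41e-24 q=1.88e-24
Immune       t=-10.14 FC=0.057 p=8.09e-22 q=8.09e-22
extra_trees AUROC=0.992 (95% CI 0.983-0.997), sens=0.949, spec=0.975
```

The susceptible type (Stroma) dominates by |t|: nephrotoxic drugs, whose
targets are enriched for Stroma marker genes, score far higher in Stroma
cells than non-nephrotoxic drugs do. The extreme fold change is a property
of the synthetic data: many non-toxic drugs have near-zero raw scores in
Stroma, which the ε = 10⁻⁹ pseudocount maps to a deep negative floor on
the log scale (see `docs/methods.md`). The classifier separates the
classes almost perfectly because, at enrichment 0.6, the Stroma feature
alone carries most of the label information.

The same stages are available from the shell:

```bash
nephrosig simulate-data --out run/ --seed 3
nephrosig score --in run/matrix --drugs run/drugs.csv --level detailed32 --out run/scores.tsv
nephrosig signatures --scores run/scores.tsv --out run/signatures.tsv
nephrosig classify --scores run/scores.tsv --level detailed32 --out run/eval.tsv
nephrosig run --config cfg.yaml       # full pipeline with manifest
```

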