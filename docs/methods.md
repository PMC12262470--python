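# Methods

This note documents the models, defaults, and numerical choices behind
`nephrosig`, and what the synthetic data can and cannot show about real
kidney scRNA-seq.

## Synthetic single-cell model

**Cell-type hierarchy.** Four abstract kidney compartments at fixed
prevalences — Nephron 0.824, Endothelium 0.078, Immune 0.071, Stroma 0.026
(renormalized to sum to 1; the published fractions sum to 0.999) —
partitioned into 32 detailed subtypes with kidney-atlas-style names. Within
a compartment, subtype prevalences decay geometrically (ratio 0.8), so each
lineage has one dominant subtype and a tail of rare ones, mimicking the
skew of real annotations. Cell counts per type are multinomial.

**Counts.** Gene counts are negative binomial per gene and cell type:
`var = μ + μ²/r` with per-gene dispersion `r ~ lognormal(ln 0.35, 0.25)`
(heavy droplet-style overdispersion). Baseline gene means follow
`lognormal(ln 0.08, 1.6)` — a long-tailed distribution in which most genes
are lowly expressed, as in droplet data after gene filtering. Each detailed
type carries a disjoint block of marker genes (default 25, mean 4.0 in the
own type, 0.04 elsewhere) plus a mild lognormal(0, 0.1) type-identity
jitter on non-markers. Markers are therefore the top-expressed genes of
their type by construction, and are the pool that signal-carrying drug
databases draw from.

**Sparsity calibration.** Before sampling, the expected NB zero fraction is
computed from the mean/dispersion table. If it exceeds the target zero
fraction, all means are scaled up by a bisection-solved factor; if it falls
short, uniform multiplicative dropout tops it up. The realized zero
fraction then lands within a few points of `target_sparsity` (default
0.90) for any reasonable spec.

**Donor structure.** Cells are assigned uniformly to donors (default 24,
matching a multi-sample integrated atlas). Donor effects are a
per-(donor, gene) lognormal factor with σ = 0.3 and unit mean. A single
scalar factor per donor would cancel exactly under the per-cell total
normalization of LogNormalize and contribute no between-replicate
variance, so the factor is drawn per gene: pseudo-bulk donor profiles then
show realistic biological replicate variance (~30% CV per gene) on top of
cell-sampling noise.

**Drug databases.** Default 215 nephrotoxic and 641 non-nephrotoxic drugs.
Target-set sizes are `1 + Poisson(4)`. A `SignalSpec` couples labels to
biology: each nephrotoxic drug draws `enrichment_strength` of its targets
from the pooled markers of the designated susceptible cell types, the rest
uniformly from the gene universe; non-toxic drugs draw uniformly. At
enrichment 0 the database is exactly null (labels independent of targets);
at enrichment 1 toxic target sets are pure marker subsets and are not
backfilled from the universe, so the boundary invariant holds exactly.

**What the generator does not model.** Gene–gene co-regulation, batch
effects requiring integration, ambient RNA, doublets, or diseased-state
shifts. Passing tests therefore demonstrate correctness of the pipeline's
statistics under an idealized independence model, not performance on real
atlas data.

## Preprocessing

Cell filters (UMI ≥ 500, detected genes ≥ 250, log₁₀ genes / log₁₀ UMI
strictly > 0.85) are applied jointly on raw counts, then genes detected in
fewer than 10 surviving cells are dropped. The minimum thresholds are read
as inclusive (≥) and the complexity ratio as strict (>), both configurable.
LogNormalize maps counts to `ln(1 + c/total × 10⁴)`; zeros stay zero and
the transform is strictly monotone within a cell.

HVG ranking standardizes counts against a mean–variance trend: a lowess
(locally linear, span 0.3) fit of log₁₀ variance on log₁₀ mean over
positive-variance genes gives each gene an expected sd; standardized counts
are clipped at √N and their variance ranks the genes. This follows the
standard VST flavor; the trend smoother is locally linear rather than
locally quadratic, which does not change rankings in any case the tests
exercise. Per-gene z-scoring (`scale_genes`) is provided but downstream
drug scoring consumes log-normalized values — z-scored expression can be
negative, which would break the subsequent log transform of scores.

## Power simulation

For each (effect size, response rate, affected cell type): draw a fresh
10% prevalence-preserving stratified subsample; multiply every gene of
`floor(rate × n_type)` randomly chosen cells of the affected type (minimum
1) by `(1 + effect)`; keep the unmodified subsample as the untreated arm.
Effects are applied to log-normalized expression (configurable to raw
counts). In `pseudo_bulk` mode both arms are collapsed to per-donor,
per-gene means with cell-type annotations masked, giving n_donors
replicates per arm; in `cell_level` mode the cells themselves are the
replicates. Per-gene Welch t-tests are thresholded at p < 2.5×10⁻⁶
(0.05/20,000); degenerate genes (zero variance in both arms, e.g. all-zero
genes, which the multiplicative effect preserves) count as non-significant.
Power is the significant fraction of all genes, averaged over
`n_replicate_runs` (default 10).

Because treated and untreated arms share the same cells, unperturbed genes
differ by exactly zero — the simulation isolates the dilution question
rather than re-testing null calibration at every gene. The default effect
grid is log-spaced 0.001–10 (the Methods-stated range; a coarser 0.01–10
range appears elsewhere in the source literature) with response rates
{0.3, 0.8, 0.95}.

Under the default conditions (20,000 genes, ~90% zeros, 24 donors), power
at effect 10 and rate 0.8 is limited by expression breadth: a gene is
detectable only if consistently expressed in the affected type across
donors, and the long-tailed gene-mean distribution leaves most genes below
that bar. The worst-case (largest) power across the four abstract
mediating types — the Nephron, at 82% prevalence — stays near 40%, and
rarer compartments near zero: the central dilution result.

## Drug scoring and signatures

`score(cell, drug)` is the arithmetic mean of the cell's log-normalized
expression over the drug's measured target genes (plain composite, no
background correction). Drugs with no targets in the measured universe are
excluded with a warning. Scores are transformed as `ln(score + ε)` with
ε = 10⁻⁹ recorded in the output; the natural-log base is fixed by the
convention FC = e^logFC used throughout. Note that cells scoring exactly
zero hit the `ln ε ≈ −20.7` floor, which inflates fold changes between
groups that differ in their zero fraction — visible in sparse synthetic
data, rarely in dense real scores.

Cell-type aggregation is the mean logged score over the cells of a type,
so detailed-level aggregates combine to abstract-level ones as cell-count-
weighted means (tested identity). The per-cell-type test is a Welch
(unequal-variance) two-sample t-test with the drug as the unit of
observation — group sizes and variances are grossly unequal (≈1:3 and
worse), and "toxic vs non-toxic drug groups" is the comparison of
interest; a cell-level variant is available. logFC is the difference of
group means on the log scale; the 95% CI is the exponentiated t-based CI
of that difference. BH correction is applied within each abstraction level
(4 tests at abstract, 32 at detailed), and rows are sorted by corrected p,
ties by |t| descending.

## Classification

Features: one row per drug, columns = mean logged score per cell type
(sorted names), label = nephrotoxic. Eight families with library defaults
(no tuning): logistic regression, RBF SVM, random forest, extra trees,
gradient boosting, XGBoost, a soft-voting ensemble of those six, and an
MLP; scale-sensitive models are wrapped with standardization. Folds are
stratified (at ~25% positive prevalence unstratified folds can go
single-class); metrics are computed on pooled out-of-fold predictions with
nephrotoxic as the positive class. The AUROC 95% CI is a stratified
bootstrap (2,000 resamples within each class) of the pooled out-of-fold
scores; the point estimate is clamped into the interval in the rare
degenerate resampling cases.

## Bulk arm

Synthetic bulk profiles are z-score-like signatures with per-drug
replicates. Replicate collapsing is the per-gene mean per drug.
DE is a per-gene Welch t-test, toxic vs non-toxic samples, with log₂FC
reported as the difference of group means (the profiles are already on a
log-like signature scale; this convention is declared in the output) and
BH FDR across genes. The default selection rule is `p < 0.05 AND |log2FC|
≤ 1` — kept verbatim from the source convention even though it selects
small effects; the conventional `≥` direction is available via
`lfc_direction="ge"`.

## Problem sizes and determinism

Default study conditions: 10,000 cells × 20,000 genes, 24 donors, 90%
target sparsity, 215:641 drugs. The test suite exercises the same code
paths at reduced sizes (hundreds of cells, hundreds of genes, dozens of
drugs) chosen so that every statistical property under test has adequate
power at that scale; `scripts/acceptance.py` runs the power analysis at
the full default size. All randomness flows from explicit integer seeds
through `numpy.random.SeedSequence` spawning; identical seeds give
byte-identical outputs, and the pipeline manifest records stage seeds,
output hashes, and package versions.

## Known limitations

- Genes are independent given cell type and donor; correlated gene modules
  would make pseudo-bulk tests anti-conservative in ways this model cannot
  show.
- Marker blocks are disjoint across types; real marker genes overlap.
- The ε floor on logged scores exaggerates fold changes in very sparse
  configurations (see above).
- QC is one-pass (cells on the full gene set, then genes); a borderline
  cell could in principle fall below threshold after gene removal, though
  none of the tested configurations produce this.
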