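# Methods

## Problem and model

A transcription factor's ChIP-Seq binding profile over-calls its
regulatory targets: many bound sites are non-functional, and many
functional targets are bound weakly. `tfica` filters binding evidence
through a module decomposition of a gene expression compendium. The
modules are consumed as a gene × module loading matrix (as produced by
independent component analysis of an expression compendium); a module's
"expression" in a sample is the projection

    proj_m(s) = Σ_{g ∈ members(m)} ℓ_{gm} · x_{gs},

the dot product of member loadings with (log-scale) expression. The
chain of inference is relational: TF → module by binding-target
enrichment, module → disease by gene-set enrichment, TF → disease by
joining the two; TF ↔ TF by similarity of associated-module sets.

## Statistical procedures and defaults

**Target assignment.** A binding site maps to at most one gene: the
nearest gene on its chromosome by interval gap (zero on overlap or
abutment of the 0-based half-open intervals), provided the gap is at
most `window` = 100,000 bp. "Nearest gene" is undefined under ties, so
ties break by smaller gap, then lexicographic gene id — deterministic
and order-independent. Distance is measured boundary-to-boundary and
strand-ignored; a TSS-anchored mode is available behind `use_tss` for
users who prefer promoter-proximal logic.

**Enrichment.** All gene-set overlaps use the two-sided Fisher exact
test on the 2×2 table (a, b, c, d) against an explicit universe, with
the sample odds ratio ad/bc. The Haldane 0.5 correction is applied to
the point estimate only when the denominator bc is zero (where the raw
OR is undefined); a zero numerator is reported as OR 0, so depleted
overlaps are never inflated above 1. The 95% CI uses the normal
approximation to the log OR on cells corrected whenever any cell is
zero (otherwise the SE is infinite). Benjamini–Hochberg adjustment runs
across the full test family (all TF × module pairs jointly; a per-TF
family is selectable), and retention requires adjusted p < 0.01 and
OR > 1. The TF–module universe is the intersection of the gene-model
table with the module decomposition's gene index — the genes for which
both data sources can speak; it is a parameter wherever enrichment is
exposed.

**Confidence tiers.** Module-specificity proxies confidence: an
association is high confidence when its module is associated with
exactly one TF, medium when with at most three, low otherwise. Tiers
are recomputed from the retained set, so they partition it.

**Expression validation.** Correlations are Spearman (rank-based; the
compendium is heterogeneous, and loadings make the projection scale
arbitrary). The TF gene is removed from its module before projecting so
the factor cannot correlate with itself. Observed TF–module
correlations are z-transformed against the empirical null of *all*
TF × module correlations (mean/SD), two-sided normal p, significance at
0.05. The comparison uses |ρ| because the sign of a module (an ICA
component) is not identifiable; a signed mode exists.

**Naive baselines.** "Best" = the k highest-scoring targets; "matched"
= for each reference score, one target drawn without replacement from
the decile bin (of the TF's full target-score distribution) containing
it, with fall-back to the nearest nonempty bin. Naive sets are
summarised by unweighted mean expression. Wins (|ρ_projection| >
|ρ_naive|) are binned by the number of TFs per module and tested
against 0.5 with a one-sided binomial test, plus a paired t on r²;
bins with fewer than 3 pairs are reported as insufficient.

**TF–TF similarity.** Tanimoto |A∩B|/|A∪B| over associated-module sets.
The confidence-weighted variant is a weighted Jaccard,
Σ_{i∈A∩B} w_i / Σ_{i∈A∪B} w_i with w_i = (N − N_TFi)/N, which is
monotone-decreasing in N_TFi (modules claimed by many factors carry
little pair-specific information), reduces exactly to the simple
Tanimoto under equal counts, and stays in [0,1]; a module associated
with every TF would get weight 0 and is floored at 1/N. An alternative
w_i = 1/N_TFi is selectable. Network export keeps edges with
Tanimoto > 0.2 (threshold mode) or the top-30 pairs (top-k mode).
Validation responses (expression correlation, literature co-mentions,
shared annotation) are consumed as input columns and fit by OLS with a
nested-model F-test for the added module-based predictors.

**Disease linking.** Disease sets must exceed 5 genes (after
restriction to the universe). Module–disease significance defaults to
BH FDR 0.15, a cutoff calibrated by maximising AUROC on labeled
training associations over a candidate grid (ties to the smaller FDR);
the calibration grid search is part of the package. A TF–disease link
is the relational join through any shared significant module, scored by
the minimum supporting module–disease adjusted p (best-evidence
statistic; Fisher combination would reward many weak modules and is
deliberately not the default). Stringent links need OR > 3 and adjusted
p < 0.001; each disease without a stringent link contributes its single
best association if it meets adjusted p < 0.01 and OR > 1. AUROC uses
the trapezoidal rule with midrank ties (equals the Mann–Whitney
concordance); AUROC50 is the *unnormalised* area over FPR ∈ [0, 0.5]
(range 0–0.5), with a normalised mode available. Combining two
predictors uses logistic regression with a 1-df likelihood-ratio χ²
for the added term. Model comparisons use a stratified view of the same
LR machinery rather than a dedicated correlated-ROC variance estimator;
the two agree asymptotically for nested predictors on one dataset.

**Cohort validation.** Probe matrices collapse to genes by the median.
Differential expression uses the pooled-variance two-sample t (Welch
behind a flag); zero-variance genes are flagged and excluded from set
tests. The module-level test is a one-sided Wilcoxon rank-sum on |t| of
members vs all other usable genes (cases-higher alternative; two-sided
available). Because genes inside functional modules trend toward higher
differential expression, the module test is corrected by permutation:
the null redraws same-size gene sets from the union of all module
genes and recomputes the rank-sum statistic — implemented as the sum of
the members' midranks in the global |t| ranking, which is monotone in
the U statistic at fixed set size, so each permutation is a vectorised
index-sum rather than a fresh rank-sum test. The empirical p uses the
add-one form (1 + #{null ≥ obs})/(n_perm + 1), which is valid (never
anti-conservative) at any n_perm ≥ 100. Classifiers are z(TF
expression), z(module projection) and their sum — z-scoring makes the
combined score invariant to affine rescaling of either feature — each
fit by univariate logistic regression; perfect separation is caught,
flagged, and the AUROC still reported. Combined-vs-single comparisons
are likelihood-ratio tests of nested logistic models.

## The synthetic generator

The generator emulates the *structure* the method exploits, not any
particular platform:

- **Genome**: `n_chromosomes` × 10 Mb, `n_genes` (default 2,000)
  non-overlapping genes of 2–10 kb with random strands; intergenic
  space distributed multinomially. 0-based half-open, BED-compatible.
- **Modules**: size ~ N(30, 5²) clipped to [1, n_genes]; member
  loadings sign_m · |N(1, 0.25)| with the sign fixed per module so the
  projection has a coherent direction; exact zeros elsewhere.
  Overlapping membership arises naturally from independent sampling.
- **Truth**: a planted (tf, module, fraction) makes ⌈fraction·|m|⌉
  members true targets; every TF also receives 30 background targets
  drawn outside its planted modules (so planted overlap is exact and
  target sets are never pure modules).
- **Peaks**: every true target gets ≥ 1 peak inside the gene body
  (width 200 bp; 1 + Poisson(0.5) peaks) with score ~
  N(base + score_shift, 1), base 5, shift default 3; background peaks
  fall uniformly at `background_peak_rate` (default 5/Mb/TF) with
  scores ~ N(base, 1). Scores clip at 0.
- **Compendium**: activities ~ N(0,1) (modules × samples, default 300
  samples); expression = loadings · activities + N(0, σ²), σ default 1.
  Each planted TF's gene row is replaced by ρ·z(activity) +
  √(1−ρ²)·ε, giving expected correlation ρ (`tf_module_coupling`,
  default 0.6) with the module activity.
- **Diseases**: each configured (disease, module, fraction) yields a
  20-gene set with that fraction drawn from module members, the rest
  genome-wide (the universe is all genes, mirroring genome-wide
  association catalogues).
- **Cohort**: 50 cases + 50 controls, baseline N(0,1) per gene. The
  planted DE modules' latent activity rises in cases: each member gene
  shifts by `cohort_effect_size` (default 1.0, in within-group SD
  units) *in the direction of its loading sign*, so the projection
  shifts upward regardless of the module's arbitrary overall sign; the
  coupled TF genes shift by the same amount.

Each generator stage draws from its own stream spawned from the single
config seed, so outputs are byte-identical across runs and independent
of call order.

What the generator does **not** emulate: probe-level microarray
artifacts, batch or lab effects, correlated backgrounds between
modules, non-Gaussian expression noise, peak-width/shape variation,
linkage between neighbouring genes, or ontology structure in disease
sets. Passing parameter-recovery tests therefore demonstrates that the
statistics are implemented correctly and calibrated under their own
assumptions — not that the method overcomes real-data confounders.

## Problem sizes

Unit and property tests run at 300–4,000 genes, 5–100 modules, 20–500
samples. The null-calibration and recovery checks use the default
design (10 TFs × 20 modules × 300 samples over 2,000 genes) across 10
seeds; the naive-baseline comparison uses 100 planted TF–module pairs
over 4,000 genes. `scripts/acceptance.py` aggregates 3 planted and 3
null replicates plus one 100-pair naive comparison, all seeded from its
`--seed` argument.

## Numerical and degenerate-input choices

- BH adjustment delegates to `statsmodels` `fdr_bh` (verified against a
  literal quadratic-time step-up in the tests); NaN p-values are
  rejected rather than propagated.
- Fisher p-values come from `scipy.stats.fisher_exact` (verified
  against full hypergeometric-tail enumeration).
- Spearman correlation on a constant vector is an error, not NaN;
  callers that sweep many pairs skip such pairs and report counts.
- Degenerate score distributions collapse matched-module decile edges
  via `np.unique`; an exhausted decile falls back to the nearest
  nonempty bin (logged at debug level).
- Constant classifier scores yield AUROC 0.5 with a warning.
- Empirical-null z-transformation requires ≥ 100 null correlations and
  positive null SD.
- All ties (nearest gene, best-module ranking, top-k edges, calibration
  grid) break lexicographically or toward the smaller parameter, never
  by dict or input order.

## Known limitations

- The weighted-similarity weight (N − N_TFi)/N is one reasonable
  monotone choice; results for densely shared modules differ under the
  1/N_TFi alternative, which is why both ship.
- The TF–disease score ignores the *number* of supporting modules;
  diseases reached through many modules are not up-weighted.
- The pipeline treats the module decomposition as fixed and noiseless;
  uncertainty in the loadings is not propagated.
- Enrichment assumes exchangeable genes within the universe; gene
  length, GC and expression-level biases present in real ChIP-Seq and
  disease catalogues are out of scope.
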