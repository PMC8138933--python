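# micromed

Integration toolkit for gnotobiotic diet-by-microbiome studies: compositional
preprocessing, diversity and ordination statistics, co-abundance module
detection, zero-sum sparse log-contrast association with stability selection,
and causal mediation analysis of microbiome and omics mediators.

## The scientific problem

Germ-free mice colonized with two distinct human fecal communities (SubA,
SubB) and fed four isocaloric diets differing only in fiber type (cellulose
C, inulin I, pectin P, assorted fiber Af) develop divergent metabolic
phenotypes (adiposity, liver triglycerides, serum glucose). Connecting the
transplanted community to those phenotypes runs through several statistical
layers, all implemented here for users analysing samples-by-taxa count
tables with a taxonomy tree, plus metabolite/expression matrices:

* **Compositional preprocessing** — genus aggregation of ASV tables,
  prevalence filtering ("fewer than 20% of samples" rule), zero replacement
  by the 0.5 rounding-error convention, rank-based inverse-normal transform
  (Blom offset, Shapiro–Wilk screen), voom-style log2-CPM, MAD-based feature
  selection.
* **Diversity** — rarefaction, Shannon (bits) and Faith PD, Bray–Curtis /
  Jaccard / unweighted and weighted (normalized) UniFrac, PCoA, PERMANOVA
  with seeded permutations.
* **Co-abundance modules** — unsigned weighted correlation networks
  (|cor|^β with the scale-free soft-power rule), topological overlap,
  a deterministic dynamic-tree-cut variant, module eigenvalues
  (eigengenes), module–trait Pearson correlations with BH FDR, and one-sided
  Fisher pathway enrichment.
* **Taxa–omics association** — the sparse linear log-contrast model

      minimize (1/2n) ‖y − β₀ − Zβ‖² + λ‖β‖₁   subject to  Σⱼ βⱼ = 0,

  where Z holds log relative abundances. The zero-sum constraint makes the
  fit invariant to compositional rescaling and avoids an arbitrary reference
  taxon. λ is chosen by 10-fold cross-validation; selection probabilities
  come from 100 bootstrap resamples (`bcv_prob`) and 100 half-size
  subsamples (`stab_prob`, stability selection); the association network
  keeps taxa with `stab_prob > 0.85` and an unpenalized constrained refit
  coefficient of at least 0.1 in absolute value.
* **Mediation** — with community as binary exposure, phenotype as outcome
  and batch as confounder: a distance-based test on beta-diversity matrices
  (eigenvalue-weighted exposure→axis→outcome correlation products with a
  row-permutation null), a taxonomy-tree scan fitting a multivariate linear
  mediation model to each high-rank node's ALR-transformed subcomposition,
  and module-based mediation through eigengenes (bootstrap indirect-effect
  inference).
* **Host statistics** — permutation Wilcoxon rank-sum (exact enumeration
  when feasible), Levene's test, two-way Type II ANOVA, Pearson correlation,
  Benjamini–Hochberg adjustment.

A first-class synthetic-data module (`micromed.synthdata`) generates seeded
datasets with the full study structure — taxonomy tree, community-exclusive
core genera, diet-responsive taxa, logistic-normal compositional noise at
variable sequencing depth, planted mediating clades, latent-factor omics
blocks, and phenotypes with planted taxa-mediated paths — together with a
ground-truth record for recovery tests.

## Worked example

```python
from micromed import synthdata as sd, preprocess as pp, logcontrast as lc
import numpy as np

design = sd.StudyDesign(n_per_cell=8, seed=0)      # 2 communities x 4 diets
tree = sd.make_taxonomy(45, 25, seed=1)            # 45 genera, 25 families
counts, meta, truth = sd.sample_counts(design, tree, seed=11)

rel = pp.zero_replace(pp.prevalence_filter(counts, 0.2))
beta = np.zeros(rel.shape[1]); beta[[3, 9]] = [1.0, -1.0]
y, _ = sd.make_phenotypes(counts, meta, beta, mediation_strength=1.0,
                          noise_sd=0.5, seed=2)

prob = lc.LogContrastProblem.from_relative_abundance(rel, y)
stab = lc.stability_selection(prob, B=100, seed=0)
print(lc.refit_and_filter(prob, stab).query("in_network"))
```

prints the two planted genera and nothing else:

```
        stab_prob  refitted_coef  in_support  in_network
taxon
g__G31        1.0       1.200914        True        True
g__G43        1.0      -1.200914        True        True
```

`stab_prob` is the fraction of 100 half-size subsamples in which the genus
was selected by the cross-validated log-contrast lasso; `refitted_coef` is
its coefficient in the unpenalized zero-sum refit on the stable support
(coefficients sum to zero across selected taxa); `in_network` applies the
`stab_prob > 0.85` and `|coef| ≥ 0.1` filters used for the association
network.

The full chain — simulate → preprocess → diversity → modules → associate →
mediate → report — is one call:

```python
from micromed.pipeline import run_study
results = run_study(seed=3, out_dir="report/")
```

A thin CLI exposes the generator and phenotype statistics:

```bash
micromed simulate --out data/ --seed 7
micromed hoststats --pheno data/phenotypes.tsv --n-perm 9999
```

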