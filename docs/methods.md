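# Methods

This note documents the statistical models, the synthetic-data generator,
and the numerical and design choices behind `micromed`.

## Study design abstraction

All analyses assume a factorial gnotobiotic design: two transplanted
communities (SubA, SubB) crossed with four fiber diets (C, I, P, Af), with a
handful of mice per cell and a batch label per mouse. Community is the
exposure of interest, diet a second factor, batch a nuisance confounder.
Exposure coding is SubA = 0, SubB = 1 throughout; batch enters every
mediation model as a dummy-coded categorical covariate.

## Synthetic data generator

`synthdata` produces datasets with the statistical structure the downstream
methods assume, not raw sequencing reads.

**Taxonomy.** A rooted five-rank tree (phylum → genus). For a 45-genus,
25-family tree the intermediate rank sizes are chosen to mimic a real
genus-level 16S survey (about 5 phyla and 11 classes/orders); children are
assigned to parents by a random surjection so no rank level is empty.
Branch lengths are uniform on [0.2, 1].

**Counts.** Per sample, a logistic-normal composition: a shared log-baseline
(sd 1.5), a community-specific shift (sd 0.5 by default), diet log-fold
effects on a designated 25% of shared "responder" taxa, and sample noise
composed of three latent factors (loadings sd 0.4) plus independent noise
(sd 0.6). The latent factors induce taxa covariance — deliberately, because
the association and mediation methods assume correlated taxa; a Dirichlet
model would make taxa quasi-independent. 30% of taxa are
community-exclusive (structural zeros in the other community), mirroring
genera detected in only one community. Counts are multinomial draws at a
uniform-random depth in [5,000, 40,000], straddling typical rarefaction
depths so the rarefaction code is genuinely exercised.

**Planted effects.** `mediating_family` plants an exposure → clade path: the
first genus of the chosen family gains `family_shift` (default 1.5) log
units in SubB and the second loses the same amount, so the family's internal
log-ratio carries the community signal while higher-rank subcompositions are
nearly unaffected — the property the tree-scan localization test relies on.
Phenotypes are community effect + diet effects + batch shifts +
`mediation_strength` × (log relative abundance · β_true) + Gaussian noise,
with β_true required to sum to zero so the planted path is a genuine
log-contrast signal. Omics matrices are latent-factor block designs:
block features are √ρ·f + √(1−ρ)·ε, giving within-block correlation exactly
ρ; a block's factor can optionally be a taxa log-contrast for
association-network recovery. Ground truth (cores, responders, β_true,
mediating node, block labels, latent factors) is serialized as JSON next to
the data.

**What the generator does not emulate.** Sequencing error and chimeras,
ASV-level phylogenetic structure below genus, overdispersion beyond the
logistic-normal/multinomial hierarchy, batch effects on the microbiome
itself (batch affects only phenotypes), and realistic metabolite/transcript
marginal distributions. Passing recovery tests therefore demonstrates that
the estimators work when their model assumptions hold at study scale — not
that they are robust to every artefact of real data.

## Preprocessing conventions

* "Fewer than 20% of samples" is applied literally: a feature at exactly 20%
  prevalence is kept.
* Zero replacement uses the maximum-rounding-error value 0.5 on counts,
  then recloses each sample to 1.
* The inverse-normal transform uses the Blom offset c = 0.375,
  Φ⁻¹((r−c)/(n−2c+1)) with average ranks for ties; the Shapiro–Wilk screen
  (P < 0.05) is applied to the *transformed* vector, so heavily tied
  features (e.g. 90% zeros) are flagged for removal. The pre/post ambiguity
  was resolved in favour of post-transform screening.
* log-CPM is log2((count+0.5)/(libsize+1)·10⁶); voom precision weights are
  not computed because the downstream consumers here (modules,
  correlations) use only the transformed values.
* MAD uses the 1.4826 consistency constant (rank-neutral); ties in MAD break
  toward the lexicographically smaller feature id for determinism.

## Diversity

Shannon is reported in bits. Faith PD includes the root path. Unweighted
UniFrac is unique/observed branch length; weighted UniFrac is the normalized
variant Σ bℓ|p_A−p_B| / Σ bℓ(p_A+p_B). Both are computed via branch-indicator
matrices (one row per branch, one column per genus), which is exact on float
relative abundances and vectorizes over all sample pairs; scikit-bio's
integer-count implementation serves as an independent cross-check in the
tests. PCoA retains axes with eigenvalue > 1e-10, scales by √λ, reports the
negative-eigenvalue fraction, and fixes each axis's sign so its
largest-magnitude loading is positive. PERMANOVA uses the pseudo-F on
squared distances; because F is monotone in SS_within for fixed SS_total,
permutations compare SS_within only. All permutation P values use the
add-one estimator (1+hits)/(1+n_perm). Rarefaction is a single multivariate
hypergeometric draw per sample (no iteration averaging).

## Co-abundance modules

The network is unsigned, a = |cor|^β; β is the smallest power whose
scale-free fit R² (log p(k) vs log k over 10 connectivity bins) reaches
0.90, falling back with a warning to the best power otherwise — block-
structured data is not scale-free, so the fallback is the common case on
simulated blocks and is harmless: topological overlap is monotone in β for
block designs. TOM is (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij) with unit
diagonal.

Branch detection is a deterministic simplified variant of the dynamic tree
cut: average-linkage clustering of 1−TOM, a static cut at the 0.99 quantile
of merge heights, then two screens — minimum module size 20, and a
*distinctness* requirement that a branch's first principal component explain
at least twice the Marchenko–Pastur noise-edge variance fraction
(1+√(m/n))²/m for a block of its size. The second screen replaces the
min-size-only rule because a static cut always leaves a few large arbitrary
chunks on pure-noise input (about 1% of merges sit above any height
quantile); empirically, noise branches stay below 1.4× the MP edge while
planted blocks with within-block correlation ≥ 0.3 exceed 6× at any soft
power, so the factor-2 threshold separates the regimes with a wide margin.
Indistinct or undersized branches become grey; grey features are carried
forward individually (standardized) in module-level mediation.

Module eigenvalues are first-PC sample scores of the standardized module
matrix, unit variance, sign-aligned so mean correlation with the module's
own features is positive. Module–trait P values are Pearson t tests
(df = n−2) with BH applied jointly over the whole module × trait grid.
Pathway enrichment is the one-sided hypergeometric upper tail with BH across
pathways.

## Zero-sum sparse log-contrast regression

The model is (1/2n)‖y−β₀−Zβ‖² + λ‖β‖₁ subject to Σβ = 0, fit after centering
y and the columns of Z (which profiles out β₀ exactly).

**Solver.** Accelerated proximal gradient (FISTA with gradient-based
adaptive restart) whose prox is the exact minimizer of
½‖b−v‖² + τ‖b‖₁ s.t. Σb = 0, found in closed form through the dual: b =
soft(v−ν, τ) with ν located by bisection over the 2p breakpoints of the
piecewise-linear dual function. Every iterate satisfies the constraint
exactly and soft-thresholding produces exact zeros. A short pairwise
coordinate-descent polish (moves along e_i−e_j with the closed-form
two-variable L1 update, accepting only strict objective decreases) settles
coefficients onto kinks. Both stages are iterate-wise invariant to adding a
per-sample constant to Z — i.e. to rescaling each sample's composition —
because such a shift changes the gradient only along the all-ones direction,
which the prox and the pair moves ignore. Convergence is max coefficient
change < 1e-7 (final fits; the objective is additionally monitored so flat
valleys in the p > n regime terminate). Path fits used only for
cross-validation model selection run on a capped iteration budget at a
looser tolerance; the fit at the chosen λ is always re-solved to full
tolerance. Solver exactness is verified against an independent SLSQP
solution of the equivalent split-variable QP (objective gap < 1e-6 on random
instances).

**Protocol.** λ grid: 50 points log-spaced over three decades below
λ_max = (max q − min q)/2 (q the centered gradient at zero, the smallest λ
with β = 0). λ is the CV-minimum over 10 seeded folds (ties prefer the
sparser model). `bcv_prob` repeats CV+fit on 100 bootstrap resamples;
`stab_prob` on 100 half-size subsamples without replacement. Selection means
|β| > 1e-8 (exact zeros make this unambiguous). The final support is
{stab_prob > 0.85}, refit by constrained least squares (KKT system; the
refit coefficients are recentered on the support so the zero-sum holds to
machine precision); taxa with |refitted coefficient| < 0.1 are excluded from
the network but kept in the report. A support of size one is forced to zero
by the constraint and therefore never enters the network. CV-minimum tuning
is liberal — null taxa show moderate bootstrap frequencies — which is
exactly why the stability filter, not `bcv_prob`, gates the network.

## Mediation

**Distance-based.** D is Gower-centered and eigendecomposed; axes with
λ > 1e-10 are kept. x, y and the axes are residualized on the covariates.
The statistic is T = Σ_j w_j |cor(x, PC_j)·cor(PC_j, y)| with eigenvalue
weights w_j = λ_j/Σλ; the null permutes the rows of the coordinate matrix
jointly (implemented as one batched matrix product over all permutations).
The cited distance-based mediation approach fixes the idea but not the
internals; this statistic is this package's own concrete instantiation, and
its type-I error under a null with a direct x→y effect is verified to sit in
[0.03, 0.07] at α = 0.05.

**Tree-based.** Every internal node from phylum through family (root
included as the whole-community composition) is scanned: child abundances
are summed over descendant genera, children detected in ≤ 10% of samples are
pruned, zeros are replaced by 0.5, rows renormalized, and the subcomposition
ALR-transformed against the child with the largest mean relative abundance.
Nodes with fewer than two surviving children are skipped and logged.

**Multivariate linear mediation.** Mediator models M_k ~ x + C and outcome
model y ~ x + M + C; indirect = Σ α_k β_k, which equals total − direct
exactly in OLS with shared covariates (asserted to 1e-10 per fit). Inference
is nonparametric case bootstrap (default B = 999 for single models, 199
inside the tree scan), percentile CI, two-sided P = 2·min(P(≤0), P(≥0))
floored at 1/B. A mediator count above n/2 is rejected as an
identifiability guard. The resampling engine settings (bootstrap rather than
quasi-Bayesian draws, the B defaults) are this package's conventions.

**Module-based.** All module eigenvalues plus standardized unclustered
features enter one joint model; per-mediator components α_kβ_k are reported
alongside the joint indirect effect.

## Host statistics

Permutation Wilcoxon rank-sum on pooled average ranks, two-sided deviations
from the null mean, exact enumeration when C(n, n_a) ≤ 20,000 and 9,999
random splits with the add-one estimator otherwise. Levene's test is the
classical mean-centered form (groups whose absolute deviations are all equal
return W = 0, P = 1 rather than 0/0). The two-way ANOVA uses Type II sums of
squares — order-invariant main effects, appropriate for the mildly
unbalanced 7–10-per-cell design. BH adjustment is the step-up procedure,
monotone and capped at 1 (note BH is not idempotent; re-adjusting an
adjusted vector changes it).

## Problem sizes and defaults

The end-to-end pipeline default is the study-shaped configuration: 2×4
design with 8 mice per cell (64 samples), 45 genera / 25 families, 300
metabolites in 3 blocks (one taxa-driven), 1,000 genes (log-CPM, MAD top
500), B = 100 stability subsamples per response, 999 permutations for
PERMANOVA and distance mediation, B = 199 bootstrap inside the tree scan.
These sizes keep a full run to a few minutes on one CPU while leaving every
estimator in the regime it was designed for. Calibration checks use 500
replicates (type-I error), power checks 200, recovery checks 10–20.

## Known limitations

* The dynamic-cut variant is deliberately simplified; deep nested modules
  (the full hybrid algorithm's target) are not resolved.
* The log-contrast model is fit without covariate adjustment, matching the
  per-response association protocol; confounder-adjusted variants are out of
  scope.
* Mediation models are linear with no exposure-mediator interaction and no
  sensitivity analysis for unmeasured confounding.
* CV-minimum tuning with B = 100 subsamples leaves the 0.85 stability
  threshold operating close to its design point: individual null taxa pass
  the combined network filter in up to ~10% of replicates under the
  recovery-test conditions.
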