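# Methods

This note documents the statistical models, algorithms, and design choices
behind `regionrank`, in the order the pipeline runs them.

## Synthetic cohorts

`synthdata.simulate_cohort` generates the multi-region study conditions every
downstream stage assumes. Each subject carries a standard-normal **severity
latent** z. Six disease traits derive from z:

* Ordinal traits threshold z at fixed quantiles — CDR on the scale
  {0, 0.5, 1, 2, 3, 4, 5}, a Braak-like stage on {0..6}, and a CERAD-like
  rating coded 0 = normal, 1 = possible AD, 2 = probable AD, 3 = definite AD.
  The lowest ~30% of subjects ("clean brains") sit in the normal band of each
  trait; because all traits threshold the same latent, they are mutually
  correlated, as cognitive and neuropathological measures are in practice.
* Quantitative lesion traits (PLQ_Mn, NPrSum, NTrSum) are 0 for clean brains
  and exp(a·z + noise) otherwise — an atom at zero plus a right-skewed
  positive part, which is exactly the shape the zero = normal / median-split
  severity grouping rule expects.

Expression for each region is built from planted modules: module m has a
latent factor; for **disease modules** (default 2 of 6) the factor is
`trait_effect`·z + √(1−trait_effect²)·ε so its population correlation with
severity equals `trait_effect` (default 0.8). Genes load on their module's
factor with loadings ~ U(0.7, 1.3) plus N(0, `noise_sd`²) residual noise.
The default `noise_sd` = 0.65 corresponds to a within-module gene–gene
correlation near 0.7 and is also used as the residual log2 SD of the
two-group generator — a typical replicate SD for expressed genes on
log2-scale microarrays. Covariates (sex, PMI, pH, race) add linear effects
with per-gene coefficients ~ N(0, `covariate_effect`²).

Module membership is **consensus-with-variation**: each module keeps a shared
core of `module_overlap`·size genes (default 80%) in every region and fills
the remainder from the background pool per region. This makes cross-region
Jaccard indices of corresponding modules ≈ 0.67 — conserved but not
identical, as real consensus modules are — and prevents different regions'
modules from being exact copies, which would make cross-region validation
statistics degenerate. Subjects are shared across regions with a
configurable `missing_fraction` (default 0.2), emulating uneven regional
tissue availability; meta-network construction uses the donor intersection.

The single-cell generator draws counts from NB(μ, φ) with
log μ = log(libsize) + baseline_g + log(marker_fold)·1[marker] + subject
effect, variance μ + φμ² (φ = `dispersion`, default 0.25). Markers (default
10% of genes, 8-fold) are split evenly across the five brain cell types.

What the generators do **not** emulate: probe-level chemistry, batch or RNA
degradation artifacts, heavy-tailed expression noise, correlated marker
programs, or doublets. Passing tests therefore demonstrate correctness of
the algorithms under the assumed generative structure, not robustness to
every artifact of real cohorts.

## Preprocessing

Quantile normalization forces every sample onto the common reference
distribution (row means of the column-sorted matrix); tie groups receive the
mean of the reference values their ranks occupy, making the operation
permutation-stable and idempotent. Covariate correction is per-probeset OLS
on intercept + sex + PMI + pH + race (treatment-coded), with the probeset
mean added back so log2 fold changes remain interpretable. A rank-deficient
design raises an error naming the collinear columns. Expression is assumed
log2-scale (RMA-like) — a documented precondition, not auto-detected.

## Differential expression and trait correlation

Per-probeset two-group comparison with empirical-Bayes variance moderation:
pooled variance s²_g (df_g = n1+n2−2) shrinks to
s²_post = (d0·s0² + df_g·s²_g)/(d0 + df_g), with (d0, s0²) estimated by
method of moments on log s²_g via digamma/trigamma identities (the trigamma
inverse solved by Newton iteration). The moderated t is
Δmean/(s_post·√(1/n1+1/n2)) on d0+df_g degrees of freedom. The
implementation is validated against an independently coded oracle (Brent
root-finding for the trigamma inverse) and against R/limma on a fixture.

The empirical FDR at cutoff c is n·(FP/N)/P, with the null built by
reshuffling group labels jointly for all probesets (preserving gene–gene
correlation) and refitting the full moderated-t model each time. Per-probeset
FDRs are made monotone non-increasing in |t| by a step-up cumulative minimum,
which makes the procedure *identical* to computing empirical permutation
p-values (FP/N, no +1 smoothing) and applying Benjamini–Hochberg — an
equivalence asserted to 1e-10 in the tests. Five permutations are the
production default; calibration tests use 20 for stability. DEGs require
FDR < 0.05 and fold change > 1.5, where FC = 2^|mean log2 difference| (the
anti-log of the mean log-difference, a documented choice). Severity groups:
Braak 0–2/3–4/5–6; CDR 0 / (0,2] / [3,5] (the low band covers the standard
CDR values 0.5, 1, 2); CERAD normal / possible-probable / definite;
quantitative traits 0 = normal, remainder median-split with the median
falling in "low".

Trait-correlated genes use Spearman rho (average ranks, t-approximation
p-values) with the same permutation-FDR machinery on a trait-permutation
null.

## Cell-type markers

Counts are filtered (< 50 reads total discarded) and modelled per gene:
y_gc ~ NB(μ, φ_g), log μ = log(libsize_c) + α_g + β_{g,t(c)} + γ_{g,s(c)},
priors β, γ ~ N(0, 2²), α ~ N(empirical log mean proportion, 5²),
φ ~ Gamma(0.01, 0.01), reference subject's γ fixed at 0. Subject effects are
per-gene, keeping the gene regressions independent and the sampler
vectorizable across genes.

Sampling is Metropolis-within-Gibbs with per-gene, per-block proposal scales
adapted toward 35% acceptance during warmup; default 4 chains × 1000 draws
after 1000 warmup (tests and the acceptance script use 2 × 500, which the
recovery and calibration checks show is sufficient at the synthetic scale).
Split-R̂ is computed per centred β; genes with R̂ > 1.1 are excluded from
calling.

α and the β vector share a weakly identified direction (only α+β_t enters
the likelihood), so "enrichment over basal expression" is defined on the
**median-centred** effects β_t − median(β_·): basal expression is the gene's
typical cross-type level, a pure function of the well-identified between-type
contrasts. With five types and markers enriched in one, the median is the
non-marker level, so a planted 8-fold marker posterior concentrates at
exp(β) ≈ 8. A gene is called specific to type t iff P(β_centred > 0) ≥ 0.999
in t, below 0.999 in every other type, and the posterior mean of
exp(β_centred) exceeds 5; the resulting per-type sets are disjoint by
construction.

## Co-expression networks

Unsigned weighted network: a_ij = |cor(x_i, x_j)|^β with β = 6 (signed
variant available via `network_type`). The scale-free fit index is the R² of
regressing log10 p(k) on log10 k **and** k (truncated exponential power-law
model) over 10 equal-width connectivity bins. TOM:
tom_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij), l_ij = Σ_u a_iu a_uj.

Modules come from average-linkage clustering of 1 − TOM with a
dynamic-hybrid-style tree cut. For average linkage, the merge height is the
mean dissimilarity between the merged clusters, so each branch's **core
scatter** (mean within-branch dissimilarity) accumulates exactly during
linkage. A branch qualifies as a module when it has ≥ `min_module_size`
members (default 30) and its core scatter sits below its attachment height
by at least a gap that is a `deep_split`-controlled fraction of the
dendrogram height range (deep_split 0–4 maps to 20% down to 5%, with an
absolute floor of 0.02 dissimilarity units). A qualifying branch is taken
whole unless it separates into ≥ 2 disjoint qualifying sub-branches, in
which case the cut descends; the root itself never forms a module, which is
what sends pure-noise input entirely to grey. When expression is available,
membership is refined by the standard kME rule: members with
|cor(gene, eigengene)| < 0.5 are demoted to grey and modules falling below
the size floor dissolve. Modules are named by descending size from the
conventional color palette; grey is reserved for unassigned probesets.

The module eigengene is the first right singular vector of the z-scored
module expression (unit norm), oriented to correlate positively with the
module's average standardized profile; variance explained is s1²/Σs².
Because the orientation anchors to the data, negating the input negates the
eigengene consistently — orientation is covariant, not fixed.

## Meta-network, conservation, and cross-region pairs

All regions' eigengenes, re-standardized on the shared donor subset, run
through the same adjacency → TOM → tree-cut pipeline (minimum meta-module
size 3, since eigengene matrices are small). Module conservation is the
Jaccard index |A∩B|/|A∪B| over cross-region module pairs with a count above
a 0.5 threshold (strict inequality). Cross-region interaction counts
Pearson-correlated probeset pairs across shared donors with BH adjustment —
BH rather than permutation FDR here because the pair universe is quadratic
and the BH null is adequate for counting; this is a deliberate divergence
from the label-permutation machinery used for DE.

## Enrichment and perturbation validation

Over-representation uses the one-sided hypergeometric tail (depletion is
never tested), fold enrichment (overlap/|query|)/(|target|/|universe|), and
BH across each batch. Perturbation validation computes signature enrichment
for every module (pooled across regions), splits modules by whether they
contain the perturbed target gene, and compares −log10 p between the groups
with a one-tailed Wilcoxon rank-sum test (exact for small untied samples,
tie-corrected normal approximation otherwise). At desk scale the signature
samples a non-trivial fraction of the universe, so random signatures show
mildly inflated false-positive rates through their chance overlap with the
(partially shared) target modules — an intrinsic property of the small
universe, reported as-is by the acceptance script.

## Ensemble ranking

S_i = (∏_j f(K_ij))^{1/n}, scaled by the maximum. Count variables use
f(K) = ln(1+K): ln(K) is undefined at the zero counts that occur in real
tables, and ln(1+K) preserves order while keeping f ≥ 0. A zero factor
zeroes the product — an item with no signal on any one variable scores 0,
which is the geometric mean's intended severity. P-value variables use
f(P) = −ln(P) with P floored at 1e-300. Region ranking uses 24 count
variables (3 contrasts × 6 traits of DEG counts + 6 TCG counts); module
ranking uses 6 eigengene–trait correlation P-values + 18 DEG-enrichment +
6 TCG-enrichment P-values; gene ranking uses DE and trait-correlation
P-values per region × trait with absent genes contributing P = 1. Natural
logs throughout (the base cancels in rank order). Ties share the minimum
rank with stable input order.

## Problem sizes and numerical choices

Synthetic study conditions: 4 regions × 60 samples, 500 probesets, 6 modules
× 50 genes (2 disease-linked), trait effect 0.8; single-cell: 300 genes,
5 types × 60 cells, 3 subjects, 10% markers at 8-fold. Calibration studies
use 5000 probesets × 20+20 samples with 20 permutations. These sizes keep
every property measurable (planted-structure recovery, FDR calibration,
posterior coverage) while the full test suite and acceptance script run on a
single CPU in a few minutes. Degenerate inputs are contracts, not crashes:
constant probesets zero their correlations with a warning, constant traits
and zero-variance modules raise errors, empty observed statistics raise, and
P = 0 is floored only where the ranking transform requires it.

## Known limitations

* The tree cut is a principled reimplementation of the dynamic-hybrid idea,
  not a line-for-line clone of WGCNA's `cutreeHybrid` (no PAM stage); its
  contracts are validated on planted structure rather than against WGCNA
  output.
* The NB sampler is random-walk Metropolis; for genes with extreme counts or
  near-zero dispersion, mixing is slower than a gradient-based sampler and
  the R̂ filter may exclude genes rather than resolve them.
* Gene-level ranking assembles per-gene evidence from one contrast per
  region-trait pair; the exact variable set is a declared convention,
  configurable by callers.
* Empirical FDR with few permutations (the default 5) is noisy below
  ~1/(5n) resolution; calibration-sensitive analyses should raise the
  permutation count.
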