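# Methods

This note documents the models implemented in `refpop`, the choices made
where the design was genuinely open, and what the synthetic data do and do
not establish about real populations.

## Synthetic population generator

**Founder haplotypes.** Each chromosome is generated by a first-order
copy/mutate Markov process along the marker map: the allele at marker *k*
copies the allele at marker *k−1* with probability exp(−d/λ), where *d* is
the inter-marker distance in bp and λ = `ld_decay_bp` (default 3,000 bp),
and is otherwise drawn fresh from the marker's allele frequency. This
produces an approximately exponential decay of haplotype correlation with
distance — the only LD feature the downstream stages depend on — at a small
fraction of the cost of a coalescent simulation. It deliberately omits
long-range admixture LD, demographic history, and selection. Base allele
frequencies are uniform on [0.1, 0.9]; each origin group receives a
once-drawn normal perturbation (SD `origin_freq_sd` = 0.03) so PCA shows
weak clines, mirroring a diverse, highly admixed germplasm panel. Markers
whose realized MAF falls below `maf_min` (default 0.05) are resampled for a
bounded number of rounds; persistent failure raises an error.

**Meiosis.** Crossovers per chromosome are Poisson(`recomb_rate`, default
1.5) with uniform positions and no interference (the Haldane model); each
gamete is the resulting mosaic of the parent's two haplotypes. 27 parental
pairs are drawn without replacement from the founders, 10 offspring each,
mirroring the progeny-group design. Mendelian consistency is exact by
construction and asserted in tests.

**Phenotypes.** Each tree's value is
offset + TBV + environment + G×E + spatial + residual, in day-of-year units
(real-valued by default; integer rounding is a flag). The true breeding
value is a sum over `n_causal` loci with normal effects. Each component is
centered and rescaled so its variance over trees equals its target fraction
of `total_sd_days`² exactly; the G×E matrix is double-centered and the
spatial surface centered within environment, so components are orthogonal
to the model terms that estimate them and realized fractions match the
requested values to within ~0.01. Spatial surfaces are three seeded Gaussian
bumps plus a linear trend per environment — smooth enough for a spline to
recover, non-trivial enough to bias unadjusted genotype means. The field
layout stacks complete blocks by rows; every genotype appears once per
block per environment.

Passing parameter-recovery tests on these data shows the estimators are
correct under the generating model; it does not establish robustness to
features real orchards add (missing trees, spatially correlated G×E,
scoring errors, triploids).

**Scaffold masking.** The low-density panel is an evenly spread, map-ordered
subset with per-chromosome allocations proportional to marker counts
(largest remainder) and a seeded random phase, so subsets are reproducible
and every chromosome keeps coverage.

## Imputation

Full localized-haplotype-cluster imputation is intentionally out of scope.
The shipped imputer is a transmission tracer for full-sib families with
phased parents: per offspring chromosome, a dynamic program over the 4
joint transmission states (which parental haplotype each parent passed)
minimizes genotype mismatches (cost 1) plus switches (cost
`switch_penalty` = 2.0, so one crossover is cheaper than two genotyping
errors). Dense markers take the equal-weight posterior over states on at
least one optimal path at the nearest scaffold anchor; observed scaffold
genotypes pass through unchanged; Mendelian-impossible scaffold genotypes
are flagged and excluded from the trace. Accuracy metrics follow the
validation convention: the mean over individuals (markers) of the Pearson
correlation between imputed and true dosages over markers (individuals);
zero-variance rows/columns are excluded and counted, never imputed as 0.
Whether the published metric averaged per-row correlations or pooled all
entries is not stated; the per-row/column mean is used here.

## Linkage disequilibrium

LD is the squared Pearson correlation of dosage vectors (composite
genotype LD; no phasing required). The decay smoother is a locally
weighted quadratic regression with tricube weights, the span interpreted
as the fraction of points in each local fit, evaluated on a 200-point
log-spaced grid; exact equivalence to any particular loess implementation
is not claimed, and tests are tolerance-based. The r² = 0.2 threshold
distance is determined from a second smoother fitted to the pairs within
5 kb only — the long-range bulk of near-zero r² would otherwise dominate
every local fit — with linear interpolation between grid points. Windowed
means average all r² within ±50 bp of each reference distance. Pruning is
greedy within sliding windows (50 SNPs, step 10): while any retained pair
exceeds r² = 0.1, the later marker is removed; ties keep the earlier
marker, so the result is deterministic.

## Population structure

The default inter-individual distance is allele-sharing dissimilarity,
mean(|dᵢ − dⱼ|)/2 (0 for clones, 1 for opposite homozygotes); Euclidean
distance is selectable. Neighbor joining is the standard Saitou–Nei
agglomeration (via scikit-bio), with negative branch lengths clamped to
zero and the length transferred to the adjacent branch so leaf-to-leaf
path lengths are preserved; on additive distances the generating tree is
recovered exactly, which the tests exploit as an oracle. PCA is fitted on
centered (by default unscaled — marker variance carries information)
dosages of the active set only; supplementary individuals are centered
with the active means and multiplied by the active loadings, so they do
not influence the components.

## Spatial adjustment

Per environment and trait, the model is
y = f(u,v) + Z_g c_g + Z_r c_r + Z_c c_c + ε with random genotype, row and
column effects and a smooth surface f over the integer (row, column)
coordinates. f is a tensor product of cubic B-spline bases (equally
spaced knots, one per 4 rows/columns by default) with a second-order
difference penalty per margin, combined anisotropically:
Λ(λ_u, λ_v) = λ_u·(D′D ⊗ I) + λ_v·(I ⊗ D′D). The marginal penalty null
spaces (constant and linear coefficient vectors, which map exactly to the
functions 1 and x for equally spaced knots) are pulled out as fixed
effects {u, v, u·v}; the remaining transformed coefficients have a
diagonal precision and enter the mixed-model equations as random effects.
This is a deliberate simplification of the five-component PS-ANOVA
decomposition: it preserves the adjusted-value contract and the effective
dimensions of smooth/row/column/genotype while keeping REML tractable at
desk scale. Variance ratios and the two smoothing parameters are chosen by
maximizing the profiled restricted likelihood over log-ratios, initialized
from a coarse 3-point grid per parameter and refined with Nelder–Mead.
Effective dimensions are q − tr(Λ C⁻¹) per block. The adjusted value of a
tree is intercept + genotype BLUP + residual; smooth, row and column terms
are excluded. If the genotype-mean model already fits exactly (zero
residual data) the spatial model is skipped and the data returned
unchanged; layouts with fewer than 5 distinct rows or columns degrade to a
1D smooth with a warning.

## Heritability and variance decomposition

One-way REML (random genotype) is computed by direct maximization of the
profiled restricted likelihood of the variance ratio, using groupwise
Woodbury identities (cost linear in observations), with an explicit
boundary check at σ²_g = 0. Direct profile maximization was chosen over
EM iterations because it reaches the balanced-design ANOVA estimators to
1e−6 in bounded time; the estimand (the REML maximizer) is identical.
n̄_r is the arithmetic mean of per-genotype replicate counts (a harmonic
alternative is available behind a flag).

The pooled model y = µ + env(fixed) + genotype + G×E + ε is fitted
exactly for equal per-cell replication via the REML factorization:
within-cell contrasts estimate σ²_ε alone (σ̂²_ε = SSW/(N−C)); the cell
means follow a one-way model with genotype variance σ²_g and cell noise
τ² = σ²_gl + σ²_ε/k, reusing the one-way machinery; σ̂²_gl = τ̂² − σ̂²_ε/k,
truncated at zero. Unequal replication is rejected rather than
approximated. The fixed-environment variance fraction is the variance of
the per-tree predictions with all random effects set to zero, divided by
the total (that variance plus the three random components). 95%
profile-likelihood CIs use the χ²₁(0.95) cutoff with a 2-parameter inner
optimization and bisection to 1e−6 on the variance scale; lower bounds at
zero are reported as exactly 0. Environments with individual-location
H² < 0.1 are excluded before pooling. LS-means come from the ordinary
least-squares two-way additive fit; the LS-mean of a genotype is its cell
prediction averaged over all retained environments, verified against the
brute-force normal equations in tests.

## GWAS

Kinship is the VanRaden genomic relationship matrix (dosages centered by
2p̂, scaled by 2Σp̂(1−p̂); monomorphic markers excluded). The multi-locus
scan is a forward/backward stepwise mixed-model regression with a
Bonferroni stopping rule (the upstream default model-selection criterion
is not reproduced): per step, the variance ratio δ = σ²_ε/σ²_g is
re-estimated by bounded scalar maximization of the restricted likelihood
over log δ ∈ [−10, 10] (tolerance 1e−6) on a single eigendecomposition of
K; all non-cofactor SNPs are then tested jointly with the current
cofactors by a GLS Wald test in the rotated space; the minimum-p SNP
enters as a cofactor while p < α* = α/m; a backward pass removes
cofactors whose re-test rises above α*. Reported per-SNP p-values are
from each SNP's last test. With K = I the scan reduces exactly to
single-marker OLS, which the tests use as an oracle. MAF filtering
(default 0.05) is computed on the analyzed individuals; m is the number
of tested markers, so the threshold adapts to subset density. Significant
SNPs within 1 Mb on a chromosome are merged into one region (the window
is a choice; a published pair 5.3 Mb apart stays two regions under it).
Per-SNP explained variance is the R² of the simple regression of the
phenotype on that SNP's dosage.

## Genomic prediction

RR-BLUP with all markers sharing one effect variance; because the response
holds one LS-mean per genotype, the design matrix relating genotypes to
phenotypes is the identity. Markers are centered by 2p̂ and not scaled.
σ²_u and σ²_ε come from spectral REML on the equivalent individual-level
model (eigendecomposition of GG′), and marker effects from the n×n dual
solve û = G′(GG′ + λI)⁻¹(y − µ̂), verified against the primal
mixed-model equations to 1e−8. In cross-validation, centering and λ are
re-estimated inside every training fold, so no information leaks from the
validation fold; per-repetition predictive ability is the mean over folds
of the within-fold Pearson correlation (a pooled-over-folds correlation
is also reported, since the published wording does not disambiguate).

## Density experiment and precision

Evenly spaced subsets take every ⌊M/m⌋-th marker from a seeded random
start, truncated to exactly m markers, using map order as the distance
proxy. Kinship for the scan is always computed from the full panel so
that density varies only the tested markers; the Bonferroni denominator
is the subset size. Confidence intervals over subset seeds use the normal
approximation mean ± 1.96·SE (a t-quantile option exists). A density
equal to the panel size makes the subset the identity for every seed —
zero seed variance — so plateau comparisons use the default ladder
truncated below the panel size, as in the published ladder, whose top
density also sits below its panel. Expected GEBV precision is the closed
form r̂² = Nh²/(Nh² + M(1−h²)); M = 0 returns 1, h² = 0 returns 0 with a
warning; the grid spans N ∈ {10, 269, 534, 1000}, M ∈ [1, 10⁶]
(log-spaced), h² ∈ {0.5, 0.8}, with precision ≥ 0.8 flagged very high.

## Problem sizes and determinism

The test suite runs the study-scale population at 539 genotypes × 5,000
SNPs × 5 environments and the desk panel at 539 × 20,000; the density
experiment uses the default ladder with 5 seeds × 10 CV repetitions.
These sizes were chosen so every stage's statistical behavior (parameter
recovery, type-I control, plateau) is measurable with stable seeds. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical configuration and seed reproduce
byte-identical artifacts, which the pipeline test asserts via content
hashes.

## Known limitations

- The generator's LD is strictly local; real panels carry long-range
  admixture LD, so real predictive-ability curves can plateau at sparser
  densities than synthetic ones.
- The pooled variance model requires equal per-cell replication; real
  trials with dead trees need the (unimplemented) unbalanced path.
- The family imputer assumes correctly phased parents and biallelic
  markers; it is a baseline for exercising the accuracy metrics, not a
  population imputer.
- Profile-likelihood CIs assume the χ²₁ asymptotics; near-boundary
  components (true variance ≈ 0) are reported with a hard floor at 0.
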