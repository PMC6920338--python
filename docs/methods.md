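# Methods

## Genotype coding and hybrid deduction

Biallelic SNPs of inbred parents are coded Z ∈ {−1, 0, +1} (A1A1, A1A2,
A2A2). Parents are expected to be homozygous; a 0 appears only as residual
heterozygosity. An F1 hybrid's code at a locus is the mean of its parents'
codes, giving the grid {−1, −½, 0, ½, 1}: e.g. A1A1 × A1A2 → (−1+0)/2 =
−0.5. A missing parental genotype makes the hybrid genotype missing.
`GenotypeMatrix` enforces the grid; mean-imputed matrices carry
`code_domain="continuous"` since imputed values fall off the grid.

Marker QC keeps markers with minor allele frequency strictly above
`maf_min` (default 0.1) and missing fraction at most `missing_max` (default
0.25); the allele frequency is computed from the codes as p = (mean + 1)/2.
The strict/non-strict comparisons are deliberate and tested. Missing
genotypes are then replaced by the marker mean. This marker-mean imputation
is a simple frequency-preserving rule; it ignores linkage, so it is noisier
than haplotype-based imputation on real, LD-structured data.

## Kinship

The additive kinship is the uncentered cross-product
K = (1/m) Σ_k Z_k Z_kᵀ — no centering by allele frequency and no VanRaden
denominator. This matters: K then has a large leading eigenvalue along the
mean-code direction, and the "genomic heritability" implied by a fit,
h² = λ·k̄/(λ·k̄ + 1) with k̄ the mean diagonal, is *not* the same number as
the realized variance ratio of genetic values (the sample variance of
ξ = Σ Z_k γ_k is φ²(k̄ − mean(K)), smaller than φ²k̄). A centered variant
is available (`compute_kinship(..., center=True)`) but is not the default.
The dominance kernel uses heterozygosity codes W = 1 − |Z| (heterozygote 1,
homozygote 0, half-codes ½ = expected heterozygosity of a cross with one
residually heterozygous parent): K_D = (1/m) Σ_k W_k W_kᵀ.

## REML and BLUP

The additive model y = Xβ + ξ + ε, ξ ~ N(0, Kφ²), ε ~ N(0, Iσ²), is
profiled to a one-parameter restricted likelihood in λ = φ²/σ². With
K = U D Uᵀ and the rotation y* = Uᵀy, X* = UᵀX, the covariance is
H = Dλ + I (diagonal) and

    L(λ) = −½ Σ ln h_i − ½ ln|X*ᵀH⁻¹X*| − ((n−q)/2) ln σ̂²(λ),

with β̂ the GLS solution and σ̂² = (y*−X*β̂)ᵀH⁻¹(y*−X*β̂)/(n−q)
(REML divisor n − q, q = rank of X). All additive constants independent of
λ — including −(n−q)/2·(1 + ln 2π) and ((n−q)/2)ln(n−q) — are dropped;
log-likelihoods are only ever compared within this convention.

Maximization: a coarse 17-point log-spaced bracket on λ ∈ [1e−8, 1e8]
locates the basin, then Newton iteration on θ = ln λ (positivity by
construction) with analytic first and second derivatives computed via
projection-matrix identities in the rotated basis (everything O(n q²)).
Convergence at |Δθ| < 1e−8 or 50 iterations; a bounded Brent search over θ
is the fallback, and the λ = 0 boundary is always compared against the
interior optimum (under a null trait, λ̂ = 0 with probability ≈ ½ — the
standard one-sided boundary mixture). An ill-conditioned X*ᵀH⁻¹X* falls
back to a pseudo-inverse with a warning rather than failing.

Prediction of untested hybrids uses the partitioned kinship exactly:
ŷ₂ = X₂β̂ + λ̂K₂₁(K₁₁λ̂ + I)⁻¹(y₁ − X₁β̂), with the inverse evaluated
through the training eigendecomposition. Multi-trait analyses are
independent per-trait univariate fits.

### Two-kernel extensions

The additive + dominance (A-D) model and the multi-environment (G×E) model
share one two-kernel REML routine: V₀ = K₁λ₁ + K₂λ₂ + I with σ² profiled
out, maximized by Nelder-Mead over (ln λ₁, ln λ₂) with tight tolerances
(xatol 1e−10, fatol 1e−12), warm-started from the one-kernel additive
optimum, and with explicit boundary comparison at λ = 0 for each ratio.
Since the two-kernel model nests the additive one, a worse-than-additive
optimum is never reported. For G×E over E environments the stacked nE
model has environment-specific fixed means, a main genomic effect with
covariance J_E ⊗ K·φ²_main (J_E all-ones) and an independent interaction
effect I_E ⊗ K·φ²_gxe — the linear-kernel multi-environment GBLUP
structure. With E = 1 only the sum λ_main + λ_gxe is identified, so the
model collapses to the additive fit with λ_gxe = 0 by construction.

## Cross-validation and prediction ability

`cross_validate` partitions n hybrids into k folds of size ⌊n/k⌋ or ⌈n/k⌉
(partition seed = seed + replicate index), refits REML on the retained
folds, predicts the held-out fold through the corresponding kinship blocks
of the *once-computed* full-sample K (matching the partitioned-BLUP
formulation; K is not recomputed per training fold), assembles all folds
and reports the Pearson correlation with the observations per replicate
plus the per-trait mean. Folds where the fit fails are skipped with a
warning and excluded from the correlation.

Known property: on a strict null trait the assembled-correlation ability is
*negatively biased*, not centered at zero. Whenever REML hits the λ = 0
boundary the held-out predictions degenerate to training-fold means, which
are anti-correlated with the held-out observations (r ≈ −√(n_f/(n−n_f)) ≈
−0.22 at k = 10 in that regime; averaged over the boundary mixture the
expected null ability is ≈ −0.1). This is a property of the estimator, not
of the implementation; on traits with genuine signal λ̂ stays interior and
the effect vanishes.

## Heritability from a randomized complete block design

With hybrids in rows and b ≥ 2 blocks (locations) in columns,
y_jk = μ + α_j + β_k + ε_jk (blocks fixed, hybrid effects random), the
expected-mean-squares equations of the two-way layout without replication
give MS_G = σ²_E + b σ²_G and MS_E = σ²_E, so σ̂²_G = (MS_G − MS_E)/b and
h²_broad = σ²_G/(σ²_G + σ²_E). A negative moment estimate is reported raw
and truncated at zero for h². `method="reml"` maximizes the profile
restricted likelihood of the same model over σ²_G/σ²_E instead. Any G×E
interaction present in the data lands in σ²_E, so this is broad-sense
heritability on a plot-mean basis within the design.

## Breeding index and selection

Predicted traits are standardized to z-scores across the candidate set
being ranked (population sd, divisor n; both the reference set and the
divisor are configurable — the choice of standardization population is a
genuine degree of freedom). The index is I_j = Σ_k w_k z_jk with
non-negative weights summing to one; the shipped default is the ten-trait
rice set (YD 0.40; PN, GN, SSR 0.10; KGW, HD, PH, PL, GW, GL 0.05). All
traits are treated as larger-is-better; per-trait sign flips are left to
the caller by negating columns before standardization. Extreme-set
selection breaks ties lexicographically by hybrid id and refuses
overlapping top/bottom sets. The PCA summary reports eigenvalues of the
trait correlation matrix (they sum to the number of traits) and component
scores of the standardized matrix.

## Synthetic data

The generator emulates the structure the pipeline assumes, not any
particular germplasm: per marker an allele frequency is drawn uniformly on
[maf_low, maf_high] (defaults 0.1–0.5, i.e. a post-QC spectrum), parents
are fully inbred (±1) apart from an optional residual-heterozygosity rate,
markers are independent (no linkage map — nothing downstream uses
position), and hybrids are exact parental means. Defaults describe a
desk-scale dense crossing program: 50 parents, 800 markers, half-diallel
crosses, 400 training hybrids; the parent:hybrid ratio follows a diallel
validation design rather than a sparse pedigree, which is what makes a
training set of a few hundred hybrids informative.

Phenotypes combine additive, optional dominance (on W codes) and optional
environment-specific additive deviations, each realized component rescaled
to unit variance and weighted by the requested shares; the residual SD is
then calibrated against the *realized* genetic variance so the designed
broad-sense heritability matches `h2_target` (robust to dominance/G×E
settings; exact at h2 = 1, pure noise at h2 = 0). Because of the
uncentered kinship (above), this broad-sense convention differs from the
genomic one: `simulate_polygenic` instead draws marker effects directly
from the GBLUP model with λ = h²/((1−h²)k̄), which is the convention under
which REML's implied genomic heritability λ̂k̄/(λ̂k̄+1) is the estimand.
Recovery checks use whichever convention defines their target. True
genetic values are always returned alongside phenotypes for oracle tests.

What passing tests on these simulations do *not* show: robustness to
linkage disequilibrium, population structure beyond the crossing design,
non-Gaussian effect distributions, or genotyping error in real panels.

## Numerical choices and problem sizes

Eigenvalues of kinship matrices are clipped at zero below a relative
tolerance of 1e−8 (more negative values raise). Rotated-basis likelihoods
agree with dense-matrix evaluation to 1e−8 and BLUP to 1e−10 on random
instances; the test suite exercises recovery simulations at n = 500 /
m = 1000 (REML), n = 400 (cross-validation) and n = 1000 (CRBD), sizes
chosen so the full suite runs in well under a minute of compute per check
while keeping Monte-Carlo error inside the stated tolerances.
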