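# Methods

## Model and estimation

`famassoc` tests each (response, predictor) pair under the linear mixed
model

r = Xb + g + e,  g ~ N(0, σ²ₐ·2Φ),  e ~ N(0, σ²ₑ·I),

where X stacks an intercept, the predictor (alternative model only) and
any covariates, and 2Φ is the relatedness matrix on the GRM scale (twice
the kinship coefficient; diagonal 1 + F). The package keeps **one scale
everywhere**: pedigree kinship, GRM input and the unrelatedness presets
(second cousin 0.03125, third cousin 0.0078125) all live on 2Φ, which
avoids silent factor-of-two mistakes.

Estimation is full **maximum likelihood**, not REML. ML keeps the
likelihood-ratio test exactly nested and matches the classical
transmission-test framework this engine mirrors; the cost is the usual
slight downward bias of the variance components (order p/n, negligible for
the scan sizes the tool targets but visible if n is tiny).

The fit exploits the standard spectral trick: with 2Φ = U D Uᵀ computed
once per missingness pattern, rotating y and X by Uᵀ diagonalizes the
covariance to σ²·(hD + (1−h)I), where h = σ²ₐ/(σ²ₐ+σ²ₑ) ∈ [0,1] and σ² is
the total variance. At fixed h the fixed effects are weighted least
squares and σ̂² = RSS/n is closed-form, leaving a 1-D profile likelihood
in h. The profile is scanned on a 21-point grid (guarding against the
occasional local optimum) and the optimum then located by **root-finding
the analytic profile derivative** (envelope theorem) with Brent's method
at xtol 1e-12. Function-value minimization alone cannot pin h beyond
~√ε·|ℓ| because the log-likelihood is O(10³); the derivative is O(1) and
numerically clean, which is what makes the fit reproducible to 1e-8 in h
under affine rescaling of the response. Boundary optima (h = 0 or 1) are
detected from the derivative's sign on the bracket.

When every eigenvalue of the subset equals 1 (all pairs unrelated), h is
unidentifiable — the likelihood depends only on σ²ₐ+σ²ₑ. The fit then
takes the closed-form OLS path with h = 0 and sets a machine-readable
`h2_identifiable = False`; heritability is reported as NA with p = 1
rather than as an arbitrary number. A pleasant consequence is that the
association test reduces *exactly* to the classical regression LRT for
unrelated samples.

Explicit-parameter likelihood evaluation (`loglikelihood`) uses a
Cholesky → LU → rank-revealing-QR cascade, recording which decomposition
succeeded; the QR branch uses the pseudo-determinant and a minimum-norm
solve and rejects residuals outside the covariance's range. LRT values in
(−1e-8, 0) are clamped to zero; anything more negative raises an internal
consistency error rather than being silently hidden.

### Tests and p-values

- Association: LRT of β = 0, p from χ²₁ (β is an interior parameter).
- Heritability: LRT of σ²ₐ = 0 against the covariates-only model, p from
  the boundary mixture ½χ²₀ + ½χ²₁ (p = 0.5 at LRT = 0).
- Standard errors of fixed effects come from σ̂²(XᵀW⁻¹X)⁻¹ at the fitted
  h (ML variance, no degrees-of-freedom correction).

## Pedigree kinship

The tabular recursion φ(i,i) = ½(1 + φ(f,m)), φ(i,j) = ½(φ(f,j) + φ(m,j))
is run in topological order within each family, founders mutually
unrelated, with full inbreeding support. All entries are dyadic rationals,
hence exact in binary floating point; the unit tests assert *equality*,
not closeness, for the canonical relationships, and cross-check inbred
pedigrees against a 10⁵-replicate gene-dropping Monte Carlo. Monozygotic
twins have no PED encoding, so an optional sidecar file lists MZ pairs
whose mutual relatedness is set to the diagonal value (their relations to
*other* relatives are left as the pedigree implies). Individuals appearing
only as parents become implicit founders with a warning.

## GSM handling

GRMs are read in the GCTA binary (float32 lower triangle) and gzipped-text
dialects and as plain labelled matrices. Bending is plain eigenvalue
clipping at ε = 1e-6 — deterministic, idempotent, and with a perturbation
exactly equal (in Frobenius norm) to the clipped eigenvalue deficits;
iterative weighted bending buys nothing here since only PSD restoration is
required. Thresholding zeroes off-diagonal entries below the cutoff and is
applied **before** bending when both are requested, so the repaired matrix
is the one actually used. Within-family permutation is meaningless without
family labels, so a GSM source silently downgrades the scheme to global
with a warning.

## Scan mechanics

Predictors are clustered by the combined (predictor | response |
covariate) missingness mask. Each cluster triggers at most one
eigendecomposition (cached across responses and clusters by mask) and one
null fit; the per-predictor path with clustering disabled takes the same
arithmetic route, which is why the equivalence test can demand bit
identity. Covariate effects are re-estimated in every null fit (exact, not
residualized once). Pairs with n below `min_n` (default 20) or a predictor
collinear with the covariates are flagged and skipped, never fatal.

## Permutations

Predictor values (never responses) are permuted; within families when a
pedigree is available, preserving the phenotypic correlation among
relatives under the null. Missing positions participate in the shuffle and
the missingness intersection is recomputed per permutation (decomposition
reuse makes the unchanged-mask case cheap). The empirical p is
(k+1)/(B+1) with ties counted as exceedances. The adaptive rule checks
after each batch (default 100, max 10,000) whether the one-sided 99%
Clopper–Pearson lower bound on the exceedance proportion exceeds the
target α (default 0.05); this is deterministic, conservative, and can
never fire while the observed statistic still beats every permutation.
Each (response, predictor) pair draws from its own seed stream derived
from the master seed and the pair's names (CRC32), so results are
independent of scan order and thread count.

## Region tests

Windows are built per chromosome, either as `size` consecutive predictors
advancing by `step` (a shorter trailing window is kept) or as half-open
base-pair intervals; windows never span chromosomes. Window members are
standardized (correlation PCA — members may be on different scales) on
complete cases, and the first principal component becomes the composite
predictor, sign-fixed so the largest-magnitude loading is positive (member
order cannot flip results) and rescaled to unit sample variance. Since the
association LRT is invariant to affine transformation of the predictor, a
size-1 window reproduces the single-predictor test to numerical precision.
Overlapping windows are statistically dependent; this is deliberately left
to the FDR stage.

## Pre- and post-processing

"Quantile normalization" is ambiguous between two standard readings, so
both exist: the default rank-based inverse-normal transform
Φ⁻¹((r−0.5)/n) per variable (average ranks for ties; missing values
excluded and preserved), and array-style cross-sample quantile
normalization onto the mean empirical distribution. Normalization is
applied to raw variables before any model fitting. Latent-confounder
correction takes the leading principal components of the (response, by
default) matrix until a user-specified percentage of variance is
explained, and enters them as fixed-effect covariates.

BH adjustment is the exact step-up q_i = min_{j≥i} m·p_j/j. Because the
pedigree covariance is block-diagonal, each model's log-likelihood is a
sum of per-family terms; the per-family contribution to the χ² statistic
is 2(ℓ_alt,f − ℓ_null,f) evaluated at each model's own fitted parameters,
so contributions sum to the total LRT by construction. The Gini
coefficient is computed on contributions clamped at zero (it needs
non-negative mass); the percentage of positively contributing families
uses raw signs. QQ plots use (i−0.5)/m expected quantiles and annotate
the genomic-inflation λ (reported, never applied).

## Simulator

The generator reproduces the three-generation, eight-member family design
(two grandparental couples, two parents, two full-sib offspring) and the
standard additive polygenic Gaussian trait model: per family,
g ~ N(0, h²·2Φ_f) via the family's Cholesky factor, i.i.d. environmental
noise sized so the total variance is 1, and an optional causal predictor
whose slope is √(variance fraction) on a standard-normal predictor.
Missingness is MCAR, optionally constrained to a small number of shared
masks to exercise clustering. Gene-dropping utilities provide the
independent oracles: an empirical kinship estimate and unlinked biallelic
genotypes from which the in-repo allelic-correlation GRM reference is
built.

What the simulations do **not** emulate: non-Gaussian traits,
ascertainment, dominance or shared-household variance, linkage
disequilibrium between gene-dropped markers, and informative missingness.
Passing tests therefore demonstrate correctness of the estimator and its
calibration under the stated model, not robustness to violations of it.

## Problem sizes and numerical defaults

Validation suites use 125 families (n = 1000) for calibration and
recovery (2000 and 500 replicates respectively), 50 random mixed-structure
instances of n ≤ 30 against the brute-force oracle, 500 exchangeable-null
datasets of n = 40 at 999 permutations for uniformity, and 50 families
with 800 gene-dropped markers for the pedigree-vs-GRM concordance — sizes
chosen so each property is measured with comfortable Monte-Carlo margin
on a single CPU. Key tolerances: eigendecomposition eigenvalues clipped at
−1e-10, identity detection at 1e-12, bending ε = 1e-6, profile-derivative
root at 1e-12 in h, LRT clamp at 1e-8.

## Known limitations

- ML (not REML) variance components are biased downward by the fixed-effect
  degrees of freedom.
- Dominance, shared-environment and GxE components are out of scope, as are
  multivariate (multi-response) models.
- The QR likelihood branch for singular covariances is a formal extension
  (pseudo-determinant); genuinely singular ω is better handled by bending.
- Base-pair windows enumerate start offsets linearly, which is fine for
  desk-scale maps but not optimized for whole-genome step-1 scans.
- Whether thresholding should precede bending is not externally specified;
  the chosen order (threshold, then bend) guarantees the final matrix is
  PSD.
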