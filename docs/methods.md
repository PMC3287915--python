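# Methods

## Model and procedure

For one gene with L variants and n unrelated individuals, the analysis has
four stages.

**Burden score.**  Minor-allele dosages are pooled into
`S_j = Σ_i I_ij / w_i` with `w_i = sqrt(n q̂_i (1 − q̂_i))` and the add-one
frequency estimate `q̂_i = (m_i + 1)/(2n + 2)` computed over all
individuals.  Estimating frequencies on everyone (rather than controls
only) keeps one score usable for quantitative traits and disease status
simultaneously.  The add-one estimator keeps `q̂ ∈ (0, 1)` so monomorphic
variants have a finite weight and simply contribute zero.  No rank-sum
standardization is applied to the score: the plain weighted dosage sum is
the scoring rule.  Minor-allele orientation is computed over all
individuals at read time; an exact 50% frequency tie keeps the file's
coding, which makes orientation idempotent and deterministic.

**Per-trait statistics.**  The score enters one regression per trait,
adjusted for covariates: OLS for quantitative traits (t statistic, residual
df = n − c − 2), ML logistic for binary traits (Wald z of the score
coefficient).  The t statistic is mapped to the normal scale through its
central CDF, `Z = Φ⁻¹(F_t(t; df))` — sign-preserving and monotone — while
the Wald z is already asymptotically N(0,1) and is used unchanged.  The
transform is evaluated through log survival functions, so extreme
statistics map to large finite quantiles instead of overflowing.

**Combined tests.**  Under the null, Z = (Z_1,…,Z_m) is approximately
N_m(0, Σ) with Σ the correlation matrix of Z induced by trait/covariate
correlations.  Σ is estimated by permutation: the whole phenotype row
(all traits and all covariates together) is permuted against the fixed
genotypes N times, Z is recomputed each time exactly as in the unpermuted
analysis, and Σ̂ is the sample correlation matrix (unit diagonal enforced)
of the permuted Z vectors.  Permuting the joint row preserves trait–trait
and trait–covariate structure while breaking the genotype link — exactly
the null being tested.  The quadratic statistic `T_Q = Zᵀ Σ̂⁻¹ Z` refers to
χ²_m; the linear statistic `T_L = 1ᵀZ/sqrt(1ᵀΣ̂1)` refers to N(0,1).  The
quadratic form is computed by Cholesky solve, never an explicit inverse.

**Optimal subset.**  `T_Q(A)` is evaluated for every trait subset A with
|A| ≥ 2 (2^m − m − 1 candidates; m is capped at 12, beyond which
enumeration is refused).  The subset with minimum χ²_{|A|} p-value is
selected; ties break toward the smaller subset, then lexicographic trait
order.  Because the minimum over subsets is optimistically biased, the
selected p-value is calibrated against a second, independent set of N₂
phenotype permutations in which the same minimization is repeated:
`p_OCMT = (1 + #{π : p*(π) ≤ p*})/(N₂ + 1)`.  The add-one form avoids
exact-zero p-values; permutations that tie the observed minimum count as
successes.  Σ̂ is *not* re-estimated inside each calibration permutation —
that would need N·N₂ nested refits and would not change the null
distribution of the min-p statistic, since the same Σ̂ is used for observed
and permuted selections alike.

## Key parameters

| parameter | default | role |
|---|---|---|
| `n_perm_sigma` | 1000 | permutations for Σ̂; correlation SE ≈ 0.03 at this N |
| `n_perm_ocmt` | 1000 | calibration permutations; p-value resolution 1/(N₂+1) |
| `alpha` | 0.05 | rejection level used by the power harness |
| `n_pcs` | 10 | principal components for stratification correction |
| regularization ε | 1e-6 | shrinkage `(1−ε)Σ̂ + εI` applied when the smallest eigenvalue of Σ̂ < 1e-8; one retry, then the gene is flagged degenerate |
| logistic cap / tol | 100 / 1e-8 | Newton iterations; convergence when the Newton decrement (the remaining log-likelihood improvement) < 1e-8 |

## Numerical and implementation choices

- **Permutation engine.**  Permuting the phenotype block by π equals
  permuting the score by π⁻¹ with phenotypes fixed (regressions are
  row-order invariant).  The implementation exploits this: the covariate
  design is factored once per trait (QR for OLS, warm-started batched
  Newton for logistic) and only the score column varies across
  permutations, so a full Σ̂ estimation at N = 1000 costs a few matrix
  products rather than a thousand independent refits.  The batched fits are
  checked against `statsmodels` in the test suite.
- **Missing data.**  Missing genotypes are imputed to zero minor alleles
  before scoring (with a count kept on the score object).  Missing trait or
  covariate values cause case-wise deletion per trait; because permutation
  is implemented on the score side, each trait's missingness pattern stays
  with the trait under permutation.
- **Degeneracies.**  Monomorphic genes (zero score variance), collinear or
  perfectly fitting designs, logistic separation (detected as a saturated
  linear predictor, |η| > 30, or unbounded coefficients) and non-PD Σ̂ after
  shrinkage degrade the affected cells or gene to NA with a status flag;
  they never abort a run.  With one usable trait the combined tests reduce
  exactly to the univariate test (Σ̂ ≡ [[1]]); OCMT requires m ≥ 2.
- **Determinism.**  Genes are processed in sorted-ID order and each gene's
  permutation streams derive from (global seed, gene index), so results are
  byte-identical across reruns and across serial vs. parallel execution,
  and a gene's numbers do not change when unrelated genes are added or
  removed from the map (as long as its sorted position is pinned).
- **Stratification.**  PCs come from the SVD of the frequency-normalized
  dosage matrix (column centered at 2p̂ and scaled by sqrt(2p̂(1−p̂))).
  Scores and quantitative traits are residualized on the PCs; binary traits
  keep their 0/1 coding and receive the PCs as extra logistic covariates,
  since residualizing a 0/1 outcome would break the logistic model.  LD
  pruning, iterative outlier removal and eigenvalue significance testing
  are not implemented; on the simulated discrete-subpopulation scenarios
  the plain SVD captures the ancestry axis essentially perfectly, which is
  easier than typical real data with gradients and relatedness.

## What the simulator does and does not emulate

The generator produces unrelated individuals, independent variants in
Hardy–Weinberg proportions with log-uniform rare MAFs (default
[5×10⁻⁴, 0.05], plus a configurable common fraction), correlated Gaussian
trait noise, three covariates (standardized age, sex, smoking) with modest
effects, a liability-threshold disease whose liability is a weighted sum of
the quantitative traits' *genetic* components plus noise (thresholded at
the empirical quantile matching the target prevalence, default 0.3), and
optional two-or-more subpopulation structure (Balding–Nichols
allele-frequency divergence plus trait-mean shifts).

It does **not** emulate LD between variants, relatedness/cryptic kinship,
non-Gaussian trait noise, genotyping error, or continuous ancestry
gradients.  Passing calibration and power checks on these simulations
therefore demonstrates correctness of the statistical machinery under its
own assumptions, not robustness to those real-data complications — the
burden score itself ignores LD, but Σ̂ estimation and PC correction could
behave differently under them.

Preset effect sizes are chosen analytically rather than by trial: a
quantitative-trait effect β per SD of score yields univariate
noncentrality ≈ β√n, so β = (z_{1−α/2} + z_{power})/√n targets a given
power; liability weights are scaled by 1/(m·φ(Φ⁻¹(1−K))/√(K(1−K))) so the
binary trait's induced univariate power roughly matches the quantitative
traits'.  The presets used by the tests and the acceptance script:
equal same-sign effects tuned to per-trait power ≈ 0.30 (pleiotropic
case), a single affected trait tuned to power ≈ 0.95, opposite-sign
effects on two traits tuned to per-trait power ≈ 0.5, and a confounded
null with F_ST = 0.1, trait shift 0.8 SD, and 150 common background
variants for PC estimation.

## Problem sizes used by the checks

The test suite's null-calibration study uses n = 500, m = 4 (three
quantitative traits + disease at prevalence 0.3), three covariates,
Σ̂ from N = 1000 permutations, 2000 replicates for CMT-Q/CMT-L (KS tests
and type-I error) and 500 replicates × N₂ = 500 for OCMT; power studies
use 400 replicates at N = 500; the stratification study 500 replicates.
`scripts/acceptance.py` repeats the same designs at 400/200 replicates,
N = 500, N₂ = 300.  All rejection-rate assertions use 99% binomial bands
at the corresponding replicate count.

## Known limitations

- Permutation assumes exchangeable individuals: family structure or
  cryptic relatedness would invalidate Σ̂ and the OCMT calibration.
- The χ²_m reference for T_Q ignores Monte-Carlo noise in Σ̂ (relative bias
  of order m/N); at N = 1000 this is negligible, but very small N would
  make T_Q slightly anticonservative — hence the warning below N = 100.
- The logistic Wald statistic is used as-is; for very rare binary outcomes
  or tiny samples a score or likelihood-ratio statistic would be better
  calibrated.
- OCMT's exhaustive enumeration is exponential in m; the hard cap of 12
  traits reflects the method's intended regime (a handful of traits).
- X-chromosome ploidy, dosage (non-integer) genotypes and multi-allelic
  records beyond biallelic splitting are out of scope at the reader level.
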