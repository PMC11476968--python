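# Methods

## Model

For one CpG and one SNP, bulk methylation (M-value scale) is modelled
without an intercept as

    M_i = Σ_c γ_c X_ic + Σ_k α_k W_ik + Σ_k β_k (W_ik · G_i) + ε_i,
    ε_i ~ N(0, φ),

with `W_ik` the proportion of cell type `k` in sample `i` (rows sum to 1)
and `G_i` the alternative-allele dosage. `β_k` is the genotype effect on
methylation *within* cell type `k`: the genotype-methylation association
strengthens with the abundance of the cell type carrying the effect.
Because proportions sum to one, an equivalent parameterisation uses an
intercept, `K−1` proportion columns, a main genotype effect `β̃_0` (the
reference cell type's effect) and `K−1` interaction contrasts; the linear
back-map `β_k = β̃_0 + β̃_k (k<K), β_K = β̃_0` recovers the cell-means
effects, and both forms are supported with the map recorded in the design
object.

### Priors

The `K` interaction coefficients carry a hierarchical shrinkage prior

    β | τ ~ N(μ, Σ),  Σ_jk = ρ_jk τ_j τ_k,
    τ_k² | s_k ~ Exp(s_k²/2),   s_k ~ Gamma(a, b_k),

which marginally is a Bayesian adaptive lasso: each `β_k` has a
double-exponential penalty centred at `μ_k` with its own data-adaptive
scale. Small `b_k` concentrates `s_k` at large values, i.e. stronger
shrinkage capacity; large `b_k` flattens the prior. Non-interaction
coefficients (covariates, proportion main effects, intercept) are nuisance
parameters with a fixed diffuse normal prior, mean 0 and variance 1e8 —
the prior rows exist so the augmented system is square, but they are
effectively unpenalised. Only the interaction block is hierarchical; this
is the design intent (the sparsity story concerns the cell-type effects).

Defaults: `a = 0.5` (the overall shrinkage is governed by `b_k`);
`b_k = 0.2` for abundant cell types (mean proportion above 10%), `b_k = 5`
for rare ones (below 5%) with linear interpolation between, appropriate
for moderate sample sizes — a rare cell type's coefficient is weakly
identified, and a too-eager prior would dominate it. For the large-n
three-cell-type simulation study the rates are `b = 0.005` (major cell
type) and `0.1` (others). Convergence tolerance `δ = 1e-5` on
`max|Δθ|`, iteration cap 500.

### EM-IWLS fitting

`(s_k, τ_k²)` are treated as missing data. The E-step uses the conditional
posteriors

    s_k | β_k        ~ Gamma(a+1, b_k + |β_k − μ_k|)
    1/τ_k² | s_k, β_k ~ InverseGaussian(s_k / |β_k − μ_k|, s_k²)

replacing both by their means, `E[s_k] = (a+1)/(b_k + |β_k − μ_k|)` and
`E[1/τ_k²] = s_k/|β_k − μ_k|`, with `|β_k − μ_k|` floored at 1e-8 so a
coefficient sitting exactly on its prior mean yields a finite (huge)
precision rather than a division by zero. With a correlated prior
(`ρ ≠ I`) the exact conditionals change; each `τ_k²` is updated by its
independent-case expectation and the prior covariance rebuilt as
`Σ33 = D ρ D`, `D = diag(τ_k)` — the stated conditional forms are used
unchanged, as presented.

The M-step augments the `n` data rows with `J` pseudo-observations:
`y* = [M; 0; μ]`, `X* = [X; I_J]`, `Cov(y*) = φ Σ*` with
`Σ* = blockdiag(I_n, Σ22/φ, Σ33/φ)` — the prior blocks carry `1/φ` so the
prior covariance itself is `φ`-free. The update is one weighted least
squares solve,

    θ̂ = (X*ᵀΣ*⁻¹X*)⁻¹ X*ᵀΣ*⁻¹ y*,
    φ̂ = (1/n) (y* − X*θ̂)ᵀ Σ*⁻¹ (y* − X*θ̂),

with divisor `n` (the data sample count, not `n+J`) and `φ̂` floored at
1e-12 for interpolating fits. Initialisation is OLS (ridge 1e-6 fallback
if singular) with `φ⁰` the OLS residual variance. At convergence,
`var(θ̂) = (X*ᵀΣ*⁻¹X*)⁻¹ φ̂`; cell-type effects are mapped to the
cell-means scale and tested two-sided against a standard normal
(large-sample Wald convention; the OLS comparator instead uses a t
reference on `n − J` degrees of freedom — documented difference). The
production loop solves the same normal equations through precomputed Gram
matrices (the design is iteration-invariant); a test verifies bit-level
agreement with the literal augmented-system path.

Numerical notes: conditioning of the normal equations is checked after
symmetric diagonal equilibration (prior precisions legitimately span many
orders of magnitude when a coefficient converges onto its prior mean;
genuine collinearity survives equilibration and raises). The prior
correlation matrix is repaired to positive definite by eigenvalue clipping
(floor scaled by K so the subsequent unit-diagonal rescale cannot undercut
1e-8) — note that repairing a strongly indefinite matrix necessarily moves
off-diagonals substantially. Non-convergence at the iteration cap is
reported (`converged=False`), never raised. Fits are fully deterministic.

A consequence of correlated designs worth knowing: coordinate-wise
soft-shrinkage (`|β̂_k| ≤ |β̂_k,OLS|`) is exact for orthogonal designs and
is property-tested there; in proportion-interaction designs the columns
are correlated, and shrinking a null coordinate can legitimately move
another coordinate past its OLS value.

## Priors from sorted-cell data

For cell types with sorted-cell methylation on a subsample, the per-SNP
effect `β̂_k,seq` is the least-squares slope of the sorted methylome on
dosage (t-based p-value), and

    μ_k = (1 − p_adjust) · β̂_k,seq,

with `p_adjust` Bonferroni (default; family = SNPs tested in the sorted
dataset) or BH as selected. Cross-cell-type prior correlation uses the
Pearson correlation of the two sorted methylomes at the CpG, weighted the
same way — a documented proxy, pluggable, since a small-sample genetic
correlation estimator is not uniquely defined at n ≈ 30-800. Cell types
without sorted data get `μ_k = 0` and zero prior correlation, reproducing
the uninformative prior exactly. Degenerate inputs (constant genotype,
fewer than 3 samples, all-missing methylation) return the null estimate
`(0, 1)`.

## Simulation study

The generator emulates a cis locus: 500 SNPs with MAF uniform on
[0.01, 0.5], drawn binomially under Hardy-Weinberg (optionally with latent
Gaussian AR(1) LD, thresholded per SNP and calibrated so adjacent
*genotype* correlation matches the requested value). Exactly
`round(prop_causal · p)` SNPs are causal. Effect scenarios: (1) effects
only in the most abundant cell type, (2) only in the least abundant, (3)
correlated effects in all cell types (compound-symmetric correlation 0.5).
Effects are drawn standard normal (scenario 3: multivariate normal) on the
*standardised-genotype* scale — the convention of variance-component
simulators — so rarer variants carry larger dosage-scale effects and
comparable variance explained; reported true effects are converted to the
dosage scale for direct comparison with fitted coefficients.

Within each causal cell type the methylome is the genetic value plus
Gaussian noise, rescaled so realised heritability is exactly h² = 0.3 and
total variance 1; non-causal cell types are pure noise of matching total
variance (the absolute methylation scale is not otherwise pinned; unit
variance makes the N(0, 0.01) bulk mixing noise a 1% perturbation).
Proportions are Dirichlet(5.30, 1.27, 1.62) (blood-like composition, mean
shares 0.647/0.155/0.198); bulk is the proportion-weighted mixture plus
noise, with the noise stored so the mixing identity is testable exactly.
A 5% simple random subsample carries observed sorted-cell methylomes.
Noisy-proportion experiments add half-normal noise, renormalise, and
calibrate the noise scale by bisection to a target mean absolute error.
Everything is bit-reproducible from `(config, seed)`.

What the generator does **not** emulate: real LD structure (independent
SNPs by default), bounded beta-values, array measurement error, covariate
confounding, or proportion-estimation error beyond the MAE perturbation —
so passing tests demonstrate correctness of the machinery and behaviour
under the stated generative model, not performance on any real cohort.

## Evaluation

Effect recovery is Pearson correlation and MSE between estimated and true
effect matrices. The study driver scores them over the causal SNP rows
(all cell-type columns): including the ~90% null rows would mostly measure
estimation noise on zeros and cannot reach the reference operating points;
both pooled and per-cell-type variants remain available in
`evaluation.effect_metrics` for other uses. Detection applies BH at 0.05
within each cell type's p-values and pools counts:
power = identified true signals / true signals, FDR = identified false /
identified (0 when nothing is selected). Replicate summaries are medians
(10 replicates per setting). The acceptance script runs the full study
size n = 15,918; the driver scales to smaller n for exploratory use.

## Scan and downstream statistics

The cis scan pairs SNPs to CpGs on the same chromosome within a closed
±500 kb window (1-based positions; a SNP at exactly 500 kb is included).
Dosages are mean-imputed per SNP up to 5% missingness; X/Y and
multi-allelic records are excluded at VCF import. Per-pair fit failures
are logged and emitted unconverged, never aborting the scan; pairs are
independent work units and output is invariant to sample and SNP order.
The genome-wide threshold helper is `α / n_pairs / n_celltypes`.
Replication against an external table joins on (SNP, CpG, cell type) and
reports sign consistency, replication (p < 0.05 and consistent sign) and
the effect correlation among replicated pairs, as percentages.

Functional enrichment uses Fisher's exact test on
`[[MR, R−MR], [M−MR, T−R−(M−MR)]]` with the two-sided p summing
hypergeometric probabilities not exceeding the observed table's, the
sample odds ratio with Haldane 0.5 correction for zero cells, and a Wald
CI on the log-OR (CI convention chosen, documented). Colocalization
enrichment is the ratio of the cell type's share among colocalized clumps
to its share among all clumps, tested one-sided (greater) by the
continuity-corrected two-proportion test (the signed square root of the
Yates chi-square against a standard normal).

## Known limitations

- Wald p-values for the hierarchical fit use a normal reference with no
  small-sample correction; post-shrinkage null p-values are conservative
  (which is why the empirical FDR under the global null sits near zero).
- The sorted-cell genetic-correlation estimator is a Pearson proxy.
- The scan is single-process; the independence contract makes external
  parallelisation safe but none is built in.
- Methylation beta-values must be transformed to M-values by the caller
  (`beta_to_mvalue` is provided); the model is linear-Gaussian on that
  scale.
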