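# ctsmeqtl

Cell-type-specific methylation QTL (meQTL) mapping from **bulk** tissue.

Bulk DNA methylation is measured on a cell mixture, so a genotype effect
confined to one cell type is diluted in proportion to that cell type's
abundance. Given cell-type proportions `W_k` (rows summing to 1), the bulk
M-value at a CpG is modelled as

```
M = Σ_c γ_c X_c + Σ_k α_k W_k + Σ_k β_k (W_k · G) + ε,     ε ~ N(0, φ)
```

where `G` is the SNP dosage (0/1/2) and the interaction coefficients `β_k`
are the cell-type-specific genotype effects of interest. Because minor cell
types contribute little variance, `β_k` for rare cells is poorly identified
by least squares. This package fits the model with a **hierarchical
Bayesian adaptive-lasso prior** on `β`: conditionally normal,
`β | τ ~ N(μ, Σ)` with `Σ_jk = ρ_jk τ_j τ_k`, `τ_k² | s_k ~ Exp(s_k²/2)`,
`s_k ~ Gamma(a, b_k)`, which marginally places a coefficient-specific
double-exponential penalty around `μ_k`. The posterior mode is found by
EM-IWLS: the E-step replaces `(s_k, 1/τ_k²)` by their Gamma /
inverse-Gaussian conditional means, the M-step solves one weighted
least-squares problem on the data rows augmented with `J` prior
pseudo-observations, and Wald inference uses
`var(θ̂) = (X*ᵀΣ*⁻¹X*)⁻¹ φ̂`.

When sorted-cell (cell-type-specific) methylation is available for a small
subsample, the prior is sharpened: `μ_k = (1 − p_adjust) · β̂_k,seq` from
regressing the sorted methylome on the dosage, with analogous weighting of
cross-cell-type prior correlations.

The package also ships the OLS interaction comparator, a seeded simulation
study generator (genotypes, heritability-calibrated cell-type methylomes,
Dirichlet proportions, bulk mixing), evaluation metrics (effect recovery,
BH power/FDR), a cis-scan driver with replication statistics, and the
downstream enrichment statistics (Fisher 2×2 functional enrichment,
cell-type colocalization enrichment with a continuity-corrected
proportions test).

## Worked example

```python
import numpy as np
from ctsmeqtl import (ScenarioConfig, simulate_dataset, build_interaction_design,
                      fit_hierarchical_interaction, fit_ols_interaction, HyperParams)

data = simulate_dataset(ScenarioConfig(scenario=1, n_samples=4000, seed=7))
j = np.abs(data.true_effects).sum(axis=1).argmax()   # strongest causal SNP
design = build_interaction_design(data.bulk, data.proportions, data.genotypes[:, j])
hyper = HyperParams(a=0.5, b=np.array([0.005, 0.1, 0.1]))
hbi = fit_hierarchical_interaction(design, hyper=hyper)
ols = fit_ols_interaction(design)
print("true  ", np.round(data.true_effects[j], 3))
print("hbi   ", np.round(hbi.cts_effects, 3), "p =", np.format_float_scientific(hbi.cts_p[0], 2))
print("ols   ", np.round(ols.cts_effects, 3))
```

prints

```
true   [-0.697  0.     0.   ]
hbi    [-0.699 -0.    -0.   ] p = 7.03e-18
ols    [-0.589 -0.105 -0.348]
```

The SNP is causal only in the most abundant cell type (the first column).
The hierarchical fit recovers that effect and shrinks the two null
coefficients essentially to zero, while OLS leaves sizeable noise in them —
exactly the behaviour that drives the method's higher effect-recovery
correlation and controlled false discovery rate in the simulation study.

Estimators follow scikit-learn conventions
(`BayesianInteractionModel(...).fit(design)` with `cts_effects_`,
`cts_p_`, … fitted attributes) and a thin CLI (`ctsmeqtl simulate | fit |
build-priors | scan | evaluate | enrich`) wraps the library.

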