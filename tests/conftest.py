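import numpy as np
import pytest

from ctsmeqtl import build_interaction_design


def make_locus(seed, n=200, K=3, C=0, beta=(0.5, 0.0, 0.0), noise=0.3, maf=0.3):
    """Small single-SNP dataset generated exactly from the cell-means model."""
    rng = np.random.default_rng(seed)
    W = rng.dirichlet((5.3, 1.27, 1.62)[:K] if K <= 3 else np.ones(K), n)
    g = rng.binomial(2, maf, n).astype(float)
    cov = rng.standard_normal((n, C)) if C else None
    gamma = rng.standard_normal(C) if C else np.zeros(0)
    alpha = rng.standard_normal(K)
    beta = np.asarray(beta, dtype=float)
    y = W @ alpha + (W * g[:, None]) @ beta + noise * rng.standard_normal(n)
    if C:
        y = y + cov @ gamma
    return y, W, g, cov, alpha, beta


@pytest.fixture
def small_design():
    y, W, g, cov, _, _ = make_locus(7, n=300)
    return build_interaction_design(y, W, g, covariates=cov)
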