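"""Screen genotype principal components as candidate known covariates.

Builds a genotype matrix with population structure (two sub-populations),
simulates expression data in which genotype PC1 has a real effect, then
screens the top genotype PCs by the variance beta^2 each explains alone,
keeping those with beta^2 >= theta * tr(C).  PCs without an expression
effect fall below the threshold even when they carry genotype variance.
"""

import numpy as np

import remlvc as rv
from remlvc.screening import genotype_pcs, screen_covariates

rng = np.random.default_rng(7)
n, n_snps, m = 80, 500, 2000

# two subpopulations with different allele frequencies
pop = rng.integers(0, 2, n)
freq = np.where(pop[:, None] == 1, 0.7, 0.3)
G = (rng.uniform(size=(n, n_snps)) < freq).astype(float)

pcs, genotype_fractions = genotype_pcs(G, k=5)
print("genotype variance explained by PCs:", np.round(genotype_fractions, 3))

# expression: PC1 of the genotypes drives 5x the residual variance
noise = rng.standard_normal((n, m))
Y = pcs.values[:, [0]] * np.sqrt(5.0) @ rng.standard_normal((1, m)) + noise
Y = rv.center_samples(Y)
C = rv.sample_covariance(Y)

kept, report = screen_covariates(C, pcs, theta=0.02)
print("\nscreening report (theta = 0.02, i.e. 2% of tr(C)):")
print(report.to_frame().round(4).to_string(index=False))
print(f"\nkept {kept.d} of {len(report.covariate_ids)} candidates: {kept.covariate_ids}")
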