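# Methods

## Model

Expression data **Y** ∈ ℝⁿˣᵐ (n samples, m genes; m > n assumed) is
modeled as

    Y = Z V + X W + ε

with known covariates **Z** ∈ ℝⁿˣᵈ, latent factors **X** ∈ ℝⁿˣᵖ, and, per
gene i, jointly normal effects (vᵢ, wᵢ) ~ N(0, [[B, D], [Dᵀ, A]]) and iid
noise ε ~ N(0, σ²). Integrating the effects out, each gene is an
independent draw from N(0, K) with

    K = Z B Zᵀ + Z D Xᵀ + X Dᵀ Zᵀ + X A Xᵀ + σ² I,

and the log-likelihood given C = Y Yᵀ / m is, up to additive constants,

    L(X, A, B, σ² | Y, Z) = −log det K − tr(K⁻¹ C).

We implement L exactly in this form (no 1/2, no m factor, no additive
constant): every use in the package — argmax identities, curve
comparisons, dominance checks — depends only on likelihood differences,
for which the normalization cancels.

Samples are centered to mean zero (per *row* of Y); gene-wise centering is
deliberately not applied. Centering removes the need for fixed effects on
the mean. Since K is full rank whenever σ² > 0, row-centering does not
make C singular; it perturbs C relative to K by O(1/m) (the per-sample
mean over genes has variance Kᵢᵢ/m), which is why simulator-convergence
tests state "up to the centering correction".

Allowing D ≠ 0 (correlated known and latent effects) is what makes the
orthogonal representation possible: any latent factor overlapping
span(Z) can be absorbed into the known-covariate effects by a linear
reparameterization of (B, D) that leaves K unchanged
(`orthogonalize_latents` implements this constructively through the
eigendecomposition of the non-noise part of K compressed to the complement
of span(Z)). A is always reducible to diagonal form by the rotational
symmetry of the latent factors; B is reported in the user's original Z
coordinates (via SVD back-substitution through the retained singular
values, with zero rows/columns for redundant directions), because known
covariates are "natural" measured variables with no such symmetry.

## Estimation

1. **Subspace split.** SVD of Z gives an orthonormal basis Q₁ of span(Z)
   (rank r at tolerance 1e−10 relative to the top singular value — near
   collinear covariates collapse) and a basis Q₂ of the complement.
2. **Latent factors (REML step).** With X ⊥ span(Z), the likelihood
   decomposes as L = L₁ + L₂ where L₂ is the probabilistic-PCA likelihood
   of C₂ = Q₂ᵀ C Q₂. Maximizing L₂ gives X̂ = Q₂ · (top-p eigenvectors of
   C₂): PPCA on the restricted subspace. We report L₂ as
   −log det(K̂₂) − tr(K̂₂⁻¹ C₂) with K̂₂ = Q₂ᵀ K̂ Q₂, and L₁ = L − L₂.
3. **Covariance parameters.** Treating (Z, X̂) as known covariates, the
   analytic maximizer is K̂ = P̃ C P̃ + σ̂² (I − P̃) with P̃ the projector onto
   span(Z) ⊕ span(X̂) and σ̂² the mean eigenvalue of C on the excluded
   n − r − p dimensions (this matches the L₁ + L₂ decomposition: the
   residual is estimated from the complement dimensions only). Matching
   blocks of GᵀK̂G for G = [Q₁, X̂] yields A = diag(λᵢ(C₂) − σ̂²),
   D = V S⁻¹ Q₁ᵀ C X̂ and B = V S⁻¹ (Q₁ᵀCQ₁ − σ̂² I) S⁻¹ Vᵀ, and
   `build_K(Z, X̂, ·)` reproduces K̂ to machine precision.
4. **Choosing p.** Given a target fraction ρ ∈ (0, 1) of tr(C), p is the
   smallest integer with (tr(Q₁ᵀCQ₁) + Σᵢ≤p λᵢ(C₂)) / tr(C) ≥ ρ, capped at
   n − r − 1 so the residual stays positive (ρ = 1 is rejected for the
   same reason). The maximizer exists only if every principal axis of
   span(Z) and every retained eigenvalue of C₂ explains strictly more than
   σ̂²; if not, p is incremented one at a time (which lowers σ̂²) until the
   condition holds. This *saturation* overshoots ρ and is reported with a
   warning — the cue that some known covariates are noninformative or
   redundant and should be re-screened.

The REML solution is not guaranteed to be the absolute maximizer of the
total likelihood: step 2 optimizes L₂ alone, while σ² couples L₁ and L₂.
It is, however, the minimizer of unexplained variance among all choices
of p latent factors in the complement, and the gap to the exact in-class
maximizer shrinks as O(1/m): at C = K the REML solution attains the
unconstrained optimum K̂ = C exactly. Empirically (see the dominance test)
the gap is below 1e−6 in likelihood units at transcriptome-scale gene
counts (m ≈ 5000) for n ≤ 20.

### Covariate screening

With more candidate covariates than samples, any n independent candidates
explain all of C, so candidates are screened first. The single-covariate
model K = β² z zᵀ + σ² I has the closed-form maximizer
σ̂² = (tr C − zᵀCz)/(n − 1), β̂² = zᵀCz − σ̂² (clipped at zero and flagged
when negative — the covariate explains less than the residual). A
candidate is kept when β̂² ≥ θ · tr(C); interpreting θ as a fraction of
tr(C) makes it scale-free. Screening is one-at-a-time by design; joint
redundancy among survivors is caught downstream by the rank tolerance and
the existence condition. For genetic covariates, screening is applied to
L2-normalized genotype PCs (left singular vectors of the sample-centered
genotype matrix) rather than raw SNPs; a raw-SNP mode exists but warns
about collinearity.

## Synthetic data generator

`simulate` draws exactly from the generative model: Z and the true X are
orthonormal frames from the QR decomposition of a Gaussian matrix (X in
the complement of span(Z)); a 'correlated' mode gives Z columns a
prescribed pairwise correlation instead. Effects are drawn with the block
covariance [[B, D], [Dᵀ, A]] via its symmetric PSD square root, noise is
iid Gaussian, and Y is row-centered like real preprocessed data. All
randomness flows through one `numpy` Generator seeded from the spec; the
same spec is bit-reproducible.

`default_components(d, p, sigma2)` supplies well-separated ground truth:
known-effect variances 6, 4.5, 3 …, mildly correlated effects
(off-diagonal 0.4), latent-effect variances 5, 3.8, 2.6 … (all distinct
and well above σ² = 1 so every planted direction is identifiable), D = 0.
`expression_with_covariance` constructs Y with an exactly prescribed
sample covariance (gene directions orthogonal to the ones vector, so rows
are centered without perturbing C) for tests needing a known spectrum.

What the generator does *not* emulate: non-Gaussian expression noise,
gene-gene correlation beyond the shared sample factors, mean effects,
missing values, and discrete genotype structure within Z. Passing tests
demonstrate correctness of the estimator under the model's own
assumptions, not robustness to their violation.

## Test problem sizes

Structural identities (shift, PPCA limit, orthogonality, minimal
unexplained variance) hold exactly and are checked at n = 20–100,
m = 300–1000. The dominance suite compares against a quasi-Newton
maximizer (L-BFGS-B on K = F Fᵀ + σ² I, F = [Q₁, X] L with L lower
triangular, analytic gradients, 10 restarts, gradient tolerance 1e−10) on
50 instances with n ≤ 20 and m = 5000, mirroring transcriptome-scale gene
counts. Parameter recovery uses n = 50, d = 2, p = 3, m up to 50 000.

## Numerical choices

- Spectral decompositions use the symmetric eigensolver; eigenvalues of C
  below −1e−10·tr(C)/n raise an error (C is PSD by construction; large
  negatives mean corrupt input), small negatives are clipped to zero.
- Positive-definiteness for likelihood evaluation: smallest eigenvalue
  > 1e−12 × largest; the log-likelihood is computed from the
  factorization, never an explicit inverse.
- Eigenvector sign convention: the entry of largest magnitude in each
  column is made positive, for reproducible output across platforms.
  Degenerate eigenvalues keep the eigensolver's stable order; factors
  within a tied eigenspace are non-unique up to rotation.
- Rank of Z: singular values ≤ 1e−10 × s_max are dropped.
- If m ≤ n the fit proceeds with a prominent warning (C is singular, the
  unconstrained-optimum property fails).
- `fit` accepts either ρ (automatic p) or an explicit p; the explicit
  form exists for likelihood-curve analyses.

## Limitations

- The latent factors are identified only up to the model's inherent
  symmetry: whether the *true* confounders overlap the known covariates
  cannot be decided from K̂, only a canonical orthogonal representative is
  returned.
- The numeric oracle is a test instrument for small n; it is not exposed
  as a fitting path and scales poorly.
- No missing-data handling, no sparse matrices, no VCF/PLINK parsing
  (genotypes enter as numeric matrices).
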