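"""Absorbing latent-covariate overlap into the known-covariate effects.

Any random-effects model whose latent factors overlap span(Z) can be
rewritten, without changing the model covariance K, as an equivalent model
whose latent factors are orthogonal to Z — the overlap moves into the
known-effect covariances B and D.  This is why latent factors returned by
the REML solver are guaranteed not to be redundant with known covariates.
"""

import numpy as np

import remlvc as rv

rng = np.random.default_rng(3)
n, d, p = 12, 2, 2
Z = np.linalg.qr(rng.standard_normal((n, d)))[0]
# latent factors deliberately contaminated with the known covariates
X_raw = np.linalg.qr(rng.standard_normal((n, p)) + Z @ rng.standard_normal((d, p)) * 2)[0]
joint = rng.standard_normal((d + p, d + p))
joint = joint @ joint.T + 0.5 * np.eye(d + p)
vc_raw = rv.VarianceComponents(B=joint[:d, :d], D=joint[:d, d:],
                               A=joint[d:, d:], sigma2=1.0)

print(f"overlap before: max |cos(X, Z)| = {rv.max_abs_cosine(X_raw, Z):.3f}")
X_new, vc_new = rv.orthogonalize_latents(Z, X_raw, vc_raw)
print(f"overlap after:  max |cos(X, Z)| = {rv.max_abs_cosine(X_new.values, Z):.3e}")

K_before = rv.build_K(Z, X_raw, vc_raw)
K_after = rv.build_K(Z, X_new, vc_new)
print(f"model covariance preserved: max |K' - K| = {np.abs(K_after - K_before).max():.2e}")
print(f"A re-diagonalized: {np.allclose(vc_new.A, np.diag(np.diag(vc_new.A)))}")
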