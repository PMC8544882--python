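"""Principal-component regression with a planted, known effect.

Builds a morphology matrix whose leading axis is a known latent variable,
plants a log-link effect of that axis on a gamma-distributed response, and
shows that standardize -> PCA -> gamma GLM recovers the planted
coefficients, with the deviance pseudo-R^2 and bootstrap diagnostics.
"""

from coralith import (
    PlantedEffectSpec,
    fit_gamma_glm,
    generate_planted_dataset,
    pca,
    simulate_residual_diagnostics,
    standardize,
)

spec = PlantedEffectSpec(b0=1.0, b_pc1=0.5, b_pc2=-0.3, family="gamma-log",
                         shape=5.0, n_per_species=10, seed=7)
data = generate_planted_dataset(spec)

std = standardize(data.morphology)
pc = pca(std)
print("variance explained: "
      + ", ".join(f"PC{i+1} {100*f:.1f}%" for i, f in enumerate(pc.variance_fraction[:3])))
print("PC1 loadings (beta):")
for var, b in zip(pc.variable_names, pc.loadings[:, 0]):
    print(f"  {var:22s} {b:+.3f}")

fit = fit_gamma_glm(data.responses, pc.scores[:, :2])
print(f"\nplanted (b0, b_PC1, b_PC2) = ({spec.b0}, {spec.b_pc1}, {spec.b_pc2})")
for name, b, se, t, p in zip(fit.param_names, fit.coefficients, fit.se, fit.t, fit.p):
    print(f"  {name:9s} estimate {b:+.3f}  se {se:.3f}  t {t:+.2f}  p {p:.2e}")
print(f"dispersion phi = {fit.phi:.3f} -> shape alpha = 1/phi = {fit.alpha_shape:.2f} "
      f"(truth {spec.shape})")
print(f"pseudo-R^2 = 1 - deviance/null deviance = {fit.pseudo_r2:.3f}")

diag = simulate_residual_diagnostics(fit, n_sims=250, seed=7)
print(f"parametric-bootstrap diagnostics: dispersion p = {diag.dispersion_p:.3f}, "
      f"residual-uniformity p = {diag.uniformity_p:.3f}")
print("large p-values: no evidence the gamma-log model is misspecified.")
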