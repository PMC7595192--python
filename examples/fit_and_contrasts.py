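"""Fit the lagged kernel machine regression and estimate percentile contrasts.

Generates a cohort whose only true signal is a linear Mn effect in the
third (infant) window, runs the fixed preparation pipeline (LOD/2
imputation, log2, standardization), fits the model by mean-field
variational Bayes and prints the main-effect contrast for every metal and
window with its 95% credible interval.
"""

from lagkmr import (
    GeneratorConfig,
    all_main_effects,
    fit_mfvb,
    generate_cohort,
    prepare,
    single_linear_surface,
    true_contrast,
)

config = GeneratorConfig(
    n_subjects=400, surface=single_linear_surface("Mn", 3, 0.23), seed=7,
)
table, truth = generate_cohort(config)
design = prepare(table)

fit = fit_mfvb(design)
print(f"converged in {fit.n_iterations} iterations "
      f"(final ELBO {fit.elbo_trace[-1]:.2f}); residual variance "
      f"E[sigma^2] = {fit.sigma2_mean:.3f}")

print("\nmain effects (q75 vs q25, co-metals at medians; standardized units):")
print(f"{'metal':>6} {'window':>18} {'estimate':>9} {'95% CrI':>18}")
for est in all_main_effects(fit):
    flag = " *" if est.significant else ""
    print(f"{est.metal:>6} {est.window:>18} {est.estimate:>+9.3f} "
          f"[{est.cri95_lower:+.3f}, {est.cri95_upper:+.3f}]{flag}")

tv = true_contrast(truth, "Mn", 3)
print(f"\ntrue Mn infant contrast: {tv:+.3f}; the fitted estimate is smaller "
      "because the fused-lasso prior shares a single-window signal with the "
      "neighboring windows (see docs/methods.md).")
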