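"""Validate the variational approximation against the Gibbs oracle.

On a small two-window fixture, compares posterior means of the window
surfaces and regression coefficients from mean-field variational Bayes with
long-run averages from the blocked Gibbs sampler over the identical model.
Means should agree closely; mean-field posterior SDs are expected to be
slightly smaller (the documented cost of the factorized approximation).
"""

import numpy as np

from lagkmr import GibbsConfig, fit_gibbs, fit_mfvb, generate_cohort, prepare
from lagkmr.synthetic import GeneratorConfig, SurfaceSpec
from lagkmr.evaluation import SMALL_COVARIATES

config = GeneratorConfig(
    n_subjects=40, metals=["As", "Mn", "Se"],
    windows=["maternal_prenatal", "infant"], covariates=list(SMALL_COVARIATES),
    surface=SurfaceSpec(linear=(("Mn", 2, 0.3), ("As", 1, -0.2))), seed=1,
)
table, _ = generate_cohort(config)
design = prepare(table)

fit = fit_mfvb(design, solver="dense")
draws = fit_gibbs(design, config=GibbsConfig(n_iterations=25_000, n_burnin=5_000, seed=2))

print(f"MFVB: {fit.n_iterations} iterations; Gibbs: {draws.n_draws} retained draws")
print(f"max |E[h] difference|:    {np.abs(fit.m_h - draws.h_mean()).max():.4f}")
print(f"max |E[beta] difference|: {np.abs(fit.m_beta - draws.beta_mean()).max():.4f}")
mfvb_sd = np.mean([np.sqrt(np.diag(S)).mean() for S in fit.sigma_h])
print(f"mean posterior SD of h:   MFVB {mfvb_sd:.3f} vs Gibbs {draws.h.std(0).mean():.3f}")
print("\ndifferences well below 0.05 standardized units indicate the "
      "coordinate-ascent updates target the same posterior the sampler explores.")
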