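# lagkmr

Lagged kernel machine regression for time-varying environmental mixtures,
fit by mean-field variational Bayes.

## The problem

Prenatal exposure to mixtures of essential and toxic metals may disturb
child neurodevelopment, and *when* an exposure occurs can matter as much
as how large it is.  Biomarkers such as toenail clippings collected at
several points in pregnancy and early infancy give a low-resolution
time series of exposure to many correlated metals at once.  Relating such
a time-varying mixture to a single continuous outcome (a behavioral raw
score at age three, say) requires a model that can (i) control co-metal
confounding within each collection window, (ii) allow nonlinear
dose–response and metal–metal interaction, (iii) borrow strength between
neighboring windows while still letting effects differ by window, and
(iv) quantify uncertainty.  This package is for environmental
epidemiologists and biostatisticians who need that analysis as a tested,
reusable library rather than a one-off script.

## The model

For subject $i$ with outcome $y_i$, covariates $x_i$ and standardized
log2 exposures $z_{it}$ over windows $t = 1..T$:

$$ y = X\beta + \sum_{t=1}^T h_t + \varepsilon, \qquad
   \varepsilon \sim \mathcal N(0, \sigma^2 I), $$

with each window's exposure–response function $h_t$ living in the RKHS of
the quadratic kernel $k(z,z') = (1 + \langle z,z'\rangle)^2$.  A Bayesian
**group lasso** shrinks each window's function norm
$\lVert h_t\rVert_{K_t}$ (within-window regularization) and a Bayesian
**fused lasso** shrinks $\lVert h_{t+1} - h_t\rVert$ (smooth evolution
across neighboring windows), both via scale mixtures of normals with
Gamma hyperpriors on the squared penalties
($\lambda_1^2 \sim \Gamma(60, 10)$, $\lambda_2^2 \sim \Gamma(45, 10)$).
Inference is coordinate-ascent mean-field variational Bayes with an exact
closed-form evidence lower bound (stopping parameter $10^{-7}$, at most
200 iterations); a blocked Gibbs sampler over the identical model serves
as a validation oracle.  Effects are reported as percentile contrasts:
the change in predicted outcome when one metal moves from its 25th to its
75th percentile, co-metals fixed at their medians, with 95% credible
intervals — plus interaction double-differences and dose–response
cross-sections.  See `docs/methods.md` for the full construction.

Because the motivating cohort's data are available only on request, the
package ships a synthetic cohort generator that reproduces the analysis'
statistical structure (right-skewed correlated concentrations, detection
limits, covariates, configurable true surfaces) together with the exact
true value of every contrast the estimators target — so the whole
pipeline is testable end to end.

## Worked example

```python
from lagkmr import (GeneratorConfig, single_linear_surface, generate_cohort,
                    prepare, fit_mfvb, all_main_effects, true_contrast)

config = GeneratorConfig(n_subjects=400,
                         surface=single_linear_surface("Mn", 3, 0.23), seed=7)
table, truth = generate_cohort(config)     # cohort + ground truth
fit = fit_mfvb(prepare(table))             # impute LOD/2 -> log2 -> standardize -> fit
for est in all_main_effects(fit):
    print(est.metal, est.window, f"{est.estimate:+.3f}",
          f"[{est.cri95_lower:+.3f}, {est.cri95_upper:+.3f}]")
```

Running `python examples/fit_and_contrasts.py` (this exact analysis)
prints, abbreviated:

```
converged in 19 iterations (final ELBO -2477.98); residual variance E[sigma^2] = 0.941

 metal             window  estimate            95% CrI
    Mn  maternal_prenatal    -0.050 [-0.146, +0.046]
    Mn maternal_postnatal    +0.007 [-0.078, +0.092]
    Mn             infant    +0.092 [-0.011, +0.195]
    Zn             infant    -0.008 [-0.113, +0.096]
    ...

true Mn infant contrast: +0.274
```

Reading: the only planted signal is a linear Mn effect in the infant
window with a true 75th-vs-25th percentile contrast of +0.27 standardized
outcome units.  The fit attributes the largest estimate to exactly that
cell (+0.092) and near-zero estimates elsewhere, but shrinks the contrast
substantially — the fused-lasso prior shares single-window signals with
neighboring windows (next section).

Other narrative examples in `examples/`: cohort simulation, dose–response
curvature, sex-stratified analysis, parametric corroboration by OLS on
IQR-scaled concentrations, and the MFVB-versus-Gibbs cross-check.  A thin
CLI (`lagkmr simulate|fit|effects|corroborate|run|report`) drives the same
pipeline from YAML configs and writes CSV/JSON result bundles.

## Known shrinkage behavior

Under the prescribed hyperparameters the fused-lasso's adaptive precision
is comparable to the likelihood precision at realistic effect sizes
(≈0.3 SD, n≈400).  Two measured consequences, reproduced by the Gibbs
oracle and therefore properties of the exact posterior rather than of the
variational approximation: a contrast confined to a single window is
attenuated by roughly half (mean absolute error 0.16 against the bound
0.05, CrI coverage 7% against the 80–99% band), and a signal-free window
retains about 0.65 of the signal window's norm (bound 0.5).  The
corresponding tests in `tests/test_acceptance.py` fail deliberately;
`docs/methods.md` gives the quantitative analysis.  For signals believed
to be concentrated in one window, compare against the
`LKMRHyperparameters(fused=False)` variant, which recovers such contrasts
almost exactly.

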