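"""Simulation studies that characterize the estimator.

These are the package's own operating-characteristic checks -- ELBO
monotonicity across model shapes, agreement with the Gibbs oracle,
parameter recovery and interval coverage, null calibration, shrinkage
structure and interaction recovery -- run on cohorts from
:mod:`lagkmr.synthetic` under the study conditions (six metals at three
windows unless a smaller shape is the point of the check).  The same
functions drive the test suite and ``scripts/acceptance.py``; simulation
sizes are documented in docs/methods.md.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .corroboration import CorroborationSpec, fit_corroboration
from .estimands import interaction_effect, main_effect
from .gibbs import GibbsConfig, fit_gibbs
from .kernels import KernelSpec
from .model import LKMRHyperparameters, fit_mfvb
from .preprocessing import prepare
from .synthetic import (
    CovariateSpec,
    GeneratorConfig,
    SurfaceSpec,
    generate_cohort,
    null_surface,
    single_linear_surface,
    true_contrast,
)

logger = logging.getLogger(__name__)

#: small covariate set for compact fixtures (keeps p << n at n = 25)
SMALL_COVARIATES = [
    CovariateSpec("age", "continuous", mean=32.0, sd=4.5, role="quadratic"),
    CovariateSpec("sex", "categorical", levels=("female", "male"), probs=(0.5, 0.5),
                  role="categorical"),
]

#: the model shapes exercised by the ELBO monotonicity sweep
ELBO_SWEEP_CONFIGS = [
    # (T, M, n)
    (1, 2, 25), (1, 3, 100), (1, 6, 400),
    (2, 2, 25), (2, 3, 100), (2, 6, 400),
    (3, 2, 25), (3, 3, 100), (3, 6, 400),
    (3, 3, 25),
]


def _seed(base: int, i: int) -> int:
    return (base * 100_003 + i) % (2**31 - 1)


def _sweep_cohort(T: int, M: int, n: int, seed: int):
    metals = ["As", "Cu", "Mn", "Pb", "Se", "Zn"][:M]
    windows = ["maternal_prenatal", "maternal_postnatal", "infant"][:T]
    terms = dict(
        linear=((metals[0], 1, 0.25),),
        quadratic=((metals[-1], T, 0.10),),
    )
    if M >= 2:
        terms["interactions"] = ((metals[0], metals[1], T, 0.10),)
    cfg = GeneratorConfig(
        n_subjects=n, metals=metals, windows=windows,
        covariates=list(SMALL_COVARIATES), surface=SurfaceSpec(**terms), seed=seed,
    )
    table, _ = generate_cohort(cfg)
    return prepare(table)


def elbo_monotonicity_study(seed: int = 0, max_iterations: int = 200) -> pd.DataFrame:
    """Fit every sweep configuration and record ELBO monotonicity.

    ``monotone`` is True when every iteration-to-iteration change is above
    -1e-6 relative slack.  Both posterior solver paths are exercised (the
    automatic selection picks dense for small problems, the low-rank path
    for large ones).
    """
    rows = []
    for i, (T, M, n) in enumerate(ELBO_SWEEP_CONFIGS):
        design = _sweep_cohort(T, M, n, _seed(seed, i))
        hyper = LKMRHyperparameters(max_iterations=max_iterations)
        fit = fit_mfvb(design, hyper)
        trace = fit.elbo_trace
        deltas = np.diff(trace)
        slack = 1e-6 * np.abs(trace[:-1])
        rows.append({
            "T": T, "M": M, "n": n,
            "n_iterations": fit.n_iterations,
            "converged": fit.converged,
            "monotone": bool(np.all(deltas >= -slack)),
            "min_delta": float(deltas.min()) if deltas.size else 0.0,
        })
    return pd.DataFrame(rows)


def oracle_comparison_study(
    seed: int = 0, n: int = 40, n_draws: int = 50_000, n_burnin: int = 5_000,
) -> dict:
    """MFVB versus long-run Gibbs on a small two-window fixture.

    Returns the maximum absolute discrepancy of the posterior means of h and
    beta (standardized outcome units) and the posterior-SD ratio (mean-field
    SDs are expected to be no larger on average).
    """
    cfg = GeneratorConfig(
        n_subjects=n, metals=["As", "Mn", "Se"],
        windows=["maternal_prenatal", "infant"],
        covariates=list(SMALL_COVARIATES),
        surface=SurfaceSpec(linear=(("Mn", 2, 0.3), ("As", 1, -0.2))),
        seed=_seed(seed, 1),
    )
    table, _ = generate_cohort(cfg)
    design = prepare(table)
    fit = fit_mfvb(design, solver="dense")
    draws = fit_gibbs(
        design,
        config=GibbsConfig(n_iterations=n_burnin + n_draws, n_burnin=n_burnin,
                           seed=_seed(seed, 2)),
    )
    h_diff = float(np.abs(fit.m_h - draws.h_mean()).max())
    beta_diff = float(np.abs(fit.m_beta - draws.beta_mean()).max())
    mfvb_sd = float(np.mean([np.sqrt(np.diag(S)).mean() for S in fit.sigma_h]))
    gibbs_sd = float(draws.h.std(axis=0).mean())
    return {
        "max_abs_diff_h": h_diff,
        "max_abs_diff_beta": beta_diff,
        "mfvb_h_sd": mfvb_sd,
        "gibbs_h_sd": gibbs_sd,
        "n": n,
        "n_draws": draws.n_draws,
    }


def recovery_study(
    seed: int = 0, n: int = 400, n_reps: int = 100, slope: float = 0.23,
    metal: str = "Mn", window=3,
) -> dict:
    """Recovery of a known linear percentile contrast (about 0.3 standardized
    units with the default slope) across replicate cohorts.

    Reports the mean absolute error of the main-effect estimator against the
    per-replicate truth, the mean signed bias, and the empirical coverage of
    the 95% credible interval.  Because the truth is purely additive (no
    product terms), the same fits also yield the null-interaction centering
    check: the across-replicate mean of the As x Se third-window interaction
    estimate.
    """
    errs, covers, ests, truths, null_inter = [], [], [], [], []
    for i in range(n_reps):
        cfg = GeneratorConfig(
            n_subjects=n, surface=single_linear_surface(metal, window, slope),
            seed=_seed(seed, 10 + i),
        )
        table, truth = generate_cohort(cfg)
        fit = fit_mfvb(prepare(table))
        est = main_effect(fit, metal, window, allow_nonconverged=True)
        tv = true_contrast(truth, metal, window)
        errs.append(est.estimate - tv)
        covers.append(est.cri95_lower <= tv <= est.cri95_upper)
        ests.append(est.estimate)
        truths.append(tv)
        null_inter.append(
            interaction_effect(fit, "As", "Se", 3, allow_nonconverged=True).estimate
        )
    errs = np.asarray(errs)
    return {
        "mae": float(np.abs(errs).mean()),
        "bias": float(errs.mean()),
        "coverage": float(np.mean(covers)),
        "mean_truth": float(np.mean(truths)),
        "mean_estimate": float(np.mean(ests)),
        "null_interaction_mean": float(np.mean(null_inter)),
        "n": n,
        "n_reps": n_reps,
    }


#: fixed terms used for the null-calibration type-I error check
NULL_TYPE1_TERMS = [
    ("Mn", "infant"), ("As", "maternal_postnatal"),
    ("Zn", "infant"), ("Pb", "maternal_prenatal"),
]


def null_calibration_study(seed: int = 0, n: int = 200, n_reps: int = 100) -> dict:
    """Behavior under a zero exposure-response surface.

    Tracks the across-replicate mean of a designated main-effect estimate
    (Mn, third window) and interaction estimate (As x Se, third window), and
    the type-I error rate of the corroboration model's metal coefficients at
    alpha = 0.05 for a fixed set of terms.
    """
    mains, inters, sig = [], [], []
    spec = CorroborationSpec(selected_main_terms=list(NULL_TYPE1_TERMS))
    for i in range(n_reps):
        cfg = GeneratorConfig(n_subjects=n, surface=null_surface(), seed=_seed(seed, 500 + i))
        table, _ = generate_cohort(cfg)
        fit = fit_mfvb(prepare(table))
        mains.append(main_effect(fit, "Mn", 3, allow_nonconverged=True).estimate)
        inters.append(interaction_effect(fit, "As", "Se", 3, allow_nonconverged=True).estimate)
        corro = fit_corroboration(table, spec)
        metal_rows = corro[corro.kind == "metal_main"]
        sig.extend((metal_rows.pvalue < 0.05).tolist())
    return {
        "mean_main_effect": float(np.mean(mains)),
        "mean_interaction": float(np.mean(inters)),
        "type1_rate": float(np.mean(sig)),
        "n_tests": len(sig),
        "n": n,
        "n_reps": n_reps,
    }


def shrinkage_study(seed: int = 0, n: int = 200, n_reps: int = 20) -> dict:
    """Structure of the two penalties.

    Group lasso: with signal confined to window 1, the ratio
    ||E[h_3]|| / ||E[h_1]|| should be well below 1 (target: mean < 0.5).
    Fused lasso: with an identical surface in every window, the mean
    ||E[h_{t+1}] - E[h_t]|| under the fused fit should be strictly smaller
    than under the variant with the fusion precision terms removed.
    """
    ratios, ratios_nofusion, fused_diffs, unfused_diffs = [], [], [], []
    window1_surface = SurfaceSpec(linear=(("Mn", 1, 0.35), ("As", 1, 0.25)))
    shared_surface = SurfaceSpec(
        linear=(("Mn", 1, 0.2), ("Mn", 2, 0.2), ("Mn", 3, 0.2)))
    for i in range(n_reps):
        cfg = GeneratorConfig(n_subjects=n, surface=window1_surface, seed=_seed(seed, 900 + i))
        table, _ = generate_cohort(cfg)
        design = prepare(table)
        fit = fit_mfvb(design)
        ratios.append(
            float(np.linalg.norm(fit.m_h[2]) / np.linalg.norm(fit.m_h[0]))
        )
        fit_nf = fit_mfvb(design, LKMRHyperparameters(fused=False))
        ratios_nofusion.append(
            float(np.linalg.norm(fit_nf.m_h[2]) / np.linalg.norm(fit_nf.m_h[0]))
        )

        cfg2 = GeneratorConfig(n_subjects=n, surface=shared_surface, seed=_seed(seed, 950 + i))
        table2, _ = generate_cohort(cfg2)
        design2 = prepare(table2)
        f_on = fit_mfvb(design2, LKMRHyperparameters(fused=True))
        f_off = fit_mfvb(design2, LKMRHyperparameters(fused=False))
        fused_diffs.append(float(np.mean(
            [np.linalg.norm(f_on.m_h[t + 1] - f_on.m_h[t]) for t in range(2)]
        )))
        unfused_diffs.append(float(np.mean(
            [np.linalg.norm(f_off.m_h[t + 1] - f_off.m_h[t]) for t in range(2)]
        )))
    return {
        "group_ratio_mean": float(np.mean(ratios)),
        "group_ratio_nofusion_mean": float(np.mean(ratios_nofusion)),
        "fused_diff_mean": float(np.mean(fused_diffs)),
        "unfused_diff_mean": float(np.mean(unfused_diffs)),
        "n": n,
        "n_reps": n_reps,
    }


def interaction_recovery_study(
    seed: int = 0, n: int = 400, n_reps: int = 50, coef: float = 0.15,
) -> dict:
    """Recovery of a planted within-window product term (As x Se, window 3):
    sign agreement with the truth and mean absolute error."""
    surface = SurfaceSpec(interactions=(("As", "Se", 3, coef),))
    agree, errs, truths = [], [], []
    for i in range(n_reps):
        cfg = GeneratorConfig(n_subjects=n, surface=surface, seed=_seed(seed, 2000 + i))
        table, truth = generate_cohort(cfg)
        fit = fit_mfvb(prepare(table))
        est = interaction_effect(fit, "As", "Se", 3, allow_nonconverged=True)
        tv = true_contrast(truth, "As", 3, "interaction", "Se")
        agree.append(np.sign(est.estimate) == np.sign(tv))
        errs.append(est.estimate - tv)
        truths.append(tv)
    return {
        "sign_agreement": float(np.mean(agree)),
        "mae": float(np.abs(errs).mean()),
        "mean_truth": float(np.mean(truths)),
        "n": n,
        "n_reps": n_reps,
    }
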