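"""Percentile-contrast estimands from a fitted lagged kernel machine model.

Main effects are the difference in the mean predicted outcome when one metal
is fixed at its 75th versus its 25th percentile, with the other metals in
the window fixed at their medians (covariate terms cancel by additivity of
the model).  Two-way interactions are the double difference over the four
(q75/q25) x (q75/q25) percentile profiles.  Uncertainty comes from the joint
predictive covariance of the profile points under the variational posterior;
95% credible intervals are Gaussian-quantile intervals (estimate +/- 1.96
posterior SD).  Dose-response cross-sections are evaluated on a grid from
the 5th to the 95th empirical percentile, with a fitted quadratic
coefficient serving as a reproducible curvature statistic in place of
visual inspection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import LKMRFit, fit_mfvb, predict_window_surface

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass
class EffectEstimate:
    """A posterior contrast tied to a named metal, window and contrast type."""

    metal: str
    window: str
    contrast_type: str  # "main" | "interaction" | "cross_window"
    estimate: float
    posterior_sd: float
    cri95_lower: float
    cri95_upper: float
    partner_metal: str | None = None
    partner_window: str | None = None
    profile: dict = field(default_factory=dict)
    structural_zero: bool = False
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "metal": self.metal, "window": self.window,
            "contrast_type": self.contrast_type,
            "partner_metal": self.partner_metal,
            "partner_window": self.partner_window,
            "estimate": self.estimate, "posterior_sd": self.posterior_sd,
            "cri95_lower": self.cri95_lower, "cri95_upper": self.cri95_upper,
            "structural_zero": self.structural_zero, "degenerate": self.degenerate,
        }

    @property
    def significant(self) -> bool:
        """95% credible interval excludes zero."""
        return (self.cri95_lower > 0) or (self.cri95_upper < 0)


@dataclass
class DoseResponseCurve:
    """Cross-section of the window surface along one metal."""

    metal: str
    window: str
    grid: np.ndarray  # standardized exposure values, strictly increasing
    mean: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    curvature: float  # fitted quadratic coefficient of mean on grid

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "metal": self.metal, "window": self.window, "grid": self.grid,
            "mean": self.mean, "lower95": self.lower95, "upper95": self.upper95,
            "curvature": self.curvature,
        })


def effects_to_frame(effects) -> pd.DataFrame:
    return pd.DataFrame([e.to_dict() for e in effects])


def _check_fit(fit: LKMRFit, allow_nonconverged: bool) -> None:
    if not fit.converged and not allow_nonconverged:
        raise RuntimeError(
            "fit did not converge within max_iterations; pass "
            "allow_nonconverged=True to compute estimands from it anyway"
        )


def percentile_profile(design, window, overrides=None) -> np.ndarray:
    """The window's exposure vector with every metal at its stored median
    except the overridden metals at their requested quantiles.

    ``overrides`` maps metal name -> "q25" | "q50" | "q75" (or an explicit
    standardized grid value).
    """
    t = design.window_index(window)
    prof = design.quantiles[t, :, 2].copy()  # medians
    for metal, level in (overrides or {}).items():
        m = design.metal_index(metal)
        if isinstance(level, str):
            prof[m] = design.quantile(metal, window, level)
        else:
            prof[m] = float(level)
    return prof


def _contrast(fit, t, profiles, weights) -> tuple[float, float]:
    """Posterior mean and SD of a linear contrast of surface values."""
    mean, cov = predict_window_surface(fit, t, np.asarray(profiles))
    w = np.asarray(weights, dtype=float)
    est = float(w @ mean)
    var = float(w @ cov @ w)
    return est, float(np.sqrt(max(var, 0.0)))


def main_effect(fit: LKMRFit, metal: str, window, allow_nonconverged: bool = False) -> EffectEstimate:
    """q75-versus-q25 contrast for one metal, co-metals at their medians."""
    _check_fit(fit, allow_nonconverged)
    design = fit.design
    t = design.window_index(window)
    w_label = design.windows[t]
    q25 = design.quantile(metal, window, "q25")
    q75 = design.quantile(metal, window, "q75")
    profile = {"q25": q25, "q50": design.quantile(metal, window, "q50"), "q75": q75}
    if q75 == q25:
        warnings.warn(
            f"degenerate exposure distribution for {metal} in window {w_label}: "
            "q75 equals q25, contrast is identically 0"
        )
        return EffectEstimate(metal, w_label, "main", 0.0, 0.0, 0.0, 0.0,
                              profile=profile, degenerate=True)
    hi = percentile_profile(design, window, {metal: "q75"})
    lo = percentile_profile(design, window, {metal: "q25"})
    est, sd = _contrast(fit, t, [hi, lo], [1.0, -1.0])
    return EffectEstimate(
        metal, w_label, "main", est, sd,
        est - Z95 * sd, est + Z95 * sd, profile=profile,
    )


def interaction_effect(
    fit: LKMRFit, metal_a: str, metal_b: str, window, allow_nonconverged: bool = False
) -> EffectEstimate:
    """Within-window double difference over the four percentile profiles."""
    _check_fit(fit, allow_nonconverged)
    if metal_a == metal_b:
        raise ValueError("interaction requires two distinct metals")
    design = fit.design
    t = design.window_index(window)
    w_label = design.windows[t]
    profs = [
        percentile_profile(design, window, {metal_a: "q75", metal_b: "q75"}),
        percentile_profile(design, window, {metal_a: "q25", metal_b: "q75"}),
        percentile_profile(design, window, {metal_a: "q75", metal_b: "q25"}),
        percentile_profile(design, window, {metal_a: "q25", metal_b: "q25"}),
    ]
    est, sd = _contrast(fit, t, profs, [1.0, -1.0, -1.0, 1.0])
    return EffectEstimate(
        metal_a, w_label, "interaction", est, sd,
        est - Z95 * sd, est + Z95 * sd, partner_metal=metal_b,
    )


def cross_window_interaction(
    fit: LKMRFit, metal_a: str, window_a, metal_b: str, window_b,
    allow_nonconverged: bool = False,
) -> EffectEstimate:
    """Structurally zero: the model is additive across windows, so contrasts
    of exposures in different windows have no interaction by construction.
    Provided so the unidentifiable quantity cannot be requested silently."""
    design = fit.design
    ta, tb = design.window_index(window_a), design.window_index(window_b)
    if ta == tb:
        raise ValueError(
            "cross_window_interaction requires two different windows; use "
            "interaction_effect for a within-window interaction"
        )
    design.metal_index(metal_a), design.metal_index(metal_b)
    logger.info(
        "cross-window interaction (%s, %s) x (%s, %s) is a structural zero "
        "of the additive-by-window model", metal_a, design.windows[ta],
        metal_b, design.windows[tb],
    )
    return EffectEstimate(
        metal_a, design.windows[ta], "cross_window", 0.0, 0.0, 0.0, 0.0,
        partner_metal=metal_b, partner_window=design.windows[tb],
        structural_zero=True,
    )


def dose_response(
    fit: LKMRFit, metal: str, window, n_grid: int = 25,
    allow_nonconverged: bool = False,
) -> DoseResponseCurve:
    """Surface cross-section along one metal, co-metals at their medians.

    The grid spans the metal's empirical 5th-95th percentile (standardized
    scale) to avoid kernel extrapolation artifacts; requests outside the
    observed range are honored with a logged extrapolation warning.
    """
    _check_fit(fit, allow_nonconverged)
    if n_grid < 5:
        raise ValueError("n_grid must be >= 5")
    design = fit.design
    t = design.window_index(window)
    m = design.metal_index(metal)
    lo, hi = design.quantiles[t, m, 0], design.quantiles[t, m, 4]
    grid = np.linspace(lo, hi, n_grid)
    zmin, zmax = design.Z[t][:, m].min(), design.Z[t][:, m].max()
    if lo < zmin or hi > zmax:
        logger.warning(
            "dose-response grid for %s extends beyond the observed range "
            "[%.3f, %.3f]; extrapolating", metal, zmin, zmax,
        )
    profs = np.tile(design.quantiles[t, :, 2], (n_grid, 1))
    profs[:, m] = grid
    mean, cov = predict_window_surface(fit, t, profs)
    sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    curvature = float(np.polyfit(grid, mean, 2)[0])
    return DoseResponseCurve(
        metal=metal, window=design.windows[t], grid=grid, mean=mean,
        lower95=mean - Z95 * sd, upper95=mean + Z95 * sd, curvature=curvature,
    )


def all_main_effects(fit: LKMRFit, allow_nonconverged: bool = False) -> list:
    design = fit.design
    return [
        main_effect(fit, m, w, allow_nonconverged)
        for w in design.windows for m in design.metals
    ]


def all_interaction_effects(fit: LKMRFit, allow_nonconverged: bool = False) -> list:
    design = fit.design
    out = []
    for w in design.windows:
        for i, a in enumerate(design.metals):
            for b in design.metals[i + 1:]:
                out.append(interaction_effect(fit, a, b, w, allow_nonconverged))
    return out


def stratified_analysis(
    table, hyper=None, kernel=None, stratum: str | None = None,
    min_stratum_n: int = 50, contrasts: str = "mains",
    allow_nonconverged: bool = False, solver: str = "auto",
) -> dict:
    """Run the full pipeline (preparation through estimands) pooled and
    independently within each stratum.

    Standardization and quantiles are recomputed within stratum, so each
    stratified fit is a complete analysis.  Strata below ``min_stratum_n``
    are skipped with a logged warning.  Returns a dict mapping "pooled" and
    each stratum level to an effect-estimate DataFrame.
    """
    from .preprocessing import prepare  # local import keeps layering obvious

    stratum = stratum or table.stratum
    if stratum is None:
        raise ValueError("no stratum column available")

    def run_one(tab, drop_stratum: bool) -> pd.DataFrame:
        t = tab.copy()
        if drop_stratum and stratum in t.covariates:
            t.covariates = {k: v for k, v in t.covariates.items() if k != stratum}
        design = prepare(t)
        fit = fit_mfvb(design, hyper, kernel, solver=solver)
        effects = all_main_effects(fit, allow_nonconverged)
        if contrasts == "all":
            effects += all_interaction_effects(fit, allow_nonconverged)
        return effects_to_frame(effects)

    results = {"pooled": run_one(table, drop_stratum=False)}
    for level in pd.unique(table.data[stratum]):
        sub = table.subset(table.data[stratum] == level)
        if sub.n < min_stratum_n:
            logger.warning(
                "skipping stratum %s=%r with n=%d below floor %d",
                stratum, level, sub.n, min_stratum_n,
            )
            continue
        results[str(level)] = run_one(sub, drop_stratum=True)
    return results
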