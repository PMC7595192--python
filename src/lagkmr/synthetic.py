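"""Synthetic pregnancy-cohort generator with known ground truth.

The study data this package targets -- toenail concentrations of six metals
(As, Cu, Mn, Pb, Se, Zn) at three collection windows spanning periconception
through early neonatal life, a continuous behavioral raw score, and mixed
covariates -- are available only by request to the cohort investigators.
This module generates cohorts with the same statistical structure so every
downstream stage is testable without any download:

* right-skewed concentrations: exp2 of a latent multivariate normal, so the
  downstream log2 transform recovers exact multivariate normality and the
  configured geometric medians are the marginal medians;
* positive cross-correlations concentrated within collection windows
  (``rho_within``) and within metal across windows (``rho_between``), with a
  weaker background (``rho_background``), specified on the latent normal
  scale (realized Spearman correlations land close by);
* per-(metal, window) detection limits placed at the empirical quantile
  matching the configured detection frequency, with below-LOD values flagged
  and the LOD recorded (reproducing the censoring rate by construction);
* outcomes from a configurable additive-by-window surface with linear,
  quadratic and within-window product terms on the latent (population-
  standardized log2) exposure scale, plus covariate effects and Gaussian
  noise.

Alongside the table the generator returns a :class:`SyntheticTruth` whose
true contrast values are computed by running the actual preparation pipeline
on the generated sample and evaluating the surface at the exact percentile
profiles the estimand layer will use -- not by re-deriving coefficients.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .preprocessing import CohortTable, prepare

logger = logging.getLogger(__name__)

DEFAULT_METALS = ["As", "Cu", "Mn", "Pb", "Se", "Zn"]
DEFAULT_WINDOWS = ["maternal_prenatal", "maternal_postnatal", "infant"]

# geometric medians (ug/g) per window, emulating the reported ordering of
# toenail concentrations (Zn >> Cu > Se >~ Mn > Pb > As; infant Mn closer to Se)
DEFAULT_GEOMETRIC_MEDIANS = {
    "As": (0.030, 0.035, 0.045),
    "Cu": (4.0, 4.2, 5.0),
    "Mn": (0.22, 0.25, 0.60),
    "Pb": (0.050, 0.055, 0.080),
    "Se": (0.85, 0.85, 0.75),
    "Zn": (100.0, 105.0, 115.0),
}
DEFAULT_LOG2_SD = {"As": 1.4, "Cu": 0.5, "Mn": 1.1, "Pb": 1.2, "Se": 0.35, "Zn": 0.4}
DEFAULT_DETECTION_FREQUENCY = {
    "As": (0.97, 0.97, 0.95),
    "Cu": (1.0, 1.0, 1.0),
    "Mn": (0.99, 0.99, 0.98),
    "Pb": (0.92, 0.92, 0.90),
    "Se": (1.0, 1.0, 1.0),
    "Zn": (1.0, 1.0, 1.0),
}


@dataclass(frozen=True)
class CovariateSpec:
    """One generated covariate: continuous (mean/sd) or categorical
    (levels/probs).  ``role`` is the preprocessing role of the column."""

    name: str
    kind: str  # "continuous" | "categorical"
    mean: float = 0.0
    sd: float = 1.0
    levels: tuple = ()
    probs: tuple = ()
    role: str = "continuous"


def default_covariates() -> list:
    """Smallest covariate set exercising every handling path: an age-like
    continuous with quadratic role, an education-like 3-level categorical,
    binary sex, three PC-like continuous scores."""
    return [
        CovariateSpec("age", "continuous", mean=32.0, sd=4.5, role="quadratic"),
        CovariateSpec("edu", "categorical", levels=("hs_or_less", "college", "graduate"),
                      probs=(0.25, 0.45, 0.30), role="categorical"),
        CovariateSpec("sex", "categorical", levels=("female", "male"),
                      probs=(0.5, 0.5), role="categorical"),
        CovariateSpec("prq_pc1", "continuous", role="continuous"),
        CovariateSpec("prq_pc2", "continuous", role="continuous"),
        CovariateSpec("prq_pc3", "continuous", role="continuous"),
    ]


@dataclass(frozen=True)
class SurfaceSpec:
    """Additive-by-window exposure-response surface on the latent scale.

    Terms reference metals by name and windows by label or 1-based index;
    slopes are per SD of the population-standardized log2 exposure.  The
    surface is additive across windows (no cross-window products), matching
    the model class fitted downstream.  ``covariate_effects`` maps design
    terms ("age", "age^2", "edu=college", ...) to coefficients.
    """

    linear: tuple = ()  # ((metal, window, slope), ...)
    quadratic: tuple = ()  # ((metal, window, coef), ...)
    interactions: tuple = ()  # ((metal_a, metal_b, window, coef), ...)
    covariate_effects: dict = field(default_factory=dict)

    def validate(self, metals, windows) -> None:
        for metal, window, _ in list(self.linear) + list(self.quadratic):
            if metal not in metals:
                raise ValueError(f"surface references unknown metal {metal!r}")
            _window_index(window, windows)
        for ma, mb, window, _ in self.interactions:
            for metal in (ma, mb):
                if metal not in metals:
                    raise ValueError(f"surface references unknown metal {metal!r}")
            _window_index(window, windows)

    def evaluate(self, zlat: np.ndarray, metals, windows) -> np.ndarray:
        """Surface contribution for latent exposures ``zlat`` (n, T, M)."""
        zlat = np.asarray(zlat, dtype=float)
        squeeze = zlat.ndim == 2
        if squeeze:
            zlat = zlat[None]
        out = np.zeros(zlat.shape[0])
        for metal, window, slope in self.linear:
            out += slope * zlat[:, _window_index(window, windows), metals.index(metal)]
        for metal, window, coef in self.quadratic:
            out += coef * zlat[:, _window_index(window, windows), metals.index(metal)] ** 2
        for ma, mb, window, coef in self.interactions:
            t = _window_index(window, windows)
            out += coef * zlat[:, t, metals.index(ma)] * zlat[:, t, metals.index(mb)]
        return out[0] if squeeze else out


def null_surface() -> SurfaceSpec:
    return SurfaceSpec()


def single_linear_surface(metal: str, window, slope: float) -> SurfaceSpec:
    return SurfaceSpec(linear=((metal, window, slope),))


def reference_surface() -> SurfaceSpec:
    """Default surface emulating the reported effect pattern: adverse Mn in
    the third window with mild nonlinearity, adverse As in the second,
    protective Zn in the third, an As-by-Se product in the third."""
    return SurfaceSpec(
        linear=(("Mn", 3, 0.12), ("As", 2, 0.08), ("Zn", 3, -0.10), ("Pb", 1, -0.05)),
        quadratic=(("Mn", 3, 0.05),),
        interactions=(("As", "Se", 3, 0.08),),
        covariate_effects={
            "age": 0.05, "age^2": -0.04, "edu=college": -0.10,
            "edu=graduate": -0.15, "sex=male": 0.15, "prq_pc1": 0.10,
        },
    )


def _window_index(window, windows) -> int:
    if isinstance(window, str):
        if window not in windows:
            raise ValueError(f"unknown window {window!r} (labels {list(windows)})")
        return windows.index(window)
    w = int(window)
    if not 1 <= w <= len(windows):
        raise ValueError(f"unknown window {window!r} (1..{len(windows)})")
    return w - 1


def _per_window(value, metal: str, T: int) -> np.ndarray:
    v = value[metal] if isinstance(value, dict) else value
    arr = np.atleast_1d(np.asarray(v, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, T)
    elif arr.size > T:
        arr = arr[:T]  # defaults cover the full window set; truncated runs use a prefix
    if arr.size != T:
        raise ValueError(f"need 1 or {T} values per metal, got {arr.size} for {metal!r}")
    return arr


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort."""

    n_subjects: int = 400
    metals: list = field(default_factory=lambda: list(DEFAULT_METALS))
    windows: list = field(default_factory=lambda: list(DEFAULT_WINDOWS))
    geometric_medians: dict = field(default_factory=lambda: dict(DEFAULT_GEOMETRIC_MEDIANS))
    log2_sd: dict = field(default_factory=lambda: dict(DEFAULT_LOG2_SD))
    rho_within: float = 0.30
    rho_between: float = 0.30
    rho_background: float = 0.09
    detection_frequency: dict | float = field(default_factory=lambda: dict(DEFAULT_DETECTION_FREQUENCY))
    covariates: list = field(default_factory=default_covariates)
    surface: SurfaceSpec = field(default_factory=reference_surface)
    surface_by_stratum: dict | None = None
    noise_sd: float = 1.0
    outcome_name: str = "outcome"
    stratum_column: str = "sex"
    seed: int = 0

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        T = self.n_windows
        for m in self.metals:
            gm = _per_window(self.geometric_medians, m, T)
            if np.any(gm <= 0):
                raise ValueError(f"geometric medians must be positive ({m})")
            df = _per_window(self.detection_frequency, m, T)
            if np.any((df <= 0) | (df > 1)):
                raise ValueError(f"detection frequencies must lie in (0, 1] ({m})")
            if (self.log2_sd[m] if isinstance(self.log2_sd, dict) else self.log2_sd) <= 0:
                raise ValueError(f"log2_sd must be positive ({m})")
        self.surface.validate(self.metals, self.windows)
        if self.surface_by_stratum:
            for surf in self.surface_by_stratum.values():
                surf.validate(self.metals, self.windows)


def latent_correlation(config: GeneratorConfig) -> np.ndarray:
    """Latent (T*M) x (T*M) correlation matrix, window-major ordering.

    Eigenvalue clipping repairs mild indefiniteness (logged); a matrix whose
    smallest eigenvalue is below -0.05 is refused.
    """
    T, M = config.n_windows, len(config.metals)
    R = np.full((T * M, T * M), config.rho_background)
    for t in range(T):
        blk = slice(t * M, (t + 1) * M)
        R[blk, blk] = config.rho_within
    for m in range(M):
        idx = np.arange(T) * M + m
        R[np.ix_(idx, idx)] = config.rho_between
    R[np.diag_indices_from(R)] = 1.0
    eig, vec = np.linalg.eigh(R)
    if eig.min() < -0.05:
        raise ValueError(
            "latent exposure correlation matrix is not positive definite beyond "
            f"repair tolerance (smallest eigenvalue {eig.min():.3f}); offending "
            f"block structure: rho_within={config.rho_within}, "
            f"rho_between={config.rho_between}, rho_background={config.rho_background}"
        )
    if eig.min() < 1e-8:
        logger.warning(
            "repairing non-positive-definite latent correlation by eigenvalue "
            "clipping (smallest eigenvalue %.3g)", eig.min()
        )
        eig = np.clip(eig, 1e-8, None)
        R = (vec * eig) @ vec.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    return R


@dataclass
class SyntheticTruth:
    """Ground-truth surface and the true value of every contrast the
    estimand layer will estimate, on the standardized-outcome scale."""

    config: GeneratorConfig
    seed: int
    surface: SurfaceSpec
    main_effects: pd.DataFrame  # metal, window, value
    interactions: pd.DataFrame  # metal_a, metal_b, window, value
    y_sd: float
    strata: dict | None = None

    def evaluate_surface(self, zlat: np.ndarray) -> np.ndarray:
        return self.surface.evaluate(zlat, self.config.metals, self.config.windows)


def true_contrast(
    truth: SyntheticTruth, metal: str, window, contrast_type: str = "main",
    partner_metal: str | None = None, stratum: str | None = None,
) -> float:
    """Look up the true percentile contrast for one metal and window."""
    if stratum is not None:
        if not truth.strata or stratum not in truth.strata:
            raise ValueError(f"no stratum-specific truth for {stratum!r}")
        mains, inters = truth.strata[stratum]["main_effects"], truth.strata[stratum]["interactions"]
    else:
        mains, inters = truth.main_effects, truth.interactions
    cfg = truth.config
    if metal not in cfg.metals:
        raise ValueError(f"unknown metal {metal!r}")
    w = cfg.windows[_window_index(window, cfg.windows)]
    if contrast_type == "main":
        if partner_metal is not None:
            raise ValueError("partner_metal is only for interaction contrasts")
        row = mains[(mains.metal == metal) & (mains.window == w)]
        return float(row.value.iloc[0])
    if contrast_type == "interaction":
        if partner_metal is None:
            raise ValueError("interaction contrast requires partner_metal")
        if partner_metal not in cfg.metals:
            raise ValueError(f"unknown metal {partner_metal!r}")
        row = inters[
            (inters.window == w)
            & (((inters.metal_a == metal) & (inters.metal_b == partner_metal))
               | ((inters.metal_a == partner_metal) & (inters.metal_b == metal)))
        ]
        return float(row.value.iloc[0])
    raise ValueError(f"unknown contrast_type {contrast_type!r}")


def _truth_tables(config, design, surface):
    """Evaluate the surface at the estimand layer's percentile profiles."""
    metals, windows = config.metals, config.windows
    T, M = len(windows), len(metals)
    log2_gm = np.array([
        np.log2(_per_window(config.geometric_medians, m, T)) for m in metals
    ]).T  # (T, M)
    sd_lat = np.array([
        config.log2_sd[m] if isinstance(config.log2_sd, dict) else config.log2_sd
        for m in metals
    ])

    def to_latent(t, m_i, z_std):
        log2c = z_std * design.exp_sd[t, m_i] + design.exp_mean[t, m_i]
        return (log2c - log2_gm[t, m_i]) / sd_lat[m_i]

    def profile(t, overrides):
        z = np.zeros((T, M))
        for tt in range(T):
            for mm in range(M):
                z[tt, mm] = to_latent(tt, mm, design.quantiles[tt, mm, 2])  # q50
        for mm, q in overrides.items():
            z[t, mm] = to_latent(t, mm, q)
        return z

    ev = lambda z: float(surface.evaluate(z, metals, windows))
    mains = []
    for t, w in enumerate(windows):
        for m_i, m in enumerate(metals):
            hi = ev(profile(t, {m_i: design.quantiles[t, m_i, 3]}))
            lo = ev(profile(t, {m_i: design.quantiles[t, m_i, 1]}))
            mains.append({"metal": m, "window": w, "value": (hi - lo) / design.y_sd})
    inters = []
    for t, w in enumerate(windows):
        for a in range(M):
            for b in range(a + 1, M):
                qa25, qa75 = design.quantiles[t, a, 1], design.quantiles[t, a, 3]
                qb25, qb75 = design.quantiles[t, b, 1], design.quantiles[t, b, 3]
                dd = (
                    ev(profile(t, {a: qa75, b: qb75})) - ev(profile(t, {a: qa25, b: qb75}))
                    - ev(profile(t, {a: qa75, b: qb25})) + ev(profile(t, {a: qa25, b: qb25}))
                )
                inters.append({
                    "metal_a": metals[a], "metal_b": metals[b], "window": w,
                    "value": dd / design.y_sd,
                })
    return pd.DataFrame(mains), pd.DataFrame(inters)


def generate_cohort(config: GeneratorConfig) -> tuple[CohortTable, SyntheticTruth]:
    """Generate a cohort table and its ground truth.  Same seed and config
    give a byte-identical table."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, T, M = config.n_subjects, config.n_windows, len(config.metals)
    metals, windows = config.metals, config.windows

    R = latent_correlation(config)
    Lmat = np.linalg.cholesky(R + 1e-12 * np.eye(T * M))
    zlat = (rng.standard_normal((n, T * M)) @ Lmat.T).reshape(n, T, M)

    log2_gm = np.array([np.log2(_per_window(config.geometric_medians, m, T)) for m in metals]).T
    sd_lat = np.array([
        config.log2_sd[m] if isinstance(config.log2_sd, dict) else config.log2_sd for m in metals
    ])
    conc = 2.0 ** (log2_gm[None] + sd_lat[None, None, :] * zlat)  # (n, T, M)

    # covariates and their standardized design terms
    cov_cols, cov_terms, roles, levels_map = {}, {}, {}, {}
    for spec in config.covariates:
        if spec.kind == "continuous":
            x = rng.normal(spec.mean, spec.sd, size=n)
            cov_cols[spec.name] = x
            z = (x - spec.mean) / spec.sd
            cov_terms[spec.name] = z
            cov_terms[f"{spec.name}^2"] = z**2
            roles[spec.name] = spec.role
        elif spec.kind == "categorical":
            draw = rng.choice(len(spec.levels), size=n, p=spec.probs)
            vals = np.asarray(spec.levels, dtype=object)[draw]
            cov_cols[spec.name] = vals
            for level in spec.levels[1:]:
                cov_terms[f"{spec.name}={level}"] = (vals == level).astype(float)
            roles[spec.name] = "categorical"
            levels_map[spec.name] = list(spec.levels)
        else:
            raise ValueError(f"unknown covariate kind {spec.kind!r}")

    cov_effects = dict(config.surface.covariate_effects)
    cov_contrib = np.zeros(n)
    for term, coef in cov_effects.items():
        if term not in cov_terms:
            raise ValueError(f"covariate effect references unknown term {term!r}")
        cov_contrib += coef * cov_terms[term]

    if config.surface_by_stratum:
        if config.stratum_column not in cov_cols:  # pragma: no cover - config error
            raise ValueError("stratified surfaces need the stratum covariate")
        surf_vals = np.zeros(n)
        strat_vals = cov_cols[config.stratum_column]
        for level, surf in config.surface_by_stratum.items():
            mask = strat_vals == level
            surf_vals[mask] = surf.evaluate(zlat[mask], metals, windows)
    else:
        surf_vals = config.surface.evaluate(zlat, metals, windows)

    y = cov_contrib + surf_vals + rng.normal(0.0, config.noise_sd, size=n)

    data = {"subject_id": np.arange(1, n + 1), config.outcome_name: y}
    for t, w in enumerate(windows):
        for m_i, m in enumerate(metals):
            col = conc[:, t, m_i].copy()
            dfreq = _per_window(config.detection_frequency, m, T)[t]
            name = f"{m}_{w}"
            if dfreq < 1.0:
                lod = float(np.quantile(col, 1.0 - dfreq))
                flags = col < lod
                col[flags] = np.nan
                data[name] = col
                data[f"{name}_belowLOD"] = flags
                data[f"{name}_LOD"] = np.full(n, lod)
            else:
                data[name] = col
                data[f"{name}_belowLOD"] = np.zeros(n, dtype=bool)
                data[f"{name}_LOD"] = np.full(n, np.nan)
    for name, vals in cov_cols.items():
        data[name] = vals
    df = pd.DataFrame(data)

    stratum = config.stratum_column if config.stratum_column in cov_cols else None
    table = CohortTable(
        data=df, metals=list(metals), windows=list(windows),
        outcome=config.outcome_name, covariates=roles, stratum=stratum,
        covariate_levels=levels_map,
    )

    design = prepare(table)
    mains, inters = _truth_tables(config, design, config.surface)
    strata_truth = None
    if config.surface_by_stratum:
        strata_truth = {}
        for level, surf in config.surface_by_stratum.items():
            sub = table.subset(df[stratum] == level)
            sub_design = prepare(sub)
            sm, si = _truth_tables(config, sub_design, surf)
            strata_truth[level] = {"main_effects": sm, "interactions": si, "y_sd": sub_design.y_sd}

    truth = SyntheticTruth(
        config=config, seed=config.seed, surface=config.surface,
        main_effects=mains, interactions=inters, y_sd=design.y_sd,
        strata=strata_truth,
    )
    return table, truth


def write_cohort(table: CohortTable, path) -> None:
    table.data.to_csv(path, index=False)


def write_truth(truth: SyntheticTruth, path) -> None:
    cfg = asdict(truth.config)
    cfg["surface"] = asdict(truth.surface)
    cfg["covariates"] = [asdict(c) for c in truth.config.covariates]
    if truth.config.surface_by_stratum:
        cfg["surface_by_stratum"] = {
            k: asdict(v) for k, v in truth.config.surface_by_stratum.items()
        }
    payload = {
        "seed": truth.seed,
        "config": cfg,
        "y_sd": truth.y_sd,
        "true_main_effects": truth.main_effects.to_dict(orient="records"),
        "true_interactions": truth.interactions.to_dict(orient="records"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)


def read_cohort(
    path, metals, windows, outcome="outcome", covariates=None, stratum=None,
    covariate_levels=None,
) -> CohortTable:
    """Load a cohort CSV written by :func:`write_cohort` (or hand-built with
    the same header convention)."""
    df = pd.read_csv(path)
    return CohortTable(
        data=df, metals=list(metals), windows=list(windows), outcome=outcome,
        covariates=dict(covariates or {}), stratum=stratum,
        covariate_levels=dict(covariate_levels or {}),
    )
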