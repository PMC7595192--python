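"""Cohort table handling and the fixed preparation pipeline.

The analysis consumes a subject-level rectangular table: one continuous
behavioral raw score, toenail metal concentrations (ug/g) for M metals at T
collection windows with below-detection flags, mixed covariates and a sex
stratum.  Preparation is a fixed, enforced sequence:

    impute_below_lod  ->  log2_transform  ->  standardize

(below-detection concentrations imputed as LOD/2; concentrations
log2-transformed; concentrations, outcome and continuous covariates
standardized to mean 0, variance 1).  Quantiles used by the contrast
estimands are computed here, once, on the standardized exposure columns with
numpy's default linear-interpolation rule, and carried on the design so the
whole package shares a single quantile definition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: covariate roles understood by ``standardize``
ROLES = ("continuous", "quadratic", "categorical")

QUANTILE_LEVELS = (0.05, 0.25, 0.50, 0.75, 0.95)
_QIDX = {"q05": 0, "q25": 1, "q50": 2, "q75": 3, "q95": 4}


@dataclass
class CohortTable:
    """Subject-level outcome, exposure and covariate table plus metadata.

    ``covariates`` maps column name -> role ("continuous", "quadratic" --
    continuous with an additional squared term -- or "categorical").
    ``stage`` tracks the preparation pipeline ("raw" -> "imputed" -> "log2")
    so the fixed composition order can be enforced.
    """

    data: pd.DataFrame
    metals: list
    windows: list
    outcome: str = "outcome"
    covariates: dict = field(default_factory=dict)
    stratum: str | None = "sex"
    covariate_levels: dict = field(default_factory=dict)
    stage: str = "raw"
    imputation_counts: dict | None = None

    def exposure_column(self, metal: str, window: str) -> str:
        return f"{metal}_{window}"

    def flag_column(self, metal: str, window: str) -> str:
        return f"{metal}_{window}_belowLOD"

    def lod_column(self, metal: str, window: str) -> str:
        return f"{metal}_{window}_LOD"

    def exposure_columns(self) -> list:
        return [self.exposure_column(m, w) for w in self.windows for m in self.metals]

    @property
    def n(self) -> int:
        return len(self.data)

    def copy(self) -> "CohortTable":
        return replace(self, data=self.data.copy())

    def subset(self, mask) -> "CohortTable":
        return replace(self, data=self.data.loc[mask].reset_index(drop=True))

    def validate(self) -> None:
        df = self.data
        for col in [self.outcome, *self.covariates]:
            if col not in df.columns:
                raise ValueError(f"missing analysis column: {col}")
            if df[col].isna().any():
                raise ValueError(f"missing values in analysis column {col!r}")
        if self.stratum is not None and self.stratum not in df.columns:
            raise ValueError(f"missing stratum column: {self.stratum}")
        for w in self.windows:
            for m in self.metals:
                col = self.exposure_column(m, w)
                if col not in df.columns:
                    raise ValueError(f"missing exposure column: {col}")
                vals = df[col]
                flagged = self._flags(m, w)
                unflagged = vals[~flagged]
                if unflagged.isna().any():
                    raise ValueError(f"missing unflagged concentrations in {col}")
                if (unflagged <= 0).any():
                    bad = df.index[(vals <= 0) & ~flagged][0]
                    raise ValueError(
                        f"non-positive concentration in {col} at subject index {bad}"
                    )

    def _flags(self, metal: str, window: str) -> pd.Series:
        col = self.flag_column(metal, window)
        if col in self.data.columns:
            return self.data[col].astype(bool)
        return pd.Series(False, index=self.data.index)


def impute_below_lod(table: CohortTable) -> CohortTable:
    """Replace below-detection concentrations by LOD / 2.

    Unflagged cells are untouched; per-(metal, window) imputation counts are
    logged and stored on the returned table.
    """
    if table.stage != "raw":
        raise ValueError(f"impute_below_lod expects a raw table, got stage {table.stage!r}")
    out = table.copy()
    counts = {}
    for w in table.windows:
        for m in table.metals:
            flags = table._flags(m, w)
            nflag = int(flags.sum())
            counts[(m, w)] = nflag
            if nflag == 0:
                continue
            lod_col = table.lod_column(m, w)
            if lod_col not in table.data.columns:
                raise ValueError(f"flagged cells in {table.exposure_column(m, w)} without a {lod_col} column")
            lods = table.data.loc[flags, lod_col]
            if lods.isna().any() or (lods <= 0).any():
                bad = lods.index[lods.isna() | (lods <= 0)][0]
                raise ValueError(
                    f"flagged cell without a valid LOD: metal {m}, window {w}, subject index {bad}"
                )
            out.data.loc[flags, table.exposure_column(m, w)] = lods / 2.0
            logger.info("imputed %d below-LOD cells as LOD/2 in %s", nflag, table.exposure_column(m, w))
    out.stage = "imputed"
    out.imputation_counts = counts
    return out


def log2_transform(table: CohortTable) -> CohortTable:
    """log2 every exposure column; outcome and covariates untouched."""
    if table.stage != "imputed":
        raise ValueError(
            "log2_transform must follow impute_below_lod "
            f"(pipeline order impute -> log2 -> standardize; got stage {table.stage!r})"
        )
    out = table.copy()
    for w in table.windows:
        for m in table.metals:
            col = table.exposure_column(m, w)
            vals = out.data[col].to_numpy(dtype=float)
            if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
                bad = int(np.flatnonzero(~np.isfinite(vals) | (vals <= 0))[0])
                raise ValueError(f"non-positive concentration in {col} at subject index {bad}")
            out.data[col] = np.log2(vals)
    out.stage = "log2"
    return out


@dataclass
class StandardizedDesign:
    """Model-ready matrices plus the transforms back to natural units.

    ``quantiles[t, m]`` holds (q05, q25, q50, q75, q95) of the standardized
    log2 exposure for metal m in window t -- the single quantile source for
    every contrast downstream.
    """

    y: np.ndarray
    y_mean: float
    y_sd: float
    X: np.ndarray
    x_names: list
    Z: list
    metals: list
    windows: list
    exp_mean: np.ndarray  # (T, M) means of log2 concentrations
    exp_sd: np.ndarray  # (T, M)
    quantiles: np.ndarray  # (T, M, 5)
    cov_stats: dict  # continuous covariate name -> (mean, sd)

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def T(self) -> int:
        return len(self.windows)

    def window_index(self, window) -> int:
        if isinstance(window, str):
            return self.windows.index(window)
        w = int(window)
        if 1 <= w <= len(self.windows):
            return w - 1
        raise ValueError(f"unknown window {window!r} (labels {self.windows})")

    def metal_index(self, metal: str) -> int:
        try:
            return self.metals.index(metal)
        except ValueError:
            raise ValueError(f"unknown metal {metal!r} (metals {self.metals})") from None

    def quantile(self, metal: str, window, which: str) -> float:
        t, m = self.window_index(window), self.metal_index(metal)
        return float(self.quantiles[t, m, _QIDX[which]])

    def destandardized_exposures(self) -> list:
        """Recover the log2 concentrations from the stored means/SDs."""
        return [
            Z * self.exp_sd[t] + self.exp_mean[t] for t, Z in enumerate(self.Z)
        ]


def _standardize_column(vals: np.ndarray, name: str) -> tuple[np.ndarray, float, float]:
    if np.unique(vals).size < 3:
        raise ValueError(f"column {name!r} has fewer than 3 distinct values; cannot standardize")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    if sd == 0:
        raise ValueError(f"constant column {name!r} cannot be standardized")
    return (vals - mean) / sd, mean, sd


def standardize(table: CohortTable) -> StandardizedDesign:
    """Build the model-ready design from a log2-stage table.

    Outcome, exposures and continuous covariates are standardized to mean 0,
    variance 1 (SD with n-1 denominator).  Quadratic covariate terms square
    the standardized column and re-standardize; categorical covariates are
    dummy-coded against their first level.  No intercept column is included:
    the quadratic kernel's offset feature spans constants, so the window
    surfaces absorb the outcome level and an explicit intercept would only
    create a flat ridge between the covariate block and the kernel block.
    """
    if table.stage != "log2":
        raise ValueError(
            "standardize must follow log2_transform "
            f"(pipeline order impute -> log2 -> standardize; got stage {table.stage!r})"
        )
    df = table.data
    n = len(df)
    y, y_mean, y_sd = _standardize_column(df[table.outcome].to_numpy(dtype=float), table.outcome)

    cols = []
    names = []
    cov_stats = {}
    for name, role in table.covariates.items():
        if role in ("continuous", "quadratic"):
            z, mean, sd = _standardize_column(df[name].to_numpy(dtype=float), name)
            cov_stats[name] = (mean, sd)
            cols.append(z)
            names.append(name)
            if role == "quadratic":
                zsq, _, _ = _standardize_column(z**2, f"{name}_sq")
                cols.append(zsq)
                names.append(f"{name}_sq")
        elif role == "categorical":
            levels = table.covariate_levels.get(name)
            if levels is None:
                levels = list(pd.unique(df[name]))
            observed = set(df[name])
            unknown = observed - set(levels)
            if unknown:
                raise ValueError(f"unknown level(s) {sorted(unknown)} in categorical covariate {name!r}")
            for level in levels[1:]:  # first listed level is the reference
                cols.append((df[name] == level).to_numpy(dtype=float))
                names.append(f"{name}={level}")
        else:
            raise ValueError(f"unknown covariate role {role!r} for {name!r} (roles: {ROLES})")
    X = np.column_stack(cols) if cols else np.zeros((n, 0))

    T, M = len(table.windows), len(table.metals)
    Z = []
    exp_mean = np.zeros((T, M))
    exp_sd = np.zeros((T, M))
    quantiles = np.zeros((T, M, len(QUANTILE_LEVELS)))
    for t, w in enumerate(table.windows):
        Zt = np.empty((n, M))
        for m_i, m in enumerate(table.metals):
            col = table.exposure_column(m, w)
            z, mean, sd = _standardize_column(df[col].to_numpy(dtype=float), col)
            Zt[:, m_i] = z
            exp_mean[t, m_i] = mean
            exp_sd[t, m_i] = sd
            quantiles[t, m_i] = np.quantile(z, QUANTILE_LEVELS)
        Z.append(Zt)

    return StandardizedDesign(
        y=y, y_mean=y_mean, y_sd=y_sd, X=X, x_names=names, Z=Z,
        metals=list(table.metals), windows=list(table.windows),
        exp_mean=exp_mean, exp_sd=exp_sd, quantiles=quantiles, cov_stats=cov_stats,
    )


def prepare(table: CohortTable) -> StandardizedDesign:
    """The full fixed pipeline: impute -> log2 -> standardize."""
    table.validate()
    return standardize(log2_transform(impute_below_lod(table)))


def iqr_transform(df: pd.DataFrame, columns) -> pd.DataFrame:
    """Center each named column at its median and scale by its IQR.

    A one-unit change in a transformed column is one interquartile range;
    the transformed column has IQR exactly 1.
    """
    out = df.copy()
    for col in columns:
        vals = df[col].to_numpy(dtype=float)
        q25, q50, q75 = np.quantile(vals, [0.25, 0.50, 0.75])
        iqr = q75 - q25
        if iqr <= 0:
            raise ValueError(f"zero IQR in column {col!r}; cannot IQR-transform")
        out[col] = (vals - q50) / iqr
    return out


def pc_scores(matrix, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First k principal-component scores of a standardized matrix.

    Columns are standardized (mean 0, SD 1, n-1 denominator) before the
    singular value decomposition.  Sign convention: each component's
    largest-magnitude loading is positive.  Returns (scores n x k, loadings
    m x k, explained-variance fractions length k).
    """
    if isinstance(matrix, pd.DataFrame):
        names = list(matrix.columns)
        A = matrix.to_numpy(dtype=float)
    else:
        A = np.asarray(matrix, dtype=float)
        names = [f"c{i}" for i in range(A.shape[1])]
    if k > A.shape[1]:
        raise ValueError(f"k = {k} exceeds the number of columns ({A.shape[1]})")
    std = np.empty_like(A)
    for i in range(A.shape[1]):
        std[:, i], _, _ = _standardize_column(A[:, i], names[i])
    U, s, Vt = np.linalg.svd(std, full_matrices=False)
    tol = s[0] * max(std.shape) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    if k > rank:
        raise ValueError(f"k = {k} exceeds the matrix rank ({rank})")
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    for i in range(k):
        top = np.argmax(np.abs(loadings[:, i]))
        if loadings[top, i] < 0:
            loadings[:, i] *= -1
            scores[:, i] *= -1
    evr = s[:k] ** 2 / np.sum(s**2)
    return scores, loadings, evr
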