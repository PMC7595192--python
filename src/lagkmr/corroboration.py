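"""Parametric corroboration of the kernel-machine findings.

Contrasts whose 95% credible interval excludes zero are entered into an
ordinary least squares model of the raw outcome score on IQR-transformed
log2 concentrations of the selected metals (plus products for selected
interactions, with the hierarchy rule that interactions drag in their main
effects), the covariates, and the first three principal components of the
non-selected metal columns as a parsimonious control for co-metal
confounding.  Coefficients are per IQR of log2 concentration, with
normal-theory 95% confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import statsmodels.api as sm

from .preprocessing import (
    CohortTable,
    impute_below_lod,
    iqr_transform,
    log2_transform,
    pc_scores,
    standardize,
)

logger = logging.getLogger(__name__)


@dataclass
class CorroborationSpec:
    """Terms selected for the parametric model."""

    selected_main_terms: list = field(default_factory=list)  # [(metal, window), ...]
    selected_interactions: list = field(default_factory=list)  # [(metal_a, metal_b, window), ...]
    n_comet_pcs: int = 3

    def __post_init__(self) -> None:
        # hierarchy rule: interactions imply their main effects
        mains = list(self.selected_main_terms)
        for ma, mb, w in self.selected_interactions:
            for m in (ma, mb):
                if (m, w) not in mains:
                    mains.append((m, w))
        self.selected_main_terms = mains

    @property
    def selected_metal_windows(self) -> set:
        return set(self.selected_main_terms)


def select_terms(effect_frame: pd.DataFrame, n_comet_pcs: int = 3) -> CorroborationSpec:
    """Build a :class:`CorroborationSpec` from an effect-estimate table.

    Statistical significance at alpha = 0.05 is operationalized as the 95%
    credible interval excluding zero.  Structural zeros and degenerate
    contrasts never qualify.
    """
    df = effect_frame
    eligible = ~(df.get("structural_zero", False) | df.get("degenerate", False))
    sig = eligible & ((df.cri95_lower > 0) | (df.cri95_upper < 0))
    mains = [
        (r.metal, r.window)
        for r in df[sig & (df.contrast_type == "main")].itertuples()
    ]
    inters = [
        (r.metal, r.partner_metal, r.window)
        for r in df[sig & (df.contrast_type == "interaction")].itertuples()
    ]
    if not mains and not inters:
        logger.info("no contrasts with CrI excluding 0; corroboration model "
                    "will contain only covariates and co-metal PCs")
    return CorroborationSpec(mains, inters, n_comet_pcs=n_comet_pcs)


def fit_corroboration(table: CohortTable, spec: CorroborationSpec) -> pd.DataFrame:
    """OLS of the raw outcome on the selected IQR-scaled metal terms.

    Returns a coefficient table (term, kind, coef, se, ci95_lower,
    ci95_upper, pvalue).  Raises on rank deficiency, naming the collinear
    columns.
    """
    if table.stage == "raw":
        table = log2_transform(impute_below_lod(table))
    elif table.stage != "log2":
        raise ValueError(f"corroboration expects a raw or log2-stage table, got {table.stage!r}")
    df = table.data
    y = df[table.outcome].to_numpy(dtype=float)

    cols: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}
    selected_cols = {
        (m, w): table.exposure_column(m, w) for m, w in spec.selected_main_terms
    }
    if selected_cols:
        iqr_df = iqr_transform(df, list(selected_cols.values()))
        for (m, w), col in selected_cols.items():
            name = f"{m}_{w}_iqr"
            cols[name] = iqr_df[col].to_numpy(dtype=float)
            kinds[name] = "metal_main"
        for ma, mb, w in spec.selected_interactions:
            name = f"{ma}_x_{mb}_{w}_iqr"
            cols[name] = (
                iqr_df[selected_cols[(ma, w)]].to_numpy(dtype=float)
                * iqr_df[selected_cols[(mb, w)]].to_numpy(dtype=float)
            )
            kinds[name] = "metal_interaction"

    # covariates, via the same design construction as the mixture model
    design = standardize(table)
    for j, name in enumerate(design.x_names):
        cols[name] = design.X[:, j]
        kinds[name] = "covariate"

    # first PCs of the standardized non-selected metal columns
    non_selected = [
        table.exposure_column(m, w)
        for w in table.windows for m in table.metals
        if (m, w) not in spec.selected_metal_windows
    ]
    if non_selected and spec.n_comet_pcs > 0:
        k = min(spec.n_comet_pcs, len(non_selected))
        scores, _, _ = pc_scores(df[non_selected], k)
        for i in range(k):
            name = f"comet_pc{i + 1}"
            cols[name] = scores[:, i]
            kinds[name] = "comet_pc"

    X = pd.DataFrame(cols)
    X.insert(0, "const", 1.0)
    kinds["const"] = "intercept"
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, _, piv = sla.qr(X.to_numpy(), mode="economic", pivoting=True)
        bad = [X.columns[i] for i in piv[rank:]]
        raise ValueError(f"rank-deficient corroboration design; collinear columns: {bad}")

    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    out = pd.DataFrame({
        "term": res.params.index,
        "kind": [kinds[t] for t in res.params.index],
        "coef": res.params.values,
        "se": res.bse.values,
        "ci95_lower": ci[0].values,
        "ci95_upper": ci[1].values,
        "pvalue": res.pvalues.values,
    })
    return out
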