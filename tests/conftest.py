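"""Shared fixtures: small synthetic designs and cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lagkmr.preprocessing import CohortTable, prepare
from lagkmr.synthetic import (
    CovariateSpec,
    GeneratorConfig,
    SurfaceSpec,
    generate_cohort,
)

SMALL_COVS = [
    CovariateSpec("age", "continuous", mean=32.0, sd=4.5, role="quadratic"),
    CovariateSpec("sex", "categorical", levels=("female", "male"), probs=(0.5, 0.5),
                  role="categorical"),
]


def make_design(n=60, T=2, M=3, seed=0, surface=None, covariates=None):
    metals = ["As", "Cu", "Mn", "Pb", "Se", "Zn"][:M]
    windows = ["maternal_prenatal", "maternal_postnatal", "infant"][:T]
    cfg = GeneratorConfig(
        n_subjects=n, metals=metals, windows=windows,
        covariates=list(covariates if covariates is not None else SMALL_COVS),
        surface=surface or SurfaceSpec(linear=((metals[0], 1, 0.3),)),
        seed=seed,
    )
    table, truth = generate_cohort(cfg)
    return prepare(table), table, truth


@pytest.fixture(scope="session")
def small_design():
    design, _, _ = make_design()
    return design


@pytest.fixture(scope="session")
def small_cohort():
    cfg = GeneratorConfig(n_subjects=120, seed=11)
    return generate_cohort(cfg)


def toy_table(n=40, seed=0):
    """Hand-built two-metal, two-window cohort table at the raw stage."""
    rng = np.random.default_rng(seed)
    metals, windows = ["As", "Mn"], ["w1", "w2"]
    data = {"subject_id": np.arange(1, n + 1)}
    for w in windows:
        for m in metals:
            data[f"{m}_{w}"] = np.exp(rng.normal(size=n))
            data[f"{m}_{w}_belowLOD"] = np.zeros(n, dtype=bool)
            data[f"{m}_{w}_LOD"] = np.full(n, np.nan)
    data["age"] = rng.normal(30, 5, size=n)
    data["sex"] = np.where(rng.random(n) < 0.5, "female", "male")
    data["outcome"] = rng.normal(size=n)
    table = CohortTable(
        data=pd.DataFrame(data), metals=metals, windows=windows,
        outcome="outcome", covariates={"age": "quadratic", "sex": "categorical"},
        stratum="sex", covariate_levels={"sex": ["female", "male"]},
    )
    return table
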