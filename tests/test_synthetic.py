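"""Synthetic cohort generator: structure, censoring, ground truth."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from lagkmr.preprocessing import prepare
from lagkmr.synthetic import (
    GeneratorConfig,
    SurfaceSpec,
    generate_cohort,
    latent_correlation,
    null_surface,
    single_linear_surface,
    true_contrast,
    write_cohort,
)


def test_reproducibility_byte_identical(tmp_path):
    cfg = lambda: GeneratorConfig(n_subjects=150, seed=9)
    t1, _ = generate_cohort(cfg())
    t2, _ = generate_cohort(cfg())
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_cohort(t1, p1)
    write_cohort(t2, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_full_detection_no_flags():
    cfg = GeneratorConfig(n_subjects=100, detection_frequency=1.0, seed=1)
    table, _ = generate_cohort(cfg)
    flags = [c for c in table.data.columns if c.endswith("belowLOD")]
    assert table.data[flags].to_numpy().sum() == 0


def test_detection_frequency_reproduced():
    cfg = GeneratorConfig(n_subjects=400, detection_frequency=0.9, seed=2)
    table, _ = generate_cohort(cfg)
    for w in cfg.windows:
        for m in cfg.metals:
            frac = 1.0 - table.data[f"{m}_{w}_belowLOD"].mean()
            assert frac == pytest.approx(0.9, abs=0.02)


def test_within_window_spearman_near_target():
    cfg = GeneratorConfig(n_subjects=500, rho_within=0.3, rho_between=0.3,
                          rho_background=0.1, detection_frequency=1.0, seed=3)
    table, _ = generate_cohort(cfg)
    meds = []
    for w in cfg.windows:
        cols = [f"{m}_{w}" for m in cfg.metals]
        rho, _ = spearmanr(table.data[cols])
        meds.append(np.median(rho[np.triu_indices(len(cols), 1)]))
    assert np.median(meds) == pytest.approx(0.3, abs=0.07)


def test_null_surface_outcome_uncorrelated():
    cfg = GeneratorConfig(n_subjects=500, surface=null_surface(), noise_sd=1.0,
                          detection_frequency=1.0, seed=4)
    table, _ = generate_cohort(cfg)
    y = table.data["outcome"]
    for w in cfg.windows:
        for m in cfg.metals:
            r = np.corrcoef(y, np.log2(table.data[f"{m}_{w}"]))[0, 1]
            assert abs(r) < 0.15


def test_marginal_medians_match_geometric_medians():
    cfg = GeneratorConfig(n_subjects=2000, detection_frequency=1.0, seed=5)
    table, _ = generate_cohort(cfg)
    for t, w in enumerate(cfg.windows):
        for m in cfg.metals:
            gm = np.atleast_1d(cfg.geometric_medians[m])[t]
            med = np.median(table.data[f"{m}_{w}"])
            assert np.log2(med / gm) == pytest.approx(0.0, abs=3 * 1.2533 * 1.5 / np.sqrt(2000))


def test_pipeline_standardization_round_trip():
    table, _ = generate_cohort(GeneratorConfig(n_subjects=300, seed=6))
    design = prepare(table)
    for Zt in design.Z:
        assert np.abs(Zt.mean(0)).max() < 1e-10
        assert np.abs(Zt.var(0, ddof=1) - 1).max() < 1e-10


class TestTrueContrast:
    def test_linear_closed_form(self):
        slope = 0.4
        cfg = GeneratorConfig(n_subjects=400, surface=single_linear_surface("Mn", 3, slope), seed=7)
        table, truth = generate_cohort(cfg)
        design = prepare(table)
        t, m = 2, design.metals.index("Mn")
        q25, q75 = design.quantiles[t, m, 1], design.quantiles[t, m, 3]
        # slope per latent SD -> standardized-column slope -> standardized outcome
        expected = slope * (q75 - q25) * design.exp_sd[t, m] / cfg.log2_sd["Mn"] / design.y_sd
        assert true_contrast(truth, "Mn", 3) == pytest.approx(expected, rel=1e-10)

    def test_absent_term_is_zero(self):
        cfg = GeneratorConfig(n_subjects=200, surface=single_linear_surface("Mn", 3, 0.4), seed=8)
        _, truth = generate_cohort(cfg)
        assert true_contrast(truth, "Pb", 1) == 0.0

    def test_interaction_double_difference_algebra(self):
        c = 0.25
        cfg = GeneratorConfig(
            n_subjects=400, surface=SurfaceSpec(interactions=(("As", "Se", 3, c),)), seed=9
        )
        table, truth = generate_cohort(cfg)
        design = prepare(table)
        t = 2
        a, b = design.metals.index("As"), design.metals.index("Se")
        da = (design.quantiles[t, a, 3] - design.quantiles[t, a, 1]) * design.exp_sd[t, a] / cfg.log2_sd["As"]
        db = (design.quantiles[t, b, 3] - design.quantiles[t, b, 1]) * design.exp_sd[t, b] / cfg.log2_sd["Se"]
        expected = c * da * db / design.y_sd
        got = true_contrast(truth, "As", 3, "interaction", "Se")
        assert got == pytest.approx(expected, rel=1e-10)
        # symmetric lookup
        assert got == true_contrast(truth, "Se", 3, "interaction", "As")

    def test_errors(self):
        _, truth = generate_cohort(GeneratorConfig(n_subjects=120, seed=10))
        with pytest.raises(ValueError, match="unknown metal"):
            true_contrast(truth, "Hg", 1)
        with pytest.raises(ValueError, match="partner"):
            true_contrast(truth, "Mn", 1, "interaction")
        with pytest.raises(ValueError, match="unknown window"):
            true_contrast(truth, "Mn", 7)


def test_stratum_specific_truth():
    male = single_linear_surface("Mn", 3, 0.5)
    female = null_surface()
    cfg = GeneratorConfig(
        n_subjects=400, surface=male, surface_by_stratum={"male": male, "female": female},
        seed=11,
    )
    _, truth = generate_cohort(cfg)
    assert truth.strata is not None
    assert true_contrast(truth, "Mn", 3, stratum="male") > 0.3
    assert true_contrast(truth, "Mn", 3, stratum="female") == 0.0


def test_correlation_beyond_repair_fails():
    cfg = GeneratorConfig(n_subjects=50, rho_within=-0.5)
    with pytest.raises(ValueError, match="positive definite"):
        latent_correlation(cfg)


def test_correlation_mild_repair_logged(caplog):
    cfg = GeneratorConfig(n_subjects=50, rho_within=1.0, rho_between=0.0, rho_background=0.0)
    with caplog.at_level("WARNING"):
        R = latent_correlation(cfg)
    assert "repair" in caplog.text
    assert np.linalg.eigvalsh(R).min() > 0


def test_invalid_config_rejected():
    with pytest.raises(ValueError, match="detection"):
        GeneratorConfig(n_subjects=10, detection_frequency=0.0).validate()
    with pytest.raises(ValueError, match="noise_sd"):
        GeneratorConfig(n_subjects=10, noise_sd=0.0).validate()
    with pytest.raises(ValueError, match="unknown metal"):
        GeneratorConfig(n_subjects=10, surface=single_linear_surface("Hg", 1, 1.0)).validate()
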