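"""Percentile-contrast estimands and their structural properties."""

import numpy as np
import pandas as pd
import pytest

from lagkmr.estimands import (
    cross_window_interaction,
    dose_response,
    effects_to_frame,
    interaction_effect,
    main_effect,
    percentile_profile,
    stratified_analysis,
)
from lagkmr.model import fit_mfvb, LKMRHyperparameters, predict_window_surface
from lagkmr.preprocessing import prepare
from lagkmr.synthetic import (
    GeneratorConfig,
    SurfaceSpec,
    generate_cohort,
    single_linear_surface,
)

from conftest import make_design, toy_table


@pytest.fixture(scope="module")
def fitted():
    design, table, truth = make_design(n=80, T=3, M=3, seed=20)
    return fit_mfvb(design), design, table, truth


class TestPercentileProfile:
    def test_no_overrides_all_medians(self, fitted):
        _, design, _, _ = fitted
        prof = percentile_profile(design, 1)
        assert np.array_equal(prof, design.quantiles[0, :, 2])

    def test_single_override_changes_one_coordinate(self, fitted):
        _, design, _, _ = fitted
        base = percentile_profile(design, 2)
        prof = percentile_profile(design, 2, {"Mn": "q75"})
        diff = prof != base
        assert diff.sum() == 1
        assert prof[design.metal_index("Mn")] == design.quantile("Mn", 2, "q75")

    def test_unknown_metal(self, fitted):
        _, design, _, _ = fitted
        with pytest.raises(ValueError, match="unknown metal"):
            percentile_profile(design, 1, {"Hg": "q75"})

    def test_explicit_grid_value(self, fitted):
        _, design, _, _ = fitted
        prof = percentile_profile(design, 1, {"As": 1.5})
        assert prof[design.metal_index("As")] == 1.5


class TestMainEffect:
    def test_matches_manual_surface_difference(self, fitted):
        fit, design, _, _ = fitted
        est = main_effect(fit, "Mn", 3)
        hi = percentile_profile(design, 3, {"Mn": "q75"})
        lo = percentile_profile(design, 3, {"Mn": "q25"})
        mean, _ = predict_window_surface(fit, 2, np.vstack([hi, lo]))
        # covariates never enter: the contrast is exactly the surface difference
        assert est.estimate == pytest.approx(mean[0] - mean[1], abs=1e-12)
        assert est.cri95_lower <= est.estimate <= est.cri95_upper
        assert est.posterior_sd > 0

    def test_metal_relabeling_equivariance(self):
        cfg = GeneratorConfig(
            n_subjects=150, metals=["As", "Mn", "Se"],
            surface=single_linear_surface("Mn", 3, 0.4), seed=21,
        )
        table, _ = generate_cohort(cfg)
        fit = fit_mfvb(prepare(table))
        est_mn = main_effect(fit, "Mn", 3, allow_nonconverged=True)
        # relabel As <-> Mn throughout the table
        ren = {}
        for w in cfg.windows:
            for suf in ("", "_belowLOD", "_LOD"):
                ren[f"As_{w}{suf}"] = f"Mn_{w}{suf}"
                ren[f"Mn_{w}{suf}"] = f"As_{w}{suf}"
        swapped = table.copy()
        swapped.data = swapped.data.rename(columns=ren)
        fit2 = fit_mfvb(prepare(swapped))
        est_as = main_effect(fit2, "As", 3, allow_nonconverged=True)
        # equal up to floating-point reordering of the column permutation
        assert est_as.estimate == pytest.approx(est_mn.estimate, abs=1e-6)

    def test_degenerate_quantiles_exact_zero(self):
        table = toy_table(n=40, seed=3)
        vals = np.ones(40)
        vals[:2] = [0.5, 2.0]  # 3 distinct values but q25 == q75 == 1
        table.data["As_w1"] = vals
        design = prepare(table)
        fit = fit_mfvb(design)
        with pytest.warns(UserWarning, match="degenerate"):
            est = main_effect(fit, "As", 1, allow_nonconverged=True)
        assert est.estimate == 0.0
        assert est.degenerate

    def test_nonconverged_refused(self, fitted):
        _, design, _, _ = fitted
        stub = fit_mfvb(design, LKMRHyperparameters(max_iterations=2))
        assert not stub.converged
        with pytest.raises(RuntimeError, match="converge"):
            main_effect(stub, "Mn", 1)
        main_effect(stub, "Mn", 1, allow_nonconverged=True)  # explicit override


class TestInteractionEffect:
    def test_symmetry_in_metals(self, fitted):
        fit, _, _, _ = fitted
        a = interaction_effect(fit, "As", "Mn", 2)
        b = interaction_effect(fit, "Mn", "As", 2)
        assert a.estimate == pytest.approx(b.estimate, abs=1e-10)
        assert a.posterior_sd == pytest.approx(b.posterior_sd, abs=1e-10)

    def test_same_metal_rejected(self, fitted):
        fit, _, _, _ = fitted
        with pytest.raises(ValueError, match="distinct"):
            interaction_effect(fit, "Mn", "Mn", 1)


class TestCrossWindowInteraction:
    def test_structural_zero(self, fitted):
        fit, _, _, _ = fitted
        est = cross_window_interaction(fit, "As", 1, "Cu", 3)
        assert est.estimate == 0.0
        assert est.posterior_sd == 0.0
        assert est.structural_zero
        assert est.to_dict()["structural_zero"] is True

    def test_same_window_redirected(self, fitted):
        fit, _, _, _ = fitted
        with pytest.raises(ValueError, match="interaction_effect"):
            cross_window_interaction(fit, "As", 2, "Cu", 2)


class TestDoseResponse:
    def test_shapes_and_bands(self, fitted):
        fit, _, _, _ = fitted
        curve = dose_response(fit, "Mn", 3, n_grid=5)
        assert curve.grid.shape == (5,)
        assert np.all(np.diff(curve.grid) > 0)
        assert np.all(curve.lower95 <= curve.mean + 1e-12)
        assert np.all(curve.mean <= curve.upper95 + 1e-12)

    def test_min_grid(self, fitted):
        fit, _, _, _ = fitted
        with pytest.raises(ValueError, match="n_grid"):
            dose_response(fit, "Mn", 3, n_grid=4)

    def test_curvature_flags_quadratic_truth(self):
        pos = 0
        for i in range(6):
            cfg = GeneratorConfig(
                n_subjects=300,
                surface=SurfaceSpec(quadratic=(("Mn", 3, 0.25),)), seed=400 + i,
            )
            table, _ = generate_cohort(cfg)
            fit = fit_mfvb(prepare(table))
            if dose_response(fit, "Mn", 3, allow_nonconverged=True).curvature > 0:
                pos += 1
        assert pos >= 5

    def test_curvature_near_zero_for_linear_truth(self):
        curvs = []
        for i in range(6):
            cfg = GeneratorConfig(n_subjects=300, surface=single_linear_surface("Mn", 3, 0.3),
                                  seed=450 + i)
            table, _ = generate_cohort(cfg)
            fit = fit_mfvb(prepare(table))
            curvs.append(dose_response(fit, "Mn", 3, allow_nonconverged=True).curvature)
        assert abs(np.mean(curvs)) < 0.05


class TestSerialization:
    def test_effect_frame_round_trip(self, fitted, tmp_path):
        fit, _, _, _ = fitted
        frame = effects_to_frame([
            main_effect(fit, "Mn", 3), interaction_effect(fit, "As", "Cu", 1),
            cross_window_interaction(fit, "As", 1, "Cu", 2),
        ])
        path = tmp_path / "effects.csv"
        frame.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(
            back.fillna(""), frame.fillna(""), check_dtype=False
        )


class TestStratifiedAnalysis:
    def test_small_stratum_skipped_with_warning(self, caplog):
        table = toy_table(n=60, seed=9)
        table.data.loc[:, "sex"] = "female"
        table.data.loc[:4, "sex"] = "male"  # n = 5 males
        with caplog.at_level("WARNING"):
            res = stratified_analysis(table, min_stratum_n=50, allow_nonconverged=True)
        assert "pooled" in res and "female" in res and "male" not in res
        assert "skipping stratum" in caplog.text

    def test_homogeneous_surface_pooled_and_strata_agree(self):
        diffs = []
        for i in range(8):
            cfg = GeneratorConfig(n_subjects=300, surface=single_linear_surface("Mn", 3, 0.3),
                                  seed=600 + i)
            table, _ = generate_cohort(cfg)
            res = stratified_analysis(table, min_stratum_n=50, allow_nonconverged=True)
            def grab(df):
                row = df[(df.metal == "Mn") & (df.window == "infant")]
                return float(row.estimate.iloc[0])
            for level in ("female", "male"):
                diffs.append(grab(res[level]) - grab(res["pooled"]))
        # no systematic pooled-vs-stratum difference beyond sampling error
        assert abs(np.mean(diffs)) < 0.05

    def test_heterogeneous_surfaces_discriminated(self):
        male_surf = single_linear_surface("Mn", 3, 0.45)
        female_surf = SurfaceSpec()
        wins = 0
        for i in range(8):
            cfg = GeneratorConfig(
                n_subjects=400, surface=male_surf,
                surface_by_stratum={"male": male_surf, "female": female_surf},
                seed=700 + i,
            )
            table, _ = generate_cohort(cfg)
            res = stratified_analysis(table, min_stratum_n=50, allow_nonconverged=True)
            def grab(df):
                row = df[(df.metal == "Mn") & (df.window == "infant")]
                return float(row.estimate.iloc[0])
            if grab(res["male"]) > grab(res["female"]) + 0.05:
                wins += 1
        assert wins >= 6
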