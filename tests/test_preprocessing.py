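"""Preparation pipeline: LOD imputation, log2, standardization, IQR, PCs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lagkmr.preprocessing import (
    impute_below_lod,
    iqr_transform,
    log2_transform,
    pc_scores,
    prepare,
    standardize,
)

from conftest import toy_table


class TestImputeBelowLod:
    def test_lod_over_two(self):
        table = toy_table()
        col, flag, lod = "As_w1", "As_w1_belowLOD", "As_w1_LOD"
        table.data.loc[0, flag] = True
        table.data.loc[0, lod] = 0.04
        table.data.loc[0, col] = np.nan
        out = impute_below_lod(table)
        assert out.data.loc[0, col] == pytest.approx(0.02)

    def test_no_flags_identity(self):
        table = toy_table()
        out = impute_below_lod(table)
        pd.testing.assert_frame_equal(
            out.data[table.exposure_columns()], table.data[table.exposure_columns()]
        )

    def test_exact_count_changed(self):
        table = toy_table(n=25)  # 25 x 4 = 100 exposure cells
        flagged = [(i, "Mn_w2") for i in range(10)]
        for i, col in flagged:
            table.data.loc[i, f"{col}_belowLOD"] = True
            table.data.loc[i, f"{col}_LOD"] = 0.5
            table.data.loc[i, col] = np.nan
        before = table.data[table.exposure_columns()].copy()
        out = impute_below_lod(table)
        after = out.data[table.exposure_columns()]
        changed = (after != before) & ~(after.isna() & before.isna())
        assert int(changed.sum().sum()) == 10
        assert (after.loc[:9, "Mn_w2"] == 0.25).all()
        # every other cell bit-identical
        untouched = [c for c in table.exposure_columns() if c != "Mn_w2"]
        assert after[untouched].equals(before[untouched])
        assert out.imputation_counts[("Mn", "w2")] == 10

    def test_missing_lod_fails_naming_cell(self):
        table = toy_table()
        table.data.loc[3, "As_w1_belowLOD"] = True
        table.data.loc[3, "As_w1"] = np.nan
        with pytest.raises(ValueError, match="As.*w1.*3"):
            impute_below_lod(table)


class TestLog2Transform:
    @pytest.mark.parametrize("value,expected", [(1.0, 0.0), (0.25, -2.0), (8.0, 3.0)])
    def test_exact_values(self, value, expected):
        table = toy_table()
        table.data.loc[0, "As_w1"] = value
        out = log2_transform(impute_below_lod(table))
        assert out.data.loc[0, "As_w1"] == pytest.approx(expected)

    def test_nonpositive_fails(self):
        table = toy_table()
        table.data.loc[5, "Mn_w1"] = -1.0
        with pytest.raises(ValueError, match="Mn_w1.*5"):
            log2_transform(impute_below_lod(table))

    def test_order_enforced(self):
        table = toy_table()
        with pytest.raises(ValueError, match="impute"):
            log2_transform(table)
        with pytest.raises(ValueError, match="log2"):
            standardize(table)
        with pytest.raises(ValueError, match="raw"):
            impute_below_lod(impute_below_lod(table))


class TestStandardize:
    def test_mean_zero_var_one(self):
        design = prepare(toy_table())
        for Zt in design.Z:
            assert np.abs(Zt.mean(axis=0)).max() < 1e-10
            assert np.abs(Zt.var(axis=0, ddof=1) - 1).max() < 1e-10
        assert abs(design.y.mean()) < 1e-10
        assert abs(design.y.std(ddof=1) - 1) < 1e-10

    @given(a=st.floats(0.1, 50), b=st.floats(-100, 100))
    @settings(max_examples=20, deadline=None)
    def test_affine_invariance(self, a, b):
        x = np.array([1.0, 2.0, 4.0, 8.0, 9.0])
        z1 = (x - x.mean()) / x.std(ddof=1)
        y = a * x + b
        z2 = (y - y.mean()) / y.std(ddof=1)
        assert np.abs(z1 - z2).max() < 1e-8

    def test_normal_quantiles(self):
        rng = np.random.default_rng(5)
        table = toy_table(n=2000, seed=5)
        design = prepare(table)
        t, m = 0, 0
        assert design.quantiles[t, m, 1] == pytest.approx(-0.674, abs=0.06)
        assert design.quantiles[t, m, 3] == pytest.approx(0.674, abs=0.06)
        assert np.all(np.diff(design.quantiles[t, m]) >= 0)

    def test_constant_column_fails(self):
        table = toy_table()
        table.data["age"] = 5.0
        with pytest.raises(ValueError, match="age"):
            prepare(table)

    def test_round_trip_destandardize(self):
        table = toy_table()
        log2_table = log2_transform(impute_below_lod(table))
        design = standardize(log2_table)
        recovered = design.destandardized_exposures()
        for t, w in enumerate(design.windows):
            for m_i, m in enumerate(design.metals):
                orig = log2_table.data[f"{m}_{w}"].to_numpy()
                assert np.abs(recovered[t][:, m_i] - orig).max() < 1e-10

    def test_quantile_single_definition(self):
        design = prepare(toy_table())
        z = design.Z[1][:, 0]
        assert design.quantiles[1, 0, 3] == np.quantile(z, 0.75)

    def test_quadratic_and_dummy_columns(self):
        design = prepare(toy_table())
        assert "age" in design.x_names and "age_sq" in design.x_names
        assert "sex=male" in design.x_names  # first listed level is reference
        assert "sex=female" not in design.x_names


class TestIqrTransform:
    def test_forced_example(self):
        # q25=2, q75=6 -> value 6 maps to (6-4)/4 = 0.5
        df = pd.DataFrame({"x": [2.0, 2.0, 4.0, 6.0, 6.0]})
        out = iqr_transform(df, ["x"])
        assert out["x"].iloc[3] == pytest.approx(0.5)

    def test_zero_iqr_fails(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0, 9.0]})
        with pytest.raises(ValueError, match="zero IQR"):
            iqr_transform(df, ["x"])

    def test_transformed_iqr_is_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(size=200)})
        out = iqr_transform(df, ["x"])
        q = np.quantile(out["x"], [0.25, 0.75])
        assert q[1] - q[0] == pytest.approx(1.0)


class TestPcScores:
    def test_perfect_correlation_single_component(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        scores, _, evr = pc_scores(np.column_stack([x, 2 * x + 3]), k=1)
        assert evr[0] == pytest.approx(1.0)

    def test_orthogonal_equal_variance_symmetry(self):
        n = 40
        a = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
        b = np.tile([1.0, -1.0], n // 2)
        a[0] += 1e-9  # keep >= 3 distinct values without breaking symmetry
        b[0] += 1e-9
        _, _, evr = pc_scores(np.column_stack([a, b]), k=2)
        assert abs(evr[0] - evr[1]) < 1e-6

    def test_against_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(80, 4)) @ np.diag([3.0, 2.0, 1.0, 0.5])
        scores, loadings, evr = pc_scores(A, k=3)
        std = (A - A.mean(0)) / A.std(0, ddof=1)
        evals, evecs = np.linalg.eigh(std.T @ std)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for i in range(3):
            v = evecs[:, i]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            assert np.abs(loadings[:, i] - v).max() < 1e-8
            assert np.abs(scores[:, i] - std @ v).max() < 1e-8
        assert np.abs(evr - evals[:3] / evals.sum()).max() < 1e-10

    def test_k_exceeds_rank(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="rank|columns"):
            pc_scores(np.column_stack([x, 2 * x]), k=2)
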