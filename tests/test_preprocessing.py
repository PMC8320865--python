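"""Preprocessing grid tests: row transforms, fitted stats, OSC, transforms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spectrafuse.preprocessing import (ColumnBlock, PreprocessingRecipe,
                                       all_recipes, center_apply, center_fit,
                                       inverse_transform_reference, msc,
                                       msc_fit_reference, normalize_rows,
                                       osc_apply, osc_fit, sg_derivative, snv,
                                       transform_reference)

finite_rows = st.lists(
    st.floats(-100, 100, allow_nan=False), min_size=8, max_size=20)


class TestSGDerivative:
    def test_constant_row_first_derivative_zero(self):
        X = np.full((3, 15), 7.0)
        assert np.allclose(sg_derivative(X, order=1), 0.0, atol=1e-12)

    def test_linear_ramp_slope_recovered_everywhere(self):
        s = 0.37
        X = (s * np.arange(20))[None, :]
        d = sg_derivative(X, order=1)
        assert np.allclose(d, s, atol=1e-10)

    def test_quadratic_second_derivative_matches_polyfit_oracle(self):
        # independent oracle: per-point least-squares quadratic over the
        # centered window, evaluated where SciPy's filter interior applies
        rng = np.random.default_rng(0)
        X = rng.normal(size=(2, 30))
        window, poly = 7, 2
        d = sg_derivative(X, order=2, window=window, polyorder=poly)
        half = window // 2
        for i in range(X.shape[0]):
            for j in range(half, 30 - half):
                seg = X[i, j - half:j + half + 1]
                coef = np.polyfit(np.arange(-half, half + 1), seg, poly)
                assert d[i, j] == pytest.approx(2.0 * coef[0], abs=1e-8)

    def test_quadratic_curvature_constant(self):
        X = (0.5 * np.arange(25.0) ** 2)[None, :]
        d = sg_derivative(X, order=2)
        assert np.allclose(d, 1.0, atol=1e-9)

    def test_short_runs_pass_through_with_warning(self):
        X = np.arange(20.0)[None, :]
        runs = [np.arange(0, 3), np.arange(3, 20)]
        with pytest.warns(UserWarning, match="shorter than"):
            d = sg_derivative(X, order=1, runs=runs)
        assert np.array_equal(d[0, :3], X[0, :3])
        assert np.allclose(d[0, 3:], 1.0, atol=1e-10)

    def test_runs_are_independent_blocks(self):
        # a jump between blocks must not bleed into either side
        X = np.concatenate([np.zeros(10), np.full(10, 50.0)])[None, :]
        runs = [np.arange(10), np.arange(10, 20)]
        d = sg_derivative(X, order=1, runs=runs)
        assert np.allclose(d, 0.0, atol=1e-9)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            sg_derivative(np.ones((2, 10)), order=1, window=6)


class TestSNV:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(finite_rows)
    def test_rows_standardized(self, row):
        row = np.asarray(row)
        if row.std() < 1e-6:
            row = row + np.arange(row.size)
        out = snv(row[None, :])
        assert out.mean() == pytest.approx(0.0, abs=1e-10)
        assert out.std() == pytest.approx(1.0, abs=1e-10)

    def test_idempotent(self, rng):
        X = rng.normal(size=(4, 30))
        assert np.allclose(snv(snv(X)), snv(X), atol=1e-10)

    def test_removes_affine_row_effects(self, rng):
        base = rng.normal(size=30)
        X = np.stack([base, 3.5 * base + 2.0])
        out = snv(X)
        assert np.allclose(out[0], out[1], atol=1e-10)

    def test_zero_variance_row_rejected(self):
        with pytest.raises(ValueError):
            snv(np.ones((2, 5)))


class TestMSC:
    def test_reference_row_unchanged(self, rng):
        ref = rng.normal(size=25)
        out = msc(ref[None, :], ref)
        assert np.allclose(out[0], ref, atol=1e-10)

    def test_exact_affine_row_restored(self, rng):
        ref = rng.normal(size=25)
        out = msc((2.0 * ref + 5.0)[None, :], ref)
        assert np.allclose(out[0], ref, atol=1e-10)

    def test_coefficients_match_normal_equation_oracle(self, rng):
        X = rng.normal(size=(5, 20))
        ref = msc_fit_reference(X)
        out = msc(X, ref)
        A = np.column_stack([np.ones(20), ref])
        for i in range(5):
            a, b = np.linalg.lstsq(A, X[i], rcond=None)[0]
            assert np.allclose(out[i], (X[i] - a) / b, atol=1e-8)

    def test_flat_row_rejected(self, rng):
        ref = rng.normal(size=10)
        with pytest.raises(ValueError):
            msc(np.ones((1, 10)), ref)


class TestRowNormalize:
    def test_constant_row(self):
        out = normalize_rows(np.full((1, 9), 3.0))
        assert np.allclose(out, 1.0 / 3.0)

    def test_unit_norm_row_unchanged(self, rng):
        row = rng.normal(size=12)
        row /= np.linalg.norm(row)
        assert np.allclose(normalize_rows(row[None, :])[0], row, atol=1e-12)

    def test_output_norm_is_one(self, rng):
        X = rng.normal(size=(6, 15))
        norms = np.linalg.norm(normalize_rows(X), axis=1)
        assert np.allclose(norms, 1.0, atol=1e-12)


class TestCentering:
    def test_calibration_columns_centered(self, rng):
        X = rng.normal(5.0, 2.0, size=(20, 6))
        for stat in ("mean", "median"):
            c = center_fit(X, stat)
            out = center_apply(X, c)
            observed = out.mean(0) if stat == "mean" else np.median(out, axis=0)
            assert np.allclose(observed, 0.0, atol=1e-12)

    def test_prediction_row_at_calibration_mean_maps_to_zero(self, rng):
        X = rng.normal(size=(15, 4))
        c = center_fit(X, "mean")
        assert np.allclose(center_apply(c[None, :], c), 0.0, atol=1e-12)

    def test_median_center_hand_case(self):
        X = np.array([[1.0], [2.0], [6.0]])
        out = center_apply(X, center_fit(X, "median"))
        assert np.allclose(out.ravel(), [-1.0, 0.0, 4.0])

    def test_apply_before_fit_rejected(self):
        recipe = PreprocessingRecipe("A0", "B1", "C0")
        with pytest.raises(RuntimeError, match="before fit"):
            recipe.transform(np.ones((3, 4)))


class TestOSC:
    def _structured(self, rng, n=40, k=25):
        y = rng.normal(size=n)
        c = rng.normal(size=k)
        ortho = rng.normal(size=n)
        ortho -= y * (y @ ortho) / (y @ y)
        d = rng.normal(size=k)
        X = np.outer(y, c) + 3.0 * np.outer(ortho, d) + 0.01 * rng.normal(size=(n, k))
        return X - X.mean(0), y - y.mean()

    def test_removed_scores_orthogonal_to_y(self, rng):
        X, y = self._structured(rng)
        model = osc_fit(X, y, ncomp=2)
        for j in range(2):
            t = model.scores[:, j]
            assert abs(t @ y) / (np.linalg.norm(t) * np.linalg.norm(y)) < 1e-6

    def test_y_covariance_preserved(self, rng):
        # X = y c' + orthogonal structure: OSC must only strip variance from
        # the orthogonal part, leaving each column's covariance with y intact
        X, y = self._structured(rng)
        Xc = osc_apply(osc_fit(X, y, 1), X)
        cov_before = X.T @ y / len(y)
        cov_after = Xc.T @ y / len(y)
        assert np.allclose(cov_before, cov_after, atol=1e-6)
        assert np.linalg.norm(Xc) < np.linalg.norm(X)

    def test_zero_components_identity(self, rng):
        X, y = self._structured(rng)
        model = osc_fit(X, y, 0)
        assert np.array_equal(osc_apply(model, X), X)

    def test_ncomp_at_rank_rejected(self, rng):
        X = np.outer(rng.normal(size=10), rng.normal(size=6))  # rank 1
        with pytest.raises(ValueError):
            osc_fit(X, rng.normal(size=10), 1)

    def test_stored_weights_reapplied_to_new_data(self, rng):
        X, y = self._structured(rng)
        model = osc_fit(X, y, 1)
        Xnew = rng.normal(size=(8, X.shape[1]))
        out = osc_apply(model, Xnew)
        t = Xnew @ model.weights[:, 0]
        assert np.allclose(out, Xnew - np.outer(t, model.loadings[:, 0]))


class TestReferenceTransforms:
    def test_log10_values(self):
        out = transform_reference(np.array([10.0, 100.0]), "C1")
        assert np.allclose(out, [1.0, 2.0])

    def test_power_round_trip(self, rng):
        y = rng.uniform(1.0, 60.0, 50)
        for p in (0.5, 2.0):
            y_t = transform_reference(y, "C2", power_exponent=p)
            back = inverse_transform_reference(y_t, "C2", power_exponent=p)
            assert np.allclose(back, y, atol=1e-12)

    def test_identity(self, rng):
        y = rng.uniform(1.0, 60.0, 20)
        assert np.array_equal(transform_reference(y, "C0"), y)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            transform_reference(np.array([0.0, 1.0]), "C1")
        with pytest.raises(ValueError):
            transform_reference(np.array([-1.0]), "C2", power_exponent=0.5)


class TestRecipes:
    def test_grid_enumerates_63(self):
        recipes = all_recipes()
        assert len(recipes) == 63
        assert len({r.code for r in recipes}) == 63
        assert recipes[0].code == "A0,B1;C0"
        assert "A5,B2;C2" in {r.code for r in recipes}

    def test_code_round_trip(self):
        r = PreprocessingRecipe.from_code("A5,B2;C2")
        assert (r.stage1, r.stage2, r.ref_transform) == ("A5", "B2", "C2")
        assert r.code == "A5,B2;C2"

    @pytest.mark.parametrize("code", ["A1,B1;C0", "A5,B2;C2", "A6,B3;C1",
                                      "A4,B2;C0", "A3,B3;C2"])
    def test_fit_transform_shapes_and_stats(self, code, rng):
        Xcal = rng.normal(1.0, 0.2, size=(30, 24)) + 0.5
        Xpred = rng.normal(1.0, 0.2, size=(10, 24)) + 0.5
        y = rng.uniform(4.0, 50.0, 30)
        recipe = PreprocessingRecipe.from_code(code)
        assert recipe.fitted_stats is None
        out = recipe.fit_transform(Xcal, recipe.transform_y(y))
        assert recipe.fitted_stats is not None
        assert out.shape == Xcal.shape
        assert recipe.transform(Xpred).shape == Xpred.shape

    @pytest.mark.parametrize("code", ["A5,B1;C0", "A6,B2;C0", "A0,B3;C2",
                                      "A4,B1;C1"])
    def test_no_leakage_from_prediction_rows(self, code, rng):
        # fitted statistics are a function of calibration data alone:
        # transforming permuted prediction rows must not alter them
        Xcal = rng.normal(1.0, 0.2, size=(30, 24)) + 0.5
        Xpred = rng.normal(1.0, 0.2, size=(12, 24)) + 0.5
        y = rng.uniform(4.0, 50.0, 30)
        recipe = PreprocessingRecipe.from_code(code)
        recipe.fit(Xcal, recipe.transform_y(y))
        snapshot = _stats_snapshot(recipe)
        out1 = recipe.transform(Xpred)
        perm = rng.permutation(12)
        out2 = recipe.transform(Xpred[perm])
        assert np.allclose(out1[perm], out2)
        assert _snapshots_equal(snapshot, _stats_snapshot(recipe))

    def test_snv_recipe_idempotence(self, rng):
        X = rng.normal(size=(10, 30))
        assert np.allclose(snv(snv(X)), snv(X), atol=1e-12)


def _stats_snapshot(recipe):
    out = {}
    for key, val in recipe.fitted_stats.items():
        if isinstance(val, list):
            out[key] = [np.array(v, copy=True) for v in val]
        elif hasattr(val, "weights"):
            out[key] = (val.weights.copy(), val.loadings.copy())
        else:
            out[key] = np.array(val, copy=True)
    return out


def _snapshots_equal(a, b):
    if a.keys() != b.keys():
        return False
    for key in a:
        va, vb = a[key], b[key]
        if isinstance(va, list):
            if not all(np.array_equal(x, y) for x, y in zip(va, vb)):
                return False
        elif isinstance(va, tuple):
            if not all(np.array_equal(x, y) for x, y in zip(va, vb)):
                return False
        elif not np.array_equal(va, vb):
            return False
    return True
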