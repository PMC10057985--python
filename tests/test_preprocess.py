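import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nirtrace import preprocess as pp
from nirtrace.errors import (DegenerateSpectrumError, ParameterError,
                             PipelineStepError)
from nirtrace.spectra import WavenumberGrid

from conftest import make_set


class TestSNV:
    def test_forced_example(self):
        out = pp.snv(make_set([[1.0, 2.0, 3.0]]))
        assert np.allclose(out.absorbance[0], [-1.0, 0.0, 1.0])

    def test_constant_row_is_degenerate(self):
        with pytest.raises(DegenerateSpectrumError, match="s0"):
            pp.snv(make_set([[5.0, 5.0, 5.0, 5.0]]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_rows_standardized_to_machine_precision(self, seed):
        a = np.random.default_rng(seed).normal(size=(3, 20)) * 2 + 1
        out = pp.snv(make_set(a)).absorbance
        assert np.abs(out.mean(axis=1)).max() < 1e-12
        assert np.abs(out.std(axis=1, ddof=1) - 1).max() < 1e-12


class TestMSC:
    def test_affine_distortion_recovers_reference(self, rng):
        base = rng.normal(size=(5, 40)) + 3
        s = make_set(base)
        step = pp.msc_fit(s)
        ref = step.fitted_state["reference"]
        distorted = make_set(2.0 * ref + 0.5, labels=["A"])
        corrected = pp.msc_apply(step, distorted)
        assert np.allclose(corrected.absorbance[0], ref, atol=1e-10)

    def test_reference_spectrum_is_fixed_point(self, rng):
        s = make_set(rng.normal(size=(4, 30)) + 2)
        step = pp.msc_fit(s)
        ref = step.fitted_state["reference"]
        out = pp.msc_apply(step, make_set(ref, labels=["A"]))
        assert np.allclose(out.absorbance[0], ref, atol=1e-10)

    def test_corrected_regresses_with_unit_slope(self, rng):
        s = make_set(rng.normal(size=(6, 50)) * rng.lognormal(size=(6, 1)) + 2)
        step = pp.msc_fit(s)
        out = pp.msc_apply(step, s).absorbance
        ref = step.fitted_state["reference"]
        A = np.column_stack([np.ones(50), ref])
        for row in out:
            intercept, slope = np.linalg.lstsq(A, row, rcond=None)[0]
            assert abs(slope - 1) < 1e-10 and abs(intercept) < 1e-10

    def test_needs_two_training_spectra(self, rng):
        with pytest.raises(ParameterError):
            pp.msc_fit(make_set(rng.normal(size=(1, 10)), labels=["A"]))


class TestOSC:
    def test_removed_scores_orthogonal_to_y(self, rng):
        X = rng.normal(size=(30, 40))
        y = np.repeat([0.0, 1.0], 15)
        X += np.outer(y, rng.normal(size=40))  # y-correlated structure
        s = make_set(X, labels=["A"] * 15 + ["B"] * 15)
        step = pp.osc_fit(s, y, n_components=1)
        w = step.fitted_state["weights"][0]
        t = X @ w  # the removed training score vector
        yc = y - y.mean()
        cos = abs(t @ yc) / (np.linalg.norm(t) * np.linalg.norm(yc))
        assert cos < 1e-8

    def test_zero_components_is_identity(self, small_set, rng):
        y = rng.integers(0, 2, small_set.n_samples).astype(float)
        step = pp.osc_fit(small_set, y, n_components=0)
        out = pp.osc_apply(step, small_set)
        assert np.array_equal(out.absorbance, small_set.absorbance)

    def test_sequential_deflation_matches_two_components(self, rng):
        X = rng.normal(size=(25, 30))
        y = np.repeat([0.0, 1.0], [12, 13])
        s = make_set(X, labels=["A"] * 12 + ["B"] * 13)
        step2 = pp.osc_fit(s, y, n_components=2)
        once = pp.osc_apply(step2, s).absorbance

        step_a = pp.osc_fit(s, y, n_components=1)
        mid = pp.osc_apply(step_a, s)
        step_b = pp.osc_fit(mid, y, n_components=1)
        twice = pp.osc_apply(step_b, mid).absorbance
        assert np.allclose(once, twice, atol=1e-8)


class TestSavitzkyGolay:
    def test_polynomial_reproduction_including_edges(self):
        g = WavenumberGrid(np.linspace(9000, 5000, 60))
        v = g.values
        row = 1e-7 * v**2 - 1e-3 * v + 0.5
        s = make_set(row, grid=g, labels=["A"])
        out = pp.sg_smooth(s, window=11, polyorder=2)
        assert np.allclose(out.absorbance[0], row, atol=1e-10)

    def test_noise_variance_reduced(self, rng):
        s = make_set(rng.normal(size=(5, 200)))
        out = pp.sg_smooth(s, window=5, polyorder=2)
        assert out.absorbance.var() < s.absorbance.var()

    @pytest.mark.parametrize("window,polyorder", [(4, 2), (5, 5), (301, 2)])
    def test_bad_parameters(self, small_set, window, polyorder):
        with pytest.raises(ParameterError):
            pp.sg_smooth(small_set, window=window, polyorder=polyorder)


class TestDerivative:
    def setup_method(self):
        self.grid = WavenumberGrid(np.linspace(9000, 5000, 101))  # descending

    def test_first_derivative_of_linear_row(self):
        v = self.grid.values
        b = 2.5e-4
        s = make_set(0.3 + b * v, grid=self.grid, labels=["A"])
        d = pp.derivative(s, order=1, window=7).absorbance[0]
        assert np.allclose(d[3:-3], b, atol=1e-8)

    def test_second_derivative_of_quadratic_row(self):
        v = self.grid.values
        c = 3e-8
        s = make_set(0.1 - 1e-4 * v + c * v**2, grid=self.grid, labels=["A"])
        d = pp.derivative(s, order=2, window=9).absorbance[0]
        assert np.allclose(d[4:-4], 2 * c, atol=1e-6)

    def test_offset_invariance_exact(self, rng):
        a = rng.normal(size=(3, 101))
        s1 = make_set(a, grid=self.grid, labels=["A", "B", "A"])
        s2 = make_set(a + 7.5, grid=self.grid, labels=["A", "B", "A"])
        d1 = pp.derivative(s1, order=1).absorbance
        d2 = pp.derivative(s2, order=1).absorbance
        # S-G derivative kernels annihilate constants; only float rounding
        # in the convolution remains
        assert np.abs(d1 - d2).max() < 1e-12

    def test_descending_grid_sign(self):
        # absorbance increasing with wavenumber => positive d/dnu
        v = self.grid.values
        s = make_set(1e-4 * v, grid=self.grid, labels=["A"])
        d = pp.derivative(s, order=1).absorbance[0]
        assert np.all(d[5:-5] > 0)


class TestBaselineAndDetrend:
    def test_linear_row_zeroed(self):
        g = WavenumberGrid(np.linspace(9000, 5000, 20))
        s = make_set(3.0 + 1e-3 * g.values, grid=g, labels=["A"])
        out = pp.baseline_correct(s).absorbance[0]
        assert np.allclose(out, 0, atol=1e-9)

    def test_endpoints_exactly_zero(self, small_set):
        out = pp.baseline_correct(small_set).absorbance
        assert np.all(out[:, 0] == 0) and np.all(out[:, -1] == 0)

    def test_detrend_removes_quadratic(self):
        g = WavenumberGrid(np.linspace(9000, 5000, 50))
        v = g.values
        s = make_set(1e-7 * v**2 - 2e-3 * v + 4, grid=g, labels=["A"])
        out = pp.detrend(s, degree=2).absorbance[0]
        assert np.abs(out).max() < 1e-9

    def test_detrend_degree_zero_is_mean_removal(self, small_set):
        out = pp.detrend(small_set, degree=0).absorbance
        assert np.abs(out.mean(axis=1)).max() < 1e-9

    def test_residual_orthogonal_to_basis(self, rng):
        g = WavenumberGrid(np.linspace(9000, 5000, 40))
        s = make_set(rng.normal(size=(4, 40)), grid=g,
                     labels=["A", "B", "A", "B"])
        out = pp.detrend(s, degree=2).absorbance
        x = 2 * (g.values - g.values.min()) / np.ptp(g.values) - 1
        basis = np.polynomial.polynomial.polyvander(x, 2)
        assert np.abs(out @ basis).max() < 1e-9


class TestMeanCenterAndAreaNorm:
    def test_train_columns_centered(self, small_set):
        step = pp.mean_center_fit(small_set)
        out = pp.mean_center_apply(step, small_set).absorbance
        assert np.abs(out.mean(axis=0)).max() < 1e-12

    def test_single_spectrum_train_maps_to_zero(self, rng):
        s = make_set(rng.normal(size=(1, 20)), labels=["A"])
        step = pp.mean_center_fit(s)
        assert np.allclose(pp.mean_center_apply(step, s).absorbance, 0)

    def test_test_set_centered_with_train_means(self, rng):
        train = make_set(rng.normal(size=(5, 20)) + 1)
        test = make_set(rng.normal(size=(4, 20)) + 5, prefix="t")
        step = pp.mean_center_fit(train)
        out = pp.mean_center_apply(step, test).absorbance
        own = test.absorbance - test.absorbance.mean(axis=0)
        assert not np.allclose(out, own)  # no leakage of test statistics

    @pytest.mark.parametrize("row,expected", [
        ([1.0, 1.0, 1.0, 1.0], [0.25, 0.25, 0.25, 0.25]),
        ([2.0, -2.0], [0.5, -0.5]),
    ])
    def test_area_norm_examples(self, row, expected):
        out = pp.area_normalize(make_set([row], labels=["A"]))
        assert np.allclose(out.absorbance[0], expected)

    def test_area_norm_unit_absolute_sum(self, rng):
        out = pp.area_normalize(make_set(rng.normal(size=(6, 30))))
        assert np.abs(np.abs(out.absorbance).sum(axis=1) - 1).max() < 1e-12

    def test_all_zero_row_rejected(self):
        with pytest.raises(DegenerateSpectrumError):
            pp.area_normalize(make_set([[0.0, 0.0, 0.0]], labels=["A"]))


class TestPipeline:
    def test_single_step_equals_direct_call(self, small_set):
        _, out = pp.fit_pipeline(["snv"], small_set)
        assert np.array_equal(out.absorbance, pp.snv(small_set).absorbance)

    def test_order_sensitivity(self, small_set):
        _, a = pp.fit_pipeline(["snv", "detrend"], small_set)
        _, b = pp.fit_pipeline(["detrend", "snv"], small_set)
        assert not np.allclose(a.absorbance, b.absorbance)

    def test_replay_on_training_data_matches_fit(self, rng):
        train = make_set(rng.lognormal(size=(8, 40)))
        y = np.tile([0.0, 1.0], 4)
        pipe, fitted = pp.fit_pipeline(
            ["snv", ("osc", {"n_components": 1}), "mean_center"], train, y)
        replay = pp.apply_pipeline(pipe, train)
        assert np.array_equal(replay.absorbance, fitted.absorbance)

    def test_step_errors_carry_index(self):
        s = make_set([[1.0, 1.0, 1.0], [2.0, 3.0, 4.0]])
        with pytest.raises(PipelineStepError) as e:
            pp.fit_pipeline(["baseline", "snv"], s)  # baseline flattens row 0
        assert e.value.step_index == 1 and e.value.kind == "snv"

    def test_osc_requires_y(self, small_set):
        with pytest.raises(PipelineStepError):
            pp.fit_pipeline(["osc"], small_set, None)

    def test_permutation_equivariance(self, rng):
        train = make_set(rng.lognormal(size=(6, 30)))
        test = make_set(rng.lognormal(size=(5, 30)), prefix="t",
                        labels=["A"] * 5)
        pipe, _ = pp.fit_pipeline(["msc", "snv"], train)
        out = pp.apply_pipeline(pipe, test).absorbance
        perm = [3, 1, 4, 0, 2]
        out_perm = pp.apply_pipeline(pipe, test.subset(perm)).absorbance
        assert np.abs(out[perm] - out_perm).max() < 1e-12
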