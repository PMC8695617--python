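import numpy as np
import pandas as pd
import pytest

from connparc.errors import NormalizationError
from connparc.preprocess import (
    BoldSeries,
    NuisanceTable,
    bandpass,
    clean_series,
    detrend_poly,
    drop_initial_volumes,
    extract_mean_signal,
    grand_mean_normalize,
    regress_nuisance,
    smooth_gaussian,
)
from connparc.volio import BinaryMask, VolumeGrid


def make_series(values, tr=0.5, shape=None):
    """values: (n_voxels, T) -> BoldSeries on an (n,1,1) grid (or given shape)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if shape is None:
        shape = (values.shape[0], 1, 1)
    grid = VolumeGrid(shape)
    return BoldSeries(grid, tr, values.reshape(shape + (values.shape[1],)))


class TestDropVolumes:
    @pytest.mark.parametrize("total,n,expected", [(300, 10, 290), (11, 10, 1)])
    def test_counts(self, total, n, expected, rng):
        series = make_series(rng.standard_normal((1, total)))
        assert drop_initial_volumes(series, n).n_timepoints == expected

    def test_zero_is_identity_and_values_preserved(self, rng):
        series = make_series(rng.standard_normal((2, 20)))
        np.testing.assert_array_equal(drop_initial_volumes(series, 0).data, series.data)
        dropped = drop_initial_volumes(series, 5)
        np.testing.assert_array_equal(dropped.data, series.data[..., 5:])

    def test_dropping_everything_rejected(self):
        with pytest.raises(ValueError):
            drop_initial_volumes(make_series(np.zeros((1, 10))), 10)


class TestDetrend:
    def test_polynomials_in_span_vanish(self):
        t = np.arange(50, dtype=float)
        series = make_series(np.vstack([3 + 2 * t, t**2]))
        out = detrend_poly(series, order=2)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-8)

    def test_sine_plus_trend_matches_least_squares_oracle(self):
        T = 64
        t = np.arange(T, dtype=float)
        y = np.sin(2 * np.pi * t / T) + 0.5 * t
        out = detrend_poly(make_series(y[None]), order=2).data.ravel()
        # independent oracle: normal equations on the raw monomial basis
        basis = np.vstack([np.ones(T), t, t**2]).T
        beta = np.linalg.solve(basis.T @ basis, basis.T @ y)
        np.testing.assert_allclose(out, y - basis @ beta, atol=1e-8)

    def test_residual_orthogonal_to_basis(self, rng):
        series = make_series(rng.standard_normal((5, 40)))
        out = detrend_poly(series, order=2).matrix()
        t = np.linspace(-1, 1, 40)
        for row in out:
            for basis_vec in (np.ones(40), t, t**2):
                assert abs(row @ basis_vec) <= 1e-8 * np.linalg.norm(series.matrix())

    def test_idempotent(self, rng):
        series = make_series(rng.standard_normal((3, 30)))
        once = detrend_poly(series, 2)
        twice = detrend_poly(once, 2)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-10)

    def test_too_few_timepoints(self):
        with pytest.raises(ValueError):
            detrend_poly(make_series(np.zeros((1, 3))), order=2)


class TestNuisanceRegression:
    def test_series_equal_to_regressor_zeroed(self, rng):
        wm = rng.standard_normal(30)
        table = NuisanceTable(pd.DataFrame({"wm": wm}))
        out = regress_nuisance(make_series(wm[None]), table)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-10)

    def test_orthogonal_series_only_loses_its_mean(self):
        T = 40
        y = np.sin(2 * np.pi * np.arange(T) / T) + 5.0
        wm = np.cos(2 * np.pi * np.arange(T) / T)  # orthogonal to y - mean(y)
        out = regress_nuisance(make_series(y[None]), NuisanceTable(pd.DataFrame({"wm": wm})))
        np.testing.assert_allclose(out.data.ravel(), y - y.mean(), atol=1e-10)

    def test_duplicated_regressor_changes_nothing(self, rng):
        y = rng.standard_normal((3, 30))
        wm = rng.standard_normal(30)
        t1 = NuisanceTable(pd.DataFrame({"wm": wm}))
        t2 = NuisanceTable(pd.DataFrame({"wm": wm, "wm2": wm}))
        out1 = regress_nuisance(make_series(y), t1)
        with pytest.warns(UserWarning, match="rank-deficient"):
            out2 = regress_nuisance(make_series(y), t2)
        np.testing.assert_allclose(out1.data, out2.data, atol=1e-8)

    def test_length_mismatch_rejected(self, rng):
        table = NuisanceTable(pd.DataFrame({"wm": np.zeros(10)}))
        with pytest.raises(ValueError):
            regress_nuisance(make_series(rng.standard_normal((1, 20))), table)

    def test_detrend_then_regress_equals_joint_regression(self, rng):
        """Sequential cleaning must equal one joint model with poly columns."""
        T = 60
        y = rng.standard_normal((4, T))
        cols = pd.DataFrame({f"motion_{i}": rng.standard_normal(T) for i in range(3)})
        series = make_series(y)
        seq = clean_series(series, NuisanceTable(cols), drop_n=0, detrend_order=2,
                           band=None, sigma_mm=0, grand_mean=None).matrix()
        t = np.linspace(-1, 1, T)
        design = np.column_stack([np.ones(T), t, t**2, cols.to_numpy()])
        beta, *_ = np.linalg.lstsq(design, y.T, rcond=None)
        joint = y - (design @ beta).T
        np.testing.assert_allclose(seq, joint, atol=1e-8)


class TestGrandMeanNormalize:
    def test_scale_is_target_over_mean(self):
        series = make_series(np.full((2, 10), 500.0))
        out = grand_mean_normalize(series, 10000.0)
        np.testing.assert_allclose(out.data, 10000.0)

    def test_identity_when_already_at_target(self, rng):
        values = rng.uniform(9000, 11000, (3, 20))
        values *= 10000.0 / values.mean()
        series = make_series(values)
        np.testing.assert_allclose(grand_mean_normalize(series).data, series.data)

    def test_zero_mean_residual_rejected(self, rng):
        y = rng.standard_normal((2, 30))
        y -= y.mean()
        with pytest.raises(NormalizationError):
            grand_mean_normalize(make_series(y))


class TestBandpass:
    def test_constant_series_zeroed(self):
        series = make_series(np.full((1, 32), 7.0), tr=1.0)
        out = bandpass(series, 0.05, 0.2)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-10)

    def test_in_band_sinusoid_preserved(self):
        T, tr = 64, 1.0
        f = 8 / (T * tr)  # exact FFT bin
        t = np.arange(T)
        y = np.sin(2 * np.pi * f * t)
        out = bandpass(make_series(y[None], tr=tr), 0.05, 0.2).data.ravel()
        np.testing.assert_allclose(out, y, atol=1e-6)

    def test_out_of_band_sinusoid_suppressed(self):
        T, tr = 64, 1.0
        t = np.arange(T)
        y = np.sin(2 * np.pi * (20 / T) * t)  # 0.3125 Hz, above band
        out = bandpass(make_series(y[None], tr=tr), 0.05, 0.2).data.ravel()
        assert np.abs(out).max() < 1e-6 * np.abs(y).max()

    def test_spectrum_zero_outside_band(self, rng):
        tr = 0.5
        series = make_series(rng.standard_normal((2, 100)), tr=tr)
        out = bandpass(series, 0.1, 0.4)
        spec = np.fft.rfft(out.matrix(), axis=1)
        freqs = np.fft.rfftfreq(100, tr)
        outside = (freqs < 0.1) | (freqs > 0.4)
        assert np.abs(spec[:, outside]).max() < 1e-8 * np.linalg.norm(series.data)

    def test_idempotent(self, rng):
        series = make_series(rng.standard_normal((2, 50)), tr=0.5)
        once = bandpass(series, 0.1, 0.4)
        twice = bandpass(once, 0.1, 0.4)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-10)

    @pytest.mark.parametrize("low,high", [(-0.1, 0.2), (0.3, 0.2), (0.1, 2.0)])
    def test_invalid_band_rejected(self, low, high, rng):
        series = make_series(rng.standard_normal((1, 50)), tr=0.5)
        with pytest.raises(ValueError):
            bandpass(series, low, high)


class TestSmoothing:
    def test_sigma_zero_identity(self, rng):
        grid_data = rng.standard_normal((5, 5, 5, 4))
        series = BoldSeries(VolumeGrid((5, 5, 5)), 1.0, grid_data)
        out = smooth_gaussian(series, 0.0)
        np.testing.assert_array_equal(out.data, grid_data)

    def test_constant_volume_unchanged(self):
        series = BoldSeries(VolumeGrid((6, 6, 6)), 1.0, np.full((6, 6, 6, 2), 7.0))
        out = smooth_gaussian(series, 3.0)
        np.testing.assert_allclose(out.data, 7.0, atol=1e-6)

    def test_unit_impulse_mass_preserved(self):
        vol = np.zeros((15, 15, 15))
        vol[7, 7, 7] = 1.0
        _, out = smooth_gaussian((VolumeGrid((15, 15, 15)), vol), 2.0)
        assert abs(out.sum() - 1.0) < 1e-6
        assert out[7, 7, 7] < 1.0  # mass actually spread

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            smooth_gaussian((VolumeGrid((3, 3, 3)), np.zeros((3, 3, 3))), -1.0)


class TestMeanSignal:
    def test_mean_of_two_voxels(self):
        series = make_series(np.array([[1.0, 2.0], [3.0, 4.0]]))
        mask = BinaryMask(series.grid, np.array([True, True]).reshape(2, 1, 1))
        np.testing.assert_allclose(extract_mean_signal(series, mask), [2.0, 3.0])

    def test_single_voxel_mask(self):
        series = make_series(np.array([[1.0, 2.0], [3.0, 4.0]]))
        mask = BinaryMask(series.grid, np.array([False, True]).reshape(2, 1, 1))
        np.testing.assert_allclose(extract_mean_signal(series, mask), [3.0, 4.0])

    def test_grid_mismatch_and_empty_mask(self):
        from connparc.errors import GridMismatchError

        series = make_series(np.zeros((2, 5)))
        other = BinaryMask(VolumeGrid((3, 1, 1)), np.ones((3, 1, 1), dtype=bool))
        with pytest.raises(GridMismatchError):
            extract_mean_signal(series, other)
        empty = BinaryMask(series.grid, np.zeros((2, 1, 1), dtype=bool))
        with pytest.raises(ValueError):
            extract_mean_signal(series, empty)
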