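"""SNV/MSC/Savitzky-Golay correctness against least-squares oracles."""

import numpy as np
import pytest

from nirquant import msc, msc_reference, sg_filter, snv
from nirquant.errors import ConfigError, DegenerateSpectrumError, DimensionError
from nirquant.preprocess import PreprocConfig, apply_method
from nirquant.sampling import ks_split
from .conftest import make_set

rng = np.random.default_rng(42)


class TestSNV:
    def test_simple_row(self):
        out = snv(make_set([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.absorbance[0], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_rows_have_zero_mean_unit_sd(self):
        out = snv(make_set(rng.random((20, 60))))
        np.testing.assert_allclose(out.absorbance.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out.absorbance.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_constant_row_rejected(self):
        with pytest.raises(DegenerateSpectrumError):
            snv(make_set(np.full((1, 10), 3.3)))

    def test_idempotent(self):
        data = make_set(rng.random((8, 40)))
        once = snv(data)
        np.testing.assert_allclose(snv(once).absorbance, once.absorbance,
                                   atol=1e-10)


class TestMSC:
    def test_reference_row_unchanged(self):
        A = rng.random((4, 30))
        ref = A.mean(axis=0)
        data = make_set(np.vstack([ref, A]))
        out = msc(data, ref)
        np.testing.assert_allclose(out.absorbance[0], ref, atol=1e-12)

    def test_affine_distortion_inverted(self):
        ref = rng.random(50)
        data = make_set((2.0 * ref + 5.0)[None, :])
        out = msc(data, ref)
        np.testing.assert_allclose(out.absorbance[0], ref, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        A = rng.random((50, 200))
        ref = rng.random(200)
        out = msc(make_set(A), ref)
        F = np.column_stack([np.ones(200), ref])
        for i in range(50):
            a, b = np.linalg.solve(F.T @ F, F.T @ A[i])
            np.testing.assert_allclose(out.absorbance[i], (A[i] - a) / b,
                                       atol=1e-10)

    def test_mean_reference_preserves_mean_spectrum(self):
        # rows that are exact affine distortions of a common shape: MSC with
        # the set's own mean as reference maps every row onto that mean
        base = rng.random(40) + np.linspace(0, 1, 40)
        a = rng.normal(0, 0.2, 12)
        b = rng.uniform(0.6, 1.6, 12)
        data = make_set(a[:, None] + b[:, None] * base[None, :])
        out = msc(data, "mean")
        np.testing.assert_allclose(out.absorbance.mean(axis=0),
                                   data.absorbance.mean(axis=0), atol=1e-10)
        # and every corrected row collapses onto the reference itself
        np.testing.assert_allclose(
            out.absorbance, np.tile(data.absorbance.mean(axis=0), (12, 1)),
            atol=1e-10)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            msc(make_set(rng.random((2, 30))), np.ones(10))


class TestSavitzkyGolay:
    def test_quadratic_signal_unchanged_by_smoothing(self):
        nu = np.linspace(10_000, 4_000, 200)
        y = 1e-7 * nu**2 - 1e-3 * nu + 0.4
        out = sg_filter(make_set(y[None, :], wavenumbers=nu), 11, 2, 0)
        np.testing.assert_allclose(out.absorbance[0], y, atol=1e-9)

    def test_interior_matches_windowed_polyfit_oracle(self):
        A = rng.random((50, 200))
        nu = np.linspace(10_000, 4_000, 200)
        window, order = 11, 2
        out = sg_filter(make_set(A, wavenumbers=nu), window, order, 0)
        half = window // 2
        x = np.arange(window) - half
        for i in range(0, 50, 7):
            for j in range(half, 200 - half, 31):
                coef = np.polynomial.polynomial.polyfit(
                    x, A[i, j - half:j + half + 1], order)
                assert abs(out.absorbance[i, j] - coef[0]) < 1e-10

    def test_second_derivative_of_quadratic_is_constant(self):
        nu = np.linspace(10_000, 4_000, 150)
        a, b, c = 3e-8, -2e-4, 1.1
        y = a * nu**2 + b * nu + c
        out = sg_filter(make_set(y[None, :], wavenumbers=nu), 11, 2, 2)
        np.testing.assert_allclose(out.absorbance[0], 2 * a, rtol=1e-6)

    def test_linearity(self):
        X = rng.random((5, 80))
        Y = rng.random((5, 80))
        lhs = sg_filter(make_set(2.0 * X + 3.0 * Y), 11, 2, 0).absorbance
        rhs = (2.0 * sg_filter(make_set(X), 11, 2, 0).absorbance
               + 3.0 * sg_filter(make_set(Y), 11, 2, 0).absorbance)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_even_window_rejected(self):
        with pytest.raises(ConfigError):
            sg_filter(make_set(rng.random((2, 30))), window=10)

    def test_window_exceeding_spectrum_rejected(self):
        with pytest.raises(ConfigError):
            sg_filter(make_set(rng.random((2, 9))), window=11)


class TestScatterRemoval:
    def test_snv_and_msc_tighten_replicate_clusters(self, small_noisy_set):
        """Scatter correction shrinks distances between same-recipe replicates."""
        def mean_replicate_spread(data):
            spread = []
            for _, grp in data.targets.groupby(["fA", "fB"]):
                rows = data.absorbance[grp.index.to_numpy()]
                centered = rows - rows.mean(axis=0)
                spread.append(np.linalg.norm(centered, axis=1).mean())
            return float(np.mean(spread))

        # SNV changes the overall scale, so compare after renormalizing by
        # the mean spectrum norm of each representation
        def normalized_spread(data):
            scale = np.linalg.norm(data.absorbance, axis=1).mean()
            return mean_replicate_spread(data) / scale

        assert normalized_spread(snv(small_noisy_set)) < normalized_spread(small_noisy_set)
        assert normalized_spread(msc(small_noisy_set, "mean")) < normalized_spread(small_noisy_set)


class TestApplyMethod:
    def test_msc_state_fitted_on_calibration_only(self, small_noisy_set):
        split = ks_split(small_noisy_set, 30)
        cal = small_noisy_set.take(split.train_indices)
        pred = small_noisy_set.take(split.test_indices)
        cal_pp, pred_pp = apply_method(PreprocConfig(method="msc"), cal, pred)
        ref = msc_reference(cal)
        np.testing.assert_allclose(pred_pp.absorbance,
                                   msc(pred, ref).absorbance, atol=1e-12)

    def test_raw_is_identity(self, small_noisy_set):
        out, _ = apply_method(PreprocConfig(method="raw"), small_noisy_set)
        assert out is small_noisy_set
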