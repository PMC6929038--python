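"""Pretreatment correctness: identities, oracles and shape preservation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spectrograin.dataset import SpectrumSet
from spectrograin.exceptions import DegenerateSpectrumError, InvalidArgumentError
from spectrograin.preprocess import (
    FFTLowPass,
    FirstDerivative,
    HilbertFilter,
    MultiplicativeScatterCorrection,
    SavitzkyGolay,
    StandardNormalVariate,
    first_derivative,
    make_pretreatment,
    msc_apply,
    msc_fit,
    sg_smooth,
    snv,
)
from spectrograin.synthetic import SyntheticConfig, generate_dataset


def _spectrum_set(matrix, wavelengths=None):
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    wl = (
        np.arange(matrix.shape[1], dtype=float) + 400
        if wavelengths is None
        else np.asarray(wavelengths, dtype=float)
    )
    return SpectrumSet(
        reflectance=matrix,
        wavelengths=wl,
        labels=np.array([f"c{i}" for i in range(matrix.shape[0])]),
    )


class TestSavitzkyGolay:
    def test_constant_unchanged(self):
        X = np.full((2, 20), 3.0)
        np.testing.assert_allclose(SavitzkyGolay().fit_transform(X), X, atol=1e-12)

    def test_quadratic_reproduced_exactly(self):
        k = np.arange(30, dtype=float)
        X = (0.3 * k**2 - 2 * k + 5)[None, :]
        np.testing.assert_allclose(
            SavitzkyGolay(window_points=9, poly_order=2).fit_transform(X),
            X,
            atol=1e-10,
        )

    def test_matches_brute_force_windowed_refit(self, rng):
        """Window-5 order-2 smoothing equals an explicit per-window
        least-squares polynomial refit (including truncated edge windows)."""
        X = rng.normal(size=(3, 20))
        out = SavitzkyGolay(window_points=5, poly_order=2).fit_transform(X)
        expected = np.empty_like(X)
        for i in range(20):
            lo, hi = max(0, i - 2), min(19, i + 2)
            idx = np.arange(lo, hi + 1)
            for s in range(3):
                coeffs = np.polyfit(idx - i, X[s, idx], 2)
                expected[s, i] = np.polyval(coeffs, 0.0)
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_even_window_rejected(self):
        with pytest.raises(InvalidArgumentError, match="odd"):
            SavitzkyGolay(window_points=8).fit(np.ones((2, 20)))

    def test_window_not_larger_than_order(self):
        with pytest.raises(InvalidArgumentError):
            SavitzkyGolay(window_points=3, poly_order=3).fit(np.ones((2, 20)))


class TestFirstDerivative:
    def test_constant_is_zero(self):
        out = FirstDerivative().fit_transform(np.full((2, 10), 4.0))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_linear_spectrum_gives_slope(self):
        wl = np.linspace(400, 900, 25)
        X = (0.002 * wl + 0.1)[None, :]
        out = FirstDerivative(wavelengths=wl).fit_transform(X)
        np.testing.assert_allclose(out, 0.002, atol=1e-12)

    def test_central_difference_by_hand(self):
        wl = np.array([100.0, 110.0, 120.0])
        out = FirstDerivative(wavelengths=wl).fit_transform([[1.0, 2.0, 4.0]])
        assert out[0, 1] == pytest.approx((4 - 1) / (120 - 100))  # 0.15
        assert out[0, 0] == pytest.approx((2 - 1) / 10)
        assert out[0, 2] == pytest.approx((4 - 2) / 10)

    def test_non_ascending_wavelengths_rejected(self):
        with pytest.raises(InvalidArgumentError):
            FirstDerivative(wavelengths=[3.0, 2.0, 1.0]).fit(np.ones((1, 3)))


class TestSNV:
    def test_hand_computed(self):
        out = StandardNormalVariate().fit_transform([[1.0, 2.0, 3.0]])
        np.testing.assert_allclose(out, [[-1.0, 0.0, 1.0]])

    def test_rows_mean_zero_sd_one(self, rng):
        out = StandardNormalVariate().fit_transform(rng.normal(size=(10, 17)))
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-10)

    def test_idempotent_on_standardized_rows(self, rng):
        first = StandardNormalVariate().fit_transform(rng.normal(size=(4, 12)))
        second = StandardNormalVariate().fit_transform(first)
        np.testing.assert_allclose(second, first, atol=1e-10)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        a=st.floats(min_value=0.1, max_value=10),
        b=st.floats(min_value=-5, max_value=5),
    )
    def test_affine_invariance(self, a, b):
        x = np.linspace(0.0, 1.0, 16)[None, :] ** 2
        t = StandardNormalVariate()
        np.testing.assert_allclose(
            t.fit_transform(a * x + b), t.fit_transform(x), atol=1e-8
        )

    def test_constant_spectrum_names_sample(self):
        sset = _spectrum_set(np.vstack([np.arange(5.0), np.full(5, 2.0)]))
        with pytest.raises(DegenerateSpectrumError, match="s00001"):
            snv(sset)


class TestMSC:
    def test_reference_spectrum_passes_through(self, rng):
        X = rng.uniform(0.1, 0.9, size=(6, 12))
        t = MultiplicativeScatterCorrection().fit(X)
        out = t.transform(t.reference_[None, :])
        np.testing.assert_allclose(out[0], t.reference_, atol=1e-10)
        assert t.alpha_[0] == pytest.approx(1.0)
        assert t.beta_[0] == pytest.approx(0.0, abs=1e-10)

    def test_exact_affine_scatter_inverted(self, rng):
        X = rng.uniform(0.1, 0.9, size=(6, 12))
        t = MultiplicativeScatterCorrection().fit(X)
        ref = t.reference_
        out = t.transform((2.0 * ref + 3.0)[None, :])
        np.testing.assert_allclose(out[0], ref, atol=1e-10)
        assert t.alpha_[0] == pytest.approx(2.0)
        assert t.beta_[0] == pytest.approx(3.0)

    def test_recovers_template_from_simulated_scatter(self, rng):
        """Rows generated as a_i * template + b_i + tiny noise are corrected
        back to within the noise of the template."""
        template = 0.3 + 0.2 * np.sin(np.linspace(0, 3, 40))
        gains = rng.uniform(0.7, 1.3, size=30)
        offsets = rng.uniform(-0.1, 0.1, size=30)
        noise = rng.normal(0, 1e-4, size=(30, 40))
        X = gains[:, None] * template[None, :] + offsets[:, None] + noise
        out = MultiplicativeScatterCorrection().fit_transform(X)
        # the fitted reference is an affine image of the template, so compare
        # after removing one global affine fit
        ref = out.mean(axis=0)
        A = np.vstack([template, np.ones(40)]).T
        coef, *_ = np.linalg.lstsq(A, ref, rcond=None)
        target = np.broadcast_to(coef[0] * template + coef[1], out.shape)
        np.testing.assert_allclose(out, target, atol=5e-3)

    def test_degenerate_reference_rejected(self):
        with pytest.raises(DegenerateSpectrumError, match="reference"):
            MultiplicativeScatterCorrection().fit(np.full((3, 8), 0.5))

    def test_model_round_trip_names_functions(self):
        sset = generate_dataset(
            SyntheticConfig(n_classes=2, samples_per_class=3, n_bands=16, rng_seed=0)
        )
        model = msc_fit(sset)
        out = msc_apply(sset, model)
        assert out.reflectance.shape == sset.reflectance.shape
        assert model.alpha.shape == (6,)
        assert model.beta.shape == (6,)


class TestFFTLowPass:
    def test_constant_unchanged(self):
        X = np.full((2, 32), 1.7)
        np.testing.assert_allclose(FFTLowPass().fit_transform(X), X, atol=1e-10)

    def test_high_frequency_sinusoid_zeroed(self):
        k = np.arange(40)
        X = np.cos(2 * np.pi * 0.40 * k)[None, :]  # exact DFT bin 16/40
        out = FFTLowPass(cutoff=0.125).fit_transform(X)
        assert np.abs(out).max() < 1e-10

    def test_low_frequency_sinusoid_kept(self):
        k = np.arange(32)
        X = np.cos(2 * np.pi * 0.0625 * k)[None, :]  # bin 2/32, below cutoff
        out = FFTLowPass(cutoff=0.125).fit_transform(X)
        np.testing.assert_allclose(out, X, atol=1e-10)

    def test_matches_direct_dft(self, rng):
        X = rng.normal(size=(3, 24))
        out = FFTLowPass(cutoff=0.125).fit_transform(X)
        spec = np.fft.fft(X, axis=1)
        freqs = np.abs(np.fft.fftfreq(24))
        spec[:, freqs > 0.125 + 1e-12] = 0
        np.testing.assert_allclose(out, np.fft.ifft(spec, axis=1).real, atol=1e-10)

    def test_idempotent_projection(self, rng):
        t = FFTLowPass(cutoff=0.125)
        once = t.fit_transform(rng.normal(size=(4, 33)))
        np.testing.assert_allclose(t.fit_transform(once), once, atol=1e-10)

    @pytest.mark.parametrize("cutoff", [0.0, -0.1, 0.6])
    def test_cutoff_range(self, cutoff):
        with pytest.raises(InvalidArgumentError):
            FFTLowPass(cutoff=cutoff).fit(np.ones((1, 8)))


class TestHilbert:
    def test_cosine_becomes_sine(self):
        k = np.arange(64)
        f = 4 / 64
        out = HilbertFilter().fit_transform(np.cos(2 * np.pi * f * k)[None, :])
        np.testing.assert_allclose(out[0], np.sin(2 * np.pi * f * k), atol=1e-10)

    def test_constant_is_zero(self):
        out = HilbertFilter().fit_transform(np.full((2, 16), 5.0))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_double_application_negates(self, rng):
        # odd band count: no Nyquist bin, so H(H(x)) = -x holds exactly for
        # zero-mean spectra
        X = rng.normal(size=(3, 51))
        X -= X.mean(axis=1, keepdims=True)
        t = HilbertFilter()
        np.testing.assert_allclose(t.fit_transform(t.fit_transform(X)), -X, atol=1e-8)


class TestShapeAndWavelengthPreservation:
    @pytest.mark.parametrize("name", ["sg", "fd", "snv", "fft", "ht", "msc"])
    def test_all_pretreatments_preserve_shape(self, small_set, name):
        t = make_pretreatment(name, wavelengths=small_set.wavelengths)
        out = t.fit_transform(small_set.reflectance)
        assert out.shape == small_set.reflectance.shape

    def test_set_level_wrappers_keep_wavelengths(self, small_set):
        for fn in (sg_smooth, first_derivative, snv):
            out = fn(small_set)
            np.testing.assert_array_equal(out.wavelengths, small_set.wavelengths)
            assert np.array_equal(out.labels, small_set.labels)

    def test_sg_does_not_bias_derivative_of_cubic_in_interior(self):
        """On a cubic-in-wavelength spectrum, order-2 smoothing leaves the
        interior derivative untouched: an odd polynomial component projects to
        zero at the centre of a symmetric window, so FD(SG(x)) = FD(x) exactly
        wherever the window does not truncate."""
        wl = np.linspace(400, 900, 60)
        X = (1e-8 * (wl - 650) ** 3 + 0.3)[None, :]
        sset = _spectrum_set(X, wl)
        deriv_smoothed = first_derivative(sg_smooth(sset, window_points=9, poly_order=2))
        deriv_raw = first_derivative(sset)
        interior = slice(5, -5)
        np.testing.assert_allclose(
            deriv_smoothed.reflectance[0, interior],
            deriv_raw.reflectance[0, interior],
            atol=1e-12,
        )
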