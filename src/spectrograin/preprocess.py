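"""Six spectral pretreatments behind one transformer contract.

Each pretreatment maps an ``(n_samples, n_bands)`` reflectance matrix to a
matrix of identical shape (and, at the :class:`~spectrograin.dataset.SpectrumSet`
level, preserves the wavelength grid):

* ``sg``  — Savitzky-Golay smoothing (moving-window least-squares polynomial).
* ``fd``  — first derivative with respect to wavelength (central differences).
* ``snv`` — standard normal variate: per-spectrum centre and scale to unit sd.
* ``fft`` — brick-wall low-pass filter in the discrete Fourier domain.
* ``ht``  — Hilbert transform (±90° phase shift, amplitudes unchanged).
* ``msc`` — multiplicative scatter correction against a mean reference
  spectrum, the only stateful pretreatment (the reference is fitted on
  training data).

The scikit-learn transformer classes are the primary API; the module-level
functions are thin SpectrumSet-in / SpectrumSet-out wrappers over them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .dataset import SpectrumSet
from .exceptions import DegenerateSpectrumError, InvalidArgumentError

__all__ = [
    "SavitzkyGolay",
    "FirstDerivative",
    "StandardNormalVariate",
    "MultiplicativeScatterCorrection",
    "FFTLowPass",
    "HilbertFilter",
    "MSCModel",
    "sg_smooth",
    "first_derivative",
    "snv",
    "msc_fit",
    "msc_apply",
    "fft_lowpass",
    "hilbert_filter",
    "make_pretreatment",
    "PRETREATMENTS",
]


def _check_X(X) -> np.ndarray:
    return check_array(X, dtype=float, ensure_all_finite=True)


class SavitzkyGolay(TransformerMixin, BaseEstimator):
    """Savitzky-Golay smoothing with truncated windows at the edges.

    Each band is replaced by the centre value of a least-squares polynomial of
    ``poly_order`` fitted over a moving window of ``window_points`` bands. At
    the spectrum edges the window is truncated (asymmetric, same order) so the
    output keeps the input shape.

    Parameters
    ----------
    window_points : int, default=9
        Window length in bands; must be odd and larger than ``poly_order``.
        (An even window has no centre band and is rejected.)
    poly_order : int, default=2
        Order of the fitted polynomial.
    """

    def __init__(self, window_points: int = 9, poly_order: int = 2):
        self.window_points = window_points
        self.poly_order = poly_order

    def _validate(self, n_bands: int) -> None:
        w, o = self.window_points, self.poly_order
        if w % 2 == 0:
            raise InvalidArgumentError(
                f"window_points must be odd (a centred window needs a middle "
                f"band); got {w}"
            )
        if w <= o:
            raise InvalidArgumentError(
                f"window_points ({w}) must exceed poly_order ({o})"
            )
        if n_bands < w:
            raise InvalidArgumentError(
                f"need at least window_points={w} bands, got {n_bands}"
            )

    @staticmethod
    def _weight_matrix(n_bands: int, window: int, order: int) -> np.ndarray:
        """(n_bands, n_bands) linear operator: smoothed = X @ W.T.

        Row i holds the least-squares weights that evaluate, at band i, the
        polynomial fitted over the (possibly truncated) window around i.
        """
        half = window // 2
        W = np.zeros((n_bands, n_bands))
        for i in range(n_bands):
            lo = max(0, i - half)
            hi = min(n_bands - 1, i + half)
            offs = np.arange(lo, hi + 1) - i
            V = np.vander(offs, N=order + 1, increasing=True)
            # value at offset 0 is coefficient 0 of the LS fit
            W[i, lo : hi + 1] = np.linalg.pinv(V)[0]
        return W

    def fit(self, X, y=None):
        X = _check_X(X)
        self._validate(X.shape[1])
        self.n_features_in_ = X.shape[1]
        self.weights_ = self._weight_matrix(
            X.shape[1], self.window_points, self.poly_order
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "weights_")
        X = _check_X(X)
        if X.shape[1] != self.n_features_in_:
            raise InvalidArgumentError(
                f"expected {self.n_features_in_} bands, got {X.shape[1]}"
            )
        return X @ self.weights_.T

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X).transform(X)


class FirstDerivative(TransformerMixin, BaseEstimator):
    """First derivative of reflectance with respect to wavelength.

    Interior bands use the symmetric difference
    ``(R[i+1] - R[i-1]) / (wl[i+1] - wl[i-1])``; the endpoints use one-sided
    two-point differences so the band count is preserved.

    Parameters
    ----------
    wavelengths : array-like of shape (n_bands,), optional
        Band centres in nm, strictly ascending. Defaults to unit band spacing.
    """

    def __init__(self, wavelengths=None):
        self.wavelengths = wavelengths

    def fit(self, X, y=None):
        X = _check_X(X)
        p = X.shape[1]
        if p < 3:
            raise InvalidArgumentError("first derivative needs at least 3 bands")
        if self.wavelengths is None:
            wl = np.arange(p, dtype=float)
        else:
            wl = np.asarray(self.wavelengths, dtype=float)
            if wl.shape != (p,):
                raise InvalidArgumentError(
                    f"wavelengths length {wl.size} != band count {p}"
                )
            if not np.all(np.diff(wl) > 0):
                raise InvalidArgumentError("wavelengths must be strictly ascending")
        self.wavelengths_ = wl
        self.n_features_in_ = p
        return self

    def transform(self, X):
        check_is_fitted(self, "wavelengths_")
        X = _check_X(X)
        wl = self.wavelengths_
        if X.shape[1] != wl.size:
            raise InvalidArgumentError(
                f"expected {wl.size} bands, got {X.shape[1]}"
            )
        out = np.empty_like(X)
        out[:, 1:-1] = (X[:, 2:] - X[:, :-2]) / (wl[2:] - wl[:-2])
        out[:, 0] = (X[:, 1] - X[:, 0]) / (wl[1] - wl[0])
        out[:, -1] = (X[:, -1] - X[:, -2]) / (wl[-1] - wl[-2])
        return out

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X).transform(X)


class StandardNormalVariate(TransformerMixin, BaseEstimator):
    """Per-spectrum centring and scaling to unit standard deviation.

    Each row has its own mean subtracted and is divided by its own standard
    deviation with an ``n - 1`` denominator, removing per-sample additive and
    multiplicative scatter. Output rows have mean 0 and sd 1.
    """

    def fit(self, X, y=None):
        X = _check_X(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = _check_X(X)
        mean = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        degenerate = np.flatnonzero(sd.ravel() == 0)
        if degenerate.size:
            raise DegenerateSpectrumError(
                f"constant spectrum (zero variance) at row(s) "
                f"{degenerate[:5].tolist()}; SNV is undefined"
            )
        return (X - mean) / sd

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X).transform(X)


@dataclass
class MSCModel:
    """Fitted multiplicative-scatter-correction state.

    ``reference`` is the mean training spectrum; ``alpha``/``beta`` hold the
    per-sample slope and intercept of the most recent application.
    """

    reference: np.ndarray
    alpha: Optional[np.ndarray] = None
    beta: Optional[np.ndarray] = None


class MultiplicativeScatterCorrection(TransformerMixin, BaseEstimator):
    """MSC against the mean training spectrum.

    ``fit`` stores the columnwise mean of the training matrix as the reference
    spectrum; ``transform`` regresses each spectrum x on the reference by
    ordinary least squares (``x = alpha * ref + beta``) and returns
    ``(x - beta) / alpha``, exactly inverting per-sample affine scatter.
    """

    def fit(self, X, y=None):
        X = _check_X(X)
        if X.shape[0] < 2:
            raise InvalidArgumentError("MSC needs at least 2 training spectra")
        ref = X.mean(axis=0)
        if np.ptp(ref) == 0:
            raise DegenerateSpectrumError(
                "mean training spectrum is constant; MSC reference is degenerate"
            )
        self.reference_ = ref
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_")
        X = _check_X(X)
        ref = self.reference_
        if X.shape[1] != ref.size:
            raise InvalidArgumentError(
                f"expected {ref.size} bands, got {X.shape[1]}"
            )
        ref_c = ref - ref.mean()
        denom = float(ref_c @ ref_c)
        alpha = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
        beta = X.mean(axis=1) - alpha * ref.mean()
        zero = np.flatnonzero(alpha == 0)
        if zero.size:
            raise DegenerateSpectrumError(
                f"fitted slope alpha = 0 at row(s) {zero[:5].tolist()}; "
                "scatter correction is undefined"
            )
        self.alpha_ = alpha
        self.beta_ = beta
        return (X - beta[:, None]) / alpha[:, None]

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X).transform(X)

    @property
    def model_(self) -> MSCModel:
        check_is_fitted(self, "reference_")
        return MSCModel(
            reference=self.reference_,
            alpha=getattr(self, "alpha_", None),
            beta=getattr(self, "beta_", None),
        )


class FFTLowPass(TransformerMixin, BaseEstimator):
    """Brick-wall low-pass filter in the discrete Fourier domain.

    Per spectrum: real FFT over bands, bins with normalized frequency (cycles
    per band interval; Nyquist = 0.5) strictly above ``cutoff`` are zeroed,
    inverse transform. Zeroing is a projection, so the filter is idempotent.

    Parameters
    ----------
    cutoff : float, default=0.125
        Normalized cutoff frequency, ``0 < cutoff <= 0.5``.
    """

    def __init__(self, cutoff: float = 0.125):
        self.cutoff = cutoff

    def fit(self, X, y=None):
        if not 0 < self.cutoff <= 0.5:
            raise InvalidArgumentError(
                f"cutoff must be in (0, 0.5], got {self.cutoff}"
            )
        X = _check_X(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        if not 0 < self.cutoff <= 0.5:
            raise InvalidArgumentError(
                f"cutoff must be in (0, 0.5], got {self.cutoff}"
            )
        X = _check_X(X)
        p = X.shape[1]
        freqs = np.fft.rfftfreq(p)  # cycles per band interval
        spec = np.fft.rfft(X, axis=1)
        spec[:, freqs > self.cutoff + 1e-12] = 0.0
        return np.fft.irfft(spec, n=p, axis=1)

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X).transform(X)


class HilbertFilter(TransformerMixin, BaseEstimator):
    """Hilbert transform of each mean-removed spectrum.

    Positive-frequency components are phase-shifted by -90°, negative by +90°,
    amplitudes untouched; the output is the transform itself (the imaginary
    part of the analytic signal), not an envelope. The per-spectrum mean is
    removed first because the DC bin has no defined ±90° shift. Applying the
    operator twice to a zero-mean spectrum negates it.
    """

    def fit(self, X, y=None):
        X = _check_X(X)
        if X.shape[1] < 2:
            raise InvalidArgumentError("Hilbert transform needs at least 2 bands")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = _check_X(X)
        centered = X - X.mean(axis=1, keepdims=True)
        return np.imag(signal.hilbert(centered, axis=1))

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X).transform(X)


# ---------------------------------------------------------------------------
# SpectrumSet-level wrappers
# ---------------------------------------------------------------------------

def _name_degenerate(sset: SpectrumSet, exc: DegenerateSpectrumError):
    """Re-raise a row-indexed degeneracy error with sample ids attached."""
    import re

    rows = re.findall(r"\d+", str(exc))
    ids = [str(sset.sample_ids[int(r)]) for r in rows if int(r) < sset.n_samples]
    raise DegenerateSpectrumError(f"{exc} (sample ids: {ids})") from exc


def sg_smooth(sset: SpectrumSet, window_points: int = 9, poly_order: int = 2) -> SpectrumSet:
    """Savitzky-Golay smoothing of every spectrum; shape preserved."""
    t = SavitzkyGolay(window_points=window_points, poly_order=poly_order)
    return sset.with_reflectance(t.fit_transform(sset.reflectance))


def first_derivative(sset: SpectrumSet) -> SpectrumSet:
    """First derivative with respect to wavelength; shape preserved."""
    t = FirstDerivative(wavelengths=sset.wavelengths)
    return sset.with_reflectance(t.fit_transform(sset.reflectance))


def snv(sset: SpectrumSet) -> SpectrumSet:
    """Standard normal variate of every spectrum; rows become mean-0, sd-1."""
    try:
        out = StandardNormalVariate().fit_transform(sset.reflectance)
    except DegenerateSpectrumError as exc:
        _name_degenerate(sset, exc)
    return sset.with_reflectance(out)


def msc_fit(train: SpectrumSet) -> MSCModel:
    """Fit the MSC reference (mean spectrum) on a training set."""
    t = MultiplicativeScatterCorrection().fit(train.reflectance)
    return t.model_


def msc_apply(sset: SpectrumSet, model: MSCModel) -> SpectrumSet:
    """Apply a fitted MSC model; fills ``model.alpha`` / ``model.beta``."""
    t = MultiplicativeScatterCorrection()
    t.reference_ = np.asarray(model.reference, dtype=float)
    t.n_features_in_ = t.reference_.size
    try:
        out = t.transform(sset.reflectance)
    except DegenerateSpectrumError as exc:
        _name_degenerate(sset, exc)
    model.alpha = t.alpha_
    model.beta = t.beta_
    return sset.with_reflectance(out)


def fft_lowpass(sset: SpectrumSet, cutoff: float = 0.125) -> SpectrumSet:
    """Low-pass FFT filtering of every spectrum; shape preserved."""
    return sset.with_reflectance(
        FFTLowPass(cutoff=cutoff).fit_transform(sset.reflectance)
    )


def hilbert_filter(sset: SpectrumSet) -> SpectrumSet:
    """Hilbert transform of every mean-removed spectrum; shape preserved."""
    return sset.with_reflectance(HilbertFilter().fit_transform(sset.reflectance))


#: Factory registry: short name -> zero-argument transformer constructor.
PRETREATMENTS = {
    "sg": SavitzkyGolay,
    "fd": FirstDerivative,
    "snv": StandardNormalVariate,
    "fft": FFTLowPass,
    "ht": HilbertFilter,
    "msc": MultiplicativeScatterCorrection,
}


def make_pretreatment(name: str, wavelengths: np.ndarray | None = None):
    """Instantiate a pretreatment transformer by its short name."""
    if name not in PRETREATMENTS:
        raise InvalidArgumentError(
            f"unknown pretreatment {name!r}; choose from {sorted(PRETREATMENTS)}"
        )
    if name == "fd":
        return FirstDerivative(wavelengths=wavelengths)
    return PRETREATMENTS[name]()
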