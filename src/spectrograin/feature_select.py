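"""Wavelength selection and feature extraction: CARS, SPA, and Kaiser PCA.

All three methods reduce a sample x band reflectance matrix to the features a
classifier sees:

* **CARS** (competitive adaptive reweighted sampling) alternates an enforced
  exponentially decreasing retention schedule with reweighted sampling by
  partial-least-squares coefficient magnitude, and keeps the band subset whose
  cross-validated indicator-regression error (RMSECV) is smallest.
* **SPA** (successive projections algorithm) grows chains of bands that
  maximise the orthogonal-projection norm against the bands already chosen
  (minimal collinearity) and picks the shortest prefix whose cross-validated
  RMSE sits on the global plateau.
* **Kaiser PCA** standardises bands, eigendecomposes the correlation matrix
  and retains components with eigenvalue > 1.

The class response for CARS/SPA is a one-hot indicator matrix (PLS-DA /
MLR-DA), the standard chemometric coding for running regression-style RMSECV
on a classification task.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import solve_triangular
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .dataset import SpectrumSet
from .exceptions import InvalidArgumentError, StratificationError

__all__ = [
    "SelectionResult",
    "PCModel",
    "pls_rmsecv",
    "CARSSelector",
    "SPASelector",
    "KaiserPCA",
    "cars_select",
    "spa_select",
    "pca_fit",
    "pca_apply",
    "make_selector",
    "SELECTORS",
]

MAX_PLS_COMPONENTS = 10


@dataclass
class SelectionResult:
    """Outcome of a wavelength-selection run.

    ``selected`` holds ascending 0-based band indices into the wavelength
    grid; ``rmsecv_trace`` is the RMSECV per sampling run (CARS) or the CV
    RMSE per subset size of the winning chain (SPA); ``retained_counts`` is
    CARS-only; ``best_index`` points at the first minimum of the trace.
    """

    selected: np.ndarray
    rmsecv_trace: np.ndarray
    best_index: int
    retained_counts: Optional[np.ndarray] = None
    n_components: Optional[int] = None

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=int)
        self.rmsecv_trace = np.asarray(self.rmsecv_trace, dtype=float)
        if self.selected.size == 0:
            raise InvalidArgumentError("selection must retain at least one band")
        if np.unique(self.selected).size != self.selected.size:
            raise InvalidArgumentError("selected band indices must be unique")
        if np.any(np.diff(self.selected) <= 0):
            raise InvalidArgumentError("selected band indices must be ascending")


@dataclass
class PCModel:
    """Fitted principal-component model on the band correlation matrix."""

    loadings: np.ndarray  # (bands_kept, n_retained), orthonormal columns
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    n_retained: int
    column_means: np.ndarray
    column_sds: np.ndarray
    cumulative_load: float
    dropped_bands: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


# ---------------------------------------------------------------------------
# PLS-DA / RMSECV engine
# ---------------------------------------------------------------------------

def _one_hot(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes, idx = np.unique(labels, return_inverse=True)
    if classes.size < 2:
        raise InvalidArgumentError("need at least 2 classes")
    return np.eye(classes.size)[idx], classes


def _stratified_folds(labels: np.ndarray, k: int, seed) -> list[tuple[np.ndarray, np.ndarray]]:
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise StratificationError(
            f"smallest class has {counts.min()} samples, fewer than k={k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(labels.size), labels))


def _fit_pls(X: np.ndarray, Y: np.ndarray, n_components: int) -> PLSRegression:
    nc = int(min(n_components, X.shape[1], max(1, X.shape[0] - 1)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls = PLSRegression(n_components=nc, scale=False)
        pls.fit(X, Y)
    return pls


def pls_rmsecv(
    X: np.ndarray,
    labels: np.ndarray,
    n_components: int,
    k_folds: int = 5,
    rng_seed: Optional[int] = None,
) -> tuple[float, np.ndarray]:
    """Cross-validated PLS-DA error and per-band coefficient magnitudes.

    The class labels are one-hot encoded and regressed on the (internally
    centred) band matrix by NIPALS partial least squares. RMSECV pools the
    squared cross-validation residuals over every indicator column and sample
    under a stratified k-fold; the returned coefficient magnitudes are the
    per-band Euclidean norms over classes of the regression coefficients from
    a full-data fit.

    Returns
    -------
    rmsecv : float
    coef_magnitudes : ndarray of shape (n_bands,)
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n, p = X.shape
    max_nc = min(n - int(np.ceil(n / k_folds)) - 1, p)
    if n_components > max_nc:
        raise InvalidArgumentError(
            f"n_components={n_components} exceeds the usable maximum {max_nc} "
            f"for {n} samples, {p} bands, {k_folds} folds"
        )
    Y, _ = _one_hot(labels)
    folds = _stratified_folds(labels, k_folds, rng_seed)
    sq_sum = 0.0
    for tr, te in folds:
        pls = _fit_pls(X[tr], Y[tr], n_components)
        resid = Y[te] - pls.predict(X[te])
        sq_sum += float(np.sum(resid**2))
    rmsecv = float(np.sqrt(sq_sum / Y.size))
    full = _fit_pls(X, Y, n_components)
    coef = np.asarray(full.coef_)  # (n_targets, n_bands)
    magnitudes = np.linalg.norm(coef, axis=0)
    return rmsecv, magnitudes


def _choose_n_components(
    X: np.ndarray, labels: np.ndarray, k_folds: int, seed, max_components: int = MAX_PLS_COMPONENTS
) -> int:
    """Smallest-RMSECV component count over 1..max (first minimum wins)."""
    n, p = X.shape
    cap = min(max_components, p, n - int(np.ceil(n / k_folds)) - 1)
    cap = max(cap, 1)
    best_nc, best_err = 1, np.inf
    for nc in range(1, cap + 1):
        err, _ = pls_rmsecv(X, labels, nc, k_folds=k_folds, rng_seed=seed)
        if err < best_err - 1e-12:
            best_err, best_nc = err, nc
    return best_nc


# ---------------------------------------------------------------------------
# CARS
# ---------------------------------------------------------------------------

class CARSSelector(TransformerMixin, BaseEstimator):
    """Competitive adaptive reweighted sampling wavelength selection.

    Run ``i`` of ``n_runs``: (1) draw a stratified calibration subset of
    ``calib_fraction`` of the samples without replacement; (2) fit PLS-DA on
    the currently retained bands and take per-band coefficient magnitudes;
    (3) apply the enforced exponentially decreasing schedule, keeping the top
    ``r(i) * p`` bands by magnitude where ``r(i) = a * exp(-k i)`` is pinned
    to ``r(1) = 1`` and ``r(n_runs) = 2 / p``; (4) adaptively re-sample from
    those, with probability proportional to coefficient magnitude, without
    replacement, to the same retained count; (5) record the RMSECV of the
    retained set on the full data. The subset of the minimum-RMSECV run wins.

    Parameters
    ----------
    n_runs : int, default=50
        Number of sampling runs (>= 2).
    calib_fraction : float, default=0.8
        Fraction of samples in each run's calibration draw.
    n_components : int, optional
        PLS component count; chosen once by inner cross-validation over
        1..10 on the full band set when omitted.
    k_folds : int, default=5
        Folds of the stratified RMSECV.
    random_state : int, optional
        Governs calibration draws, reweighted sampling and fold assignment.
    """

    def __init__(
        self,
        n_runs: int = 50,
        calib_fraction: float = 0.8,
        n_components: Optional[int] = None,
        k_folds: int = 5,
        random_state: Optional[int] = None,
    ):
        self.n_runs = n_runs
        self.calib_fraction = calib_fraction
        self.n_components = n_components
        self.k_folds = k_folds
        self.random_state = random_state

    @staticmethod
    def edf_schedule(p: int, n_runs: int) -> np.ndarray:
        """Retained-band counts per run: p at run 1 decaying to 2 at the last."""
        i = np.arange(1, n_runs + 1, dtype=float)
        k = np.log(p / 2.0) / (n_runs - 1)
        a = np.exp(k)  # pins r(1) = 1
        ratio = a * np.exp(-k * i)
        counts = np.round(ratio * p).astype(int)
        counts[0], counts[-1] = p, 2
        counts = np.maximum(counts, 2)
        return np.minimum.accumulate(counts)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n, p = X.shape
        if p < 2:
            raise InvalidArgumentError("CARS needs at least 2 bands")
        if self.n_runs < 2:
            raise InvalidArgumentError("n_runs must be >= 2")
        rng = np.random.default_rng(self.random_state)
        fold_seed = int(rng.integers(2**31 - 1))
        nc = self.n_components
        if nc is None:
            nc = _choose_n_components(X, y, self.k_folds, fold_seed)
        self.n_components_ = nc

        counts = self.edf_schedule(p, self.n_runs)
        Y, _ = _one_hot(y)
        classes, class_idx = np.unique(y, return_inverse=True)
        retained = np.arange(p)
        traces, subsets = [], []
        for i in range(self.n_runs):
            cal = self._stratified_draw(class_idx, classes.size, rng)
            pls = _fit_pls(X[np.ix_(cal, retained)], Y[cal], min(nc, retained.size))
            mags = np.linalg.norm(np.asarray(pls.coef_), axis=0)
            target = counts[i]
            if retained.size < 2:
                raise RuntimeError(
                    "CARS schedule violation: retained set collapsed below 2 bands"
                )
            if target < retained.size:
                # enforced schedule: stable top-k keeps first index under ties
                order = np.argsort(-mags, kind="stable")[:target]
                retained = retained[np.sort(order)]
                mags = mags[np.sort(order)]
            # adaptive reweighted sampling: draw, weighted by |coefficient|,
            # without replacement, back to the same count
            if np.all(mags == 0):
                weights = np.full(retained.size, 1.0 / retained.size)
            else:
                weights = mags / mags.sum()
            keep = rng.choice(retained.size, size=retained.size, replace=False, p=weights)
            retained = np.sort(retained[keep])
            err, _ = pls_rmsecv(
                X[:, retained], y, min(nc, retained.size, self._max_nc(n)),
                k_folds=self.k_folds, rng_seed=fold_seed,
            )
            traces.append(err)
            subsets.append(retained.copy())

        trace = np.asarray(traces)
        best = int(np.argmin(trace))
        self.selected_ = subsets[best]
        self.rmsecv_trace_ = trace
        self.retained_counts_ = counts
        self.best_index_ = best
        self.n_features_in_ = p
        return self

    def _max_nc(self, n: int) -> int:
        return max(1, n - int(np.ceil(n / self.k_folds)) - 1)

    def _stratified_draw(self, class_idx: np.ndarray, n_classes: int, rng) -> np.ndarray:
        """Per-class draw of calib_fraction of samples, without replacement."""
        chosen = []
        for c in range(n_classes):
            members = np.flatnonzero(class_idx == c)
            k = max(2, int(round(self.calib_fraction * members.size)))
            k = min(k, members.size)
            chosen.append(rng.choice(members, size=k, replace=False))
        return np.sort(np.concatenate(chosen))

    def transform(self, X):
        check_is_fitted(self, "selected_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise InvalidArgumentError(
                f"expected {self.n_features_in_} bands, got {X.shape[1]}"
            )
        return X[:, self.selected_]

    @property
    def result_(self) -> SelectionResult:
        check_is_fitted(self, "selected_")
        return SelectionResult(
            selected=self.selected_,
            rmsecv_trace=self.rmsecv_trace_,
            best_index=self.best_index_,
            retained_counts=self.retained_counts_,
            n_components=self.n_components_,
        )


# ---------------------------------------------------------------------------
# SPA
# ---------------------------------------------------------------------------

class SPASelector(TransformerMixin, BaseEstimator):
    """Successive projections algorithm band selection.

    From every candidate starting band a chain of up to ``m_max`` bands is
    grown; each next band maximises the norm of its column's projection onto
    the orthogonal complement of the columns already chosen. Every (chain,
    prefix size) pair is scored by the stratified 5-fold CV RMSE of an
    ordinary least-squares fit of the one-hot indicator on the prefix (with
    intercept); the winner is the smallest prefix size whose RMSE is within
    ``plateau_tol`` of the global minimum (ties: the chain with the smaller
    RMSE, first index first).

    Parameters
    ----------
    m_max : int, default=30
        Maximum chain length; capped at ``min(n_bands, n_samples - 2)``.
    plateau_tol : float, default=1.01
        "Almost unchanged" plateau multiplier on the global minimum RMSE.
    k_folds : int, default=5
    random_state : int, optional
        Governs fold assignment only (the projections are deterministic).
    """

    def __init__(
        self,
        m_max: int = 30,
        plateau_tol: float = 1.01,
        k_folds: int = 5,
        random_state: Optional[int] = None,
    ):
        self.m_max = m_max
        self.plateau_tol = plateau_tol
        self.k_folds = k_folds
        self.random_state = random_state

    @staticmethod
    def build_chain(X: np.ndarray, start: int, m_max: int) -> list[int]:
        """Successive-projection chain from a starting column.

        Each step picks the unselected column with the largest residual norm
        after projecting out the span of the chain so far; the chain truncates
        when every remaining column is numerically inside that span.
        """
        n, p = X.shape
        norms2 = np.einsum("ij,ij->j", X, X)
        res2 = norms2.copy()
        chain = [start]
        q = X[:, start] / max(np.sqrt(norms2[start]), 1e-300)
        Q = [q]
        proj = q @ X
        res2 = res2 - proj**2
        selected = np.zeros(p, dtype=bool)
        selected[start] = True
        while len(chain) < m_max:
            res2_mask = np.where(selected, -np.inf, res2)
            j = int(np.argmax(res2_mask))
            if np.sqrt(max(res2_mask[j], 0.0)) < 1e-12:
                break  # remaining columns are collinear with the chain
            chain.append(j)
            selected[j] = True
            v = X[:, j].copy()
            for qk in Q:
                v -= (qk @ v) * qk
            nv = np.linalg.norm(v)
            if nv < 1e-300:
                break
            q = v / nv
            Q.append(q)
            proj = q @ X
            res2 = np.maximum(res2 - proj**2, 0.0)
        return chain

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n, p = X.shape
        m_max = min(self.m_max, p, n - 2)
        if m_max < 1:
            raise InvalidArgumentError("too few samples or bands for SPA")
        self.m_max_used_ = m_max
        Y, _ = _one_hot(y)
        folds = _stratified_folds(y, self.k_folds, self.random_state)

        chains = [self.build_chain(X, s, m_max) for s in range(p)]
        # sum of squared CV errors per (chain, prefix size); NaN = size unreachable
        sse = np.full((p, m_max), np.nan)
        counts = np.zeros((p, m_max))
        for tr, te in folds:
            Xtr, Xte, Ytr, Yte = X[tr], X[te], Y[tr], Y[te]
            for ci, chain in enumerate(chains):
                errs = self._prefix_cv_errors(Xtr, Ytr, Xte, Yte, chain)
                m_eff = len(errs)
                sse[ci, :m_eff] = np.nan_to_num(sse[ci, :m_eff]) + errs
                counts[ci, :m_eff] += Yte.size
        with np.errstate(invalid="ignore", divide="ignore"):
            rmse = np.sqrt(sse / counts)

        finite = np.isfinite(rmse)
        if not finite.any():
            raise InvalidArgumentError("SPA produced no evaluable subsets")
        global_min = np.nanmin(rmse)
        threshold = self.plateau_tol * global_min
        best_chain, best_m = None, None
        for m in range(m_max):
            col = rmse[:, m]
            ok = np.isfinite(col) & (col <= threshold)
            if ok.any():
                best_chain = int(np.flatnonzero(ok)[np.argmin(col[ok])])
                best_m = m + 1
                break
        assert best_chain is not None
        prefix = chains[best_chain][:best_m]
        trace = rmse[best_chain]
        trace = trace[np.isfinite(trace)]
        self.selected_ = np.sort(np.asarray(prefix, dtype=int))
        self.rmsecv_trace_ = trace
        self.best_index_ = int(np.argmin(trace))
        self.n_features_in_ = p
        return self

    @staticmethod
    def _prefix_cv_errors(
        Xtr: np.ndarray, Ytr: np.ndarray, Xte: np.ndarray, Yte: np.ndarray, chain: list[int]
    ) -> np.ndarray:
        """Summed squared test errors of OLS indicator fits on every prefix.

        Incremental Gram-Schmidt with an R factor: adding one band updates the
        QR factorisation of the training design matrix (intercept + prefix
        columns), so every prefix is scored in one pass over the chain. A
        column collinear with the current span (within this training fold)
        contributes no pivot and implicitly carries a zero coefficient.
        """
        n_tr = Xtr.shape[0]
        m = len(chain)
        Q = np.empty((n_tr, m + 1))
        R = np.zeros((m + 1, m + 1))
        D = np.empty((m + 1, Ytr.shape[1]))
        Q[:, 0] = 1.0 / np.sqrt(n_tr)
        R[0, 0] = np.sqrt(n_tr)
        D[0] = Q[:, 0] @ Ytr
        retained_cols = [0]  # design-column indices holding a pivot
        Ate = np.column_stack([np.ones(Xte.shape[0]), Xte[:, chain]])
        errs = np.empty(m)
        k = 1
        for j, band in enumerate(chain):
            v = Xtr[:, band].astype(float, copy=True)
            col_norm = np.linalg.norm(v)
            s = Q[:, :k].T @ v
            v -= Q[:, :k] @ s
            nv = np.linalg.norm(v)
            if nv > 1e-10 * max(1.0, col_norm):
                Q[:, k] = v / nv
                R[:k, k] = s
                R[k, k] = nv
                D[k] = Q[:, k] @ Ytr
                retained_cols.append(j + 1)
                k += 1
            # LS coefficients of the retained design columns: beta = R^{-1} Q'Y
            beta = solve_triangular(R[:k, :k], D[:k], lower=False)
            resid = Yte - Ate[:, retained_cols] @ beta
            errs[j] = float(np.sum(resid**2))
        return errs

    def transform(self, X):
        check_is_fitted(self, "selected_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise InvalidArgumentError(
                f"expected {self.n_features_in_} bands, got {X.shape[1]}"
            )
        return X[:, self.selected_]

    @property
    def result_(self) -> SelectionResult:
        check_is_fitted(self, "selected_")
        return SelectionResult(
            selected=self.selected_,
            rmsecv_trace=self.rmsecv_trace_,
            best_index=self.best_index_,
        )


# ---------------------------------------------------------------------------
# Kaiser PCA
# ---------------------------------------------------------------------------

class KaiserPCA(TransformerMixin, BaseEstimator):
    """PCA on the band correlation matrix with the eigenvalue > 1 rule.

    ``fit`` standardises each band (mean 0, sd 1 with an n-1 denominator),
    eigendecomposes the correlation matrix and retains the components with
    eigenvalue above 1 (a component weaker than a single standardised band
    carries no summarising power); at least the leading component is always
    kept. Zero-variance bands are dropped with a warning and recorded.
    ``transform`` standardises with the stored statistics and projects onto
    the retained loadings.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if n < 2:
            raise InvalidArgumentError("PCA needs at least 2 training samples")
        sds = X.std(axis=0, ddof=1)
        # a column is constant when its range is exactly zero or its sd is
        # numerically indistinguishable from rounding noise at its own scale
        scale = np.maximum(np.abs(X).max(axis=0), 1.0)
        constant = (np.ptp(X, axis=0) == 0) | (sds < 1e-12 * scale)
        dropped = np.flatnonzero(constant)
        if dropped.size:
            warnings.warn(
                f"dropping {dropped.size} zero-variance band(s) at indices "
                f"{dropped[:10].tolist()}",
                UserWarning,
                stacklevel=2,
            )
        kept = np.flatnonzero(~constant)
        if kept.size == 0:
            raise InvalidArgumentError("every band has zero variance")
        Z = (X[:, kept] - X[:, kept].mean(axis=0)) / sds[kept]
        corr = (Z.T @ Z) / (n - 1)
        eigvals, eigvecs = np.linalg.eigh(corr)
        order = np.argsort(eigvals)[::-1]
        eigvals = np.maximum(eigvals[order], 0.0)
        eigvecs = eigvecs[:, order]
        n_retained = max(1, int(np.sum(eigvals > 1.0)))
        self.kept_bands_ = kept
        self.dropped_bands_ = dropped
        self.column_means_ = X[:, kept].mean(axis=0)
        self.column_sds_ = sds[kept]
        self.eigenvalues_ = eigvals
        self.loadings_ = eigvecs[:, :n_retained]
        self.n_retained_ = n_retained
        self.cumulative_load_ = float(eigvals[:n_retained].sum() / eigvals.sum())
        self.n_features_in_ = p
        return self

    def transform(self, X):
        check_is_fitted(self, "loadings_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise InvalidArgumentError(
                f"expected {self.n_features_in_} bands, got {X.shape[1]}"
            )
        Z = (X[:, self.kept_bands_] - self.column_means_) / self.column_sds_
        return Z @ self.loadings_

    @property
    def model_(self) -> PCModel:
        check_is_fitted(self, "loadings_")
        return PCModel(
            loadings=self.loadings_,
            eigenvalues=self.eigenvalues_,
            n_retained=self.n_retained_,
            column_means=self.column_means_,
            column_sds=self.column_sds_,
            cumulative_load=self.cumulative_load_,
            dropped_bands=self.dropped_bands_,
        )


# ---------------------------------------------------------------------------
# SpectrumSet-level wrappers
# ---------------------------------------------------------------------------

def cars_select(
    sset: SpectrumSet,
    n_runs: int = 50,
    calib_fraction: float = 0.8,
    n_components: Optional[int] = None,
    k_folds: int = 5,
    rng_seed: Optional[int] = None,
) -> SelectionResult:
    """Run CARS on a SpectrumSet and return its :class:`SelectionResult`."""
    sel = CARSSelector(
        n_runs=n_runs,
        calib_fraction=calib_fraction,
        n_components=n_components,
        k_folds=k_folds,
        random_state=rng_seed,
    ).fit(sset.reflectance, sset.labels)
    return sel.result_


def spa_select(
    sset: SpectrumSet, m_max: int = 30, rng_seed: Optional[int] = None
) -> SelectionResult:
    """Run SPA on a SpectrumSet and return its :class:`SelectionResult`."""
    sel = SPASelector(m_max=m_max, random_state=rng_seed).fit(
        sset.reflectance, sset.labels
    )
    return sel.result_


def pca_fit(train: SpectrumSet) -> PCModel:
    """Fit Kaiser-rule PCA on a training SpectrumSet."""
    return KaiserPCA().fit(train.reflectance).model_


def pca_apply(sset: SpectrumSet, model: PCModel) -> np.ndarray:
    """Project a SpectrumSet onto a fitted :class:`PCModel`'s retained axes."""
    pca = KaiserPCA()
    pca.kept_bands_ = np.setdiff1d(
        np.arange(model.column_means.size + model.dropped_bands.size),
        model.dropped_bands,
    )
    pca.dropped_bands_ = model.dropped_bands
    pca.column_means_ = model.column_means
    pca.column_sds_ = model.column_sds
    pca.eigenvalues_ = model.eigenvalues
    pca.loadings_ = model.loadings
    pca.n_retained_ = model.n_retained
    pca.cumulative_load_ = model.cumulative_load
    pca.n_features_in_ = model.column_means.size + model.dropped_bands.size
    return pca.transform(sset.reflectance)


#: Factory registry: short name -> selector constructor taking random_state.
SELECTORS = {
    "cars": lambda random_state=None: CARSSelector(random_state=random_state),
    "spa": lambda random_state=None: SPASelector(random_state=random_state),
    "pca": lambda random_state=None: KaiserPCA(),
}


def make_selector(name: str, random_state: Optional[int] = None):
    """Instantiate a selector transformer by its short name."""
    if name not in SELECTORS:
        raise InvalidArgumentError(
            f"unknown selector {name!r}; choose from {sorted(SELECTORS)}"
        )
    return SELECTORS[name](random_state=random_state)
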