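"""The factorial pretreatment x selector x classifier benchmark.

``run_grid`` evaluates every combination of pretreatment, wavelength
selector and classifier on one shared stratified 3:1 split: the pretreatment
is fitted on the training partition (where stateful) and applied to both
partitions, selection is fitted on the training partition, and the classifier
is trained on the selected training features. Each cell records train and
test accuracies plus a 5-fold cross-validation accuracy computed *within the
training partition* under the same per-fold fitting discipline, so the test
partition never leaks into any fitted statistic. With the default six
pretreatments, three selectors and five classifiers the grid has 90 cells.

``pooled_fit=True`` instead fits the stateful pretreatment and the selector
once on all samples and cross-validates over the full set — a shortcut often
seen in applied chemometric studies — and logs a leakage warning.

A failed cell is caught, logged and recorded; the grid always completes.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold

from . import __version__ as _pkg_version
from .classify import ClassifierSpec, EvalResult, make_classifier, _fit, stratified_split
from .dataset import SpectrumSet
from .exceptions import (
    DegenerateTraitError,
    InvalidArgumentError,
    LookupError_,
)
from .feature_select import make_selector
from .preprocess import make_pretreatment

__all__ = [
    "DEFAULT_PRETREATMENTS",
    "DEFAULT_SELECTORS",
    "DEFAULT_CLASSIFIERS",
    "enumerate_grid",
    "GridEntry",
    "BenchmarkResult",
    "run_grid",
    "confusion_report",
    "correlate_trait",
    "result_table",
]

logger = logging.getLogger(__name__)

DEFAULT_PRETREATMENTS = ("sg", "fd", "snv", "fft", "ht", "msc")
DEFAULT_SELECTORS = ("cars", "spa", "pca")
DEFAULT_CLASSIFIERS = ("bayes", "svm", "knn", "el", "ann")


def enumerate_grid(
    pretreatments: Sequence[str] = DEFAULT_PRETREATMENTS,
    selectors: Sequence[str] = DEFAULT_SELECTORS,
    classifiers: Sequence[str] = DEFAULT_CLASSIFIERS,
) -> list[tuple[str, str, str]]:
    """All (pretreatment, selector, classifier) triples of the grid."""
    if not (pretreatments and selectors and classifiers):
        raise InvalidArgumentError("method lists must be non-empty")
    return list(product(pretreatments, selectors, classifiers))


@dataclass
class GridEntry:
    """One grid cell: its evaluation or the error that prevented it."""

    triple: tuple[str, str, str]
    eval: Optional[EvalResult] = None
    n_features: Optional[int] = None
    selection_summary: dict = field(default_factory=dict)
    error: Optional[str] = None
    runtime_s: float = 0.0

    @property
    def ok(self) -> bool:
        return self.error is None


@dataclass
class BenchmarkResult:
    """All grid entries plus the winning triple and run provenance."""

    entries: dict[tuple[str, str, str], GridEntry]
    best: Optional[tuple[str, str, str]]
    provenance: dict

    def __getitem__(self, triple: tuple[str, str, str]) -> GridEntry:
        if triple not in self.entries:
            raise LookupError_(f"no grid entry for triple {triple!r}")
        return self.entries[triple]


def _derive_seed(base: int, *tokens) -> int:
    """Stable sub-seed from a base seed and a name path (below 2**31)."""
    crc = zlib.crc32("/".join(str(t) for t in tokens).encode())
    return int((int(base) * 2654435761 + crc) % (2**31 - 1))


def _best_triple(entries: dict) -> Optional[tuple[str, str, str]]:
    """Highest cv accuracy; ties by test accuracy, then lexicographic."""
    candidates = [
        (e.eval.cv_accuracy, e.eval.test_accuracy, t)
        for t, e in entries.items()
        if e.ok and e.eval is not None
    ]
    if not candidates:
        return None
    # lexicographically smallest triple among maxima: sort descending on the
    # accuracies and ascending on the triple
    candidates.sort(key=lambda c: (-c[0], -c[1], c[2]))
    return candidates[0][2]


def run_grid(
    sset: SpectrumSet,
    pretreatments: Sequence[str] = DEFAULT_PRETREATMENTS,
    selectors: Sequence[str] = DEFAULT_SELECTORS,
    classifiers: Sequence[str] = DEFAULT_CLASSIFIERS,
    rng_seed: int = 0,
    cv_folds: int = 5,
    train_fraction: float = 0.75,
    pooled_fit: bool = False,
    selector_params: Optional[dict[str, dict]] = None,
) -> BenchmarkResult:
    """Run the full factorial benchmark on one shared stratified split.

    Parameters
    ----------
    sset : SpectrumSet
        Labeled reflectance spectra.
    pretreatments, selectors, classifiers : sequences of short names
        Grid axes; defaults give the full 6 x 3 x 5 = 90-cell study.
    rng_seed : int
        Master seed; every stage derives its own stable sub-seed from it.
    cv_folds : int, default=5
        Folds of the cross-validation accuracy.
    train_fraction : float, default=0.75
        The 3:1 split.
    pooled_fit : bool, default=False
        Fit stateful pretreatment and selection once on *all* samples and
        cross-validate the full set (leakage; logged as such).
    selector_params : dict, optional
        Extra constructor arguments per selector name, e.g.
        ``{"cars": {"n_runs": 30}}``.
    """
    triples = enumerate_grid(pretreatments, selectors, classifiers)
    selector_params = selector_params or {}
    wl = sset.wavelengths
    split_seed = _derive_seed(rng_seed, "split")
    train, test = stratified_split(sset, train_fraction, rng_seed=split_seed)
    if pooled_fit:
        logger.warning(
            "pooled_fit: pretreatment/selection fitted on ALL samples and "
            "cross-validation run over the full set; test information leaks "
            "into fitted statistics"
        )

    y_tr, y_te = train.labels, test.labels
    cv_set = sset if pooled_fit else train
    skf = StratifiedKFold(
        n_splits=cv_folds, shuffle=True, random_state=_derive_seed(rng_seed, "cv")
    )
    cv_splits = list(skf.split(cv_set.reflectance, cv_set.labels))

    pre_cache: dict = {}
    feat_cache: dict = {}
    fold_cache: dict = {}
    entries: dict[tuple[str, str, str], GridEntry] = {}

    def _pretreated(pre_name: str):
        if pre_name not in pre_cache:
            pre = make_pretreatment(pre_name, wavelengths=wl)
            fit_X = sset.reflectance if pooled_fit else train.reflectance
            pre.fit(fit_X)
            pre_cache[pre_name] = (
                pre.transform(train.reflectance),
                pre.transform(test.reflectance),
            )
        return pre_cache[pre_name]

    def _selected(pre_name: str, sel_name: str):
        key = (pre_name, sel_name)
        if key not in feat_cache:
            Xtr_p, Xte_p = _pretreated(pre_name)
            seed = _derive_seed(rng_seed, "select", pre_name, sel_name)
            sel = make_selector(sel_name, random_state=seed)
            for k, v in selector_params.get(sel_name, {}).items():
                setattr(sel, k, v)
            if pooled_fit:
                pre = make_pretreatment(pre_name, wavelengths=wl)
                X_all = pre.fit_transform(sset.reflectance)
                sel.fit(X_all, sset.labels)
            else:
                sel.fit(Xtr_p, y_tr)
            summary = {"selector": sel_name}
            if hasattr(sel, "selected_"):
                summary["selected_bands"] = sel.selected_.tolist()
                summary["selected_wavelengths_nm"] = wl[sel.selected_].round(2).tolist()
            if hasattr(sel, "n_retained_"):
                summary["n_components_retained"] = int(sel.n_retained_)
                summary["cumulative_load"] = float(sel.cumulative_load_)
            Xtr_f = sel.transform(Xtr_p)
            Xte_f = sel.transform(Xte_p)
            feat_cache[key] = (Xtr_f, Xte_f, summary)
        return feat_cache[key]

    def _fold_features(pre_name: str, sel_name: str, fold: int):
        """Per-fold pretreat + select, fitted on the fold's training side."""
        key = (pre_name, sel_name, fold)
        if key not in fold_cache:
            tr, te = cv_splits[fold]
            X, y = cv_set.reflectance, cv_set.labels
            if pooled_fit:
                # selection fitted once on all data; folds reuse it
                pre = make_pretreatment(pre_name, wavelengths=wl)
                pre.fit(X)
                Xp = pre.transform(X)
                _, _, _summary = _selected(pre_name, sel_name)
                seed = _derive_seed(rng_seed, "select", pre_name, sel_name)
                sel = make_selector(sel_name, random_state=seed)
                for k, v in selector_params.get(sel_name, {}).items():
                    setattr(sel, k, v)
                sel.fit(Xp, y)
                fold_cache[key] = (sel.transform(Xp[tr]), sel.transform(Xp[te]))
            else:
                pre = make_pretreatment(pre_name, wavelengths=wl)
                pre.fit(X[tr])
                Xtr_p = pre.transform(X[tr])
                Xte_p = pre.transform(X[te])
                seed = _derive_seed(rng_seed, "select", pre_name, sel_name, fold)
                sel = make_selector(sel_name, random_state=seed)
                for k, v in selector_params.get(sel_name, {}).items():
                    setattr(sel, k, v)
                sel.fit(Xtr_p, y[tr])
                fold_cache[key] = (sel.transform(Xtr_p), sel.transform(Xte_p))
        return fold_cache[key]

    classes = np.unique(cv_set.labels)
    for triple in triples:
        pre_name, sel_name, clf_name = triple
        t0 = time.perf_counter()
        try:
            Xtr_f, Xte_f, summary = _selected(pre_name, sel_name)
            clf_seed = _derive_seed(rng_seed, "clf", *triple)
            spec = ClassifierSpec(name=clf_name, rng_seed=clf_seed)
            est = make_classifier(spec, n_train=Xtr_f.shape[0])
            _fit(est, Xtr_f, y_tr)
            train_acc = float(np.mean(est.predict(Xtr_f) == y_tr))
            test_acc = float(np.mean(est.predict(Xte_f) == y_te))

            y_cv = cv_set.labels
            predictions = np.empty(y_cv.shape, dtype=y_cv.dtype)
            for fold, (tr, te) in enumerate(cv_splits):
                Xtr_cv, Xte_cv = _fold_features(pre_name, sel_name, fold)
                fold_est = make_classifier(spec, n_train=Xtr_cv.shape[0])
                _fit(fold_est, Xtr_cv, y_cv[tr])
                predictions[te] = fold_est.predict(Xte_cv)
            conf = confusion_matrix(y_cv, predictions, labels=classes)
            cv_acc = float(np.trace(conf) / conf.sum())
            row_sums = conf.sum(axis=1)
            recall = np.divide(
                np.diag(conf),
                row_sums,
                out=np.zeros(classes.size),
                where=row_sums > 0,
            )
            entries[triple] = GridEntry(
                triple=triple,
                eval=EvalResult(
                    train_accuracy=train_acc,
                    test_accuracy=test_acc,
                    cv_accuracy=cv_acc,
                    confusion=conf,
                    per_class_recall=recall,
                    classes=classes,
                ),
                n_features=int(Xtr_f.shape[1]),
                selection_summary=summary,
                runtime_s=time.perf_counter() - t0,
            )
            logger.info(
                "%s: train %.3f test %.3f cv %.3f (%d features, %.1fs)",
                "-".join(triple), train_acc, test_acc, cv_acc,
                Xtr_f.shape[1], entries[triple].runtime_s,
            )
        except Exception as exc:  # a failed cell must not abort the study
            logger.exception("grid cell %s failed", "-".join(triple))
            entries[triple] = GridEntry(
                triple=triple,
                error=f"{type(exc).__name__}: {exc}",
                runtime_s=time.perf_counter() - t0,
            )

    config_hash = zlib.crc32(
        repr((sorted(pretreatments), sorted(selectors), sorted(classifiers),
              rng_seed, cv_folds, train_fraction, pooled_fit)).encode()
    )
    provenance = {
        "rng_seed": int(rng_seed),
        "package_version": _pkg_version,
        "config_hash": f"{config_hash:08x}",
        "n_samples": int(sset.n_samples),
        "n_bands": int(sset.n_bands),
        "n_train": int(train.n_samples),
        "n_test": int(test.n_samples),
        "pooled_fit": bool(pooled_fit),
        "cv_folds": int(cv_folds),
    }
    return BenchmarkResult(
        entries=entries, best=_best_triple(entries), provenance=provenance
    )


def confusion_report(
    result: BenchmarkResult, triple: tuple[str, str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Confusion matrix and per-class recall table for one grid cell.

    Rows of the matrix are true classes, columns predicted classes; the
    recall table is the row-normalised diagonal.
    """
    entry = result[triple]
    if not entry.ok or entry.eval is None:
        raise LookupError_(f"grid entry {triple!r} failed: {entry.error}")
    ev = entry.eval
    classes = [str(c) for c in ev.classes]
    matrix = pd.DataFrame(ev.confusion, index=classes, columns=classes)
    recall = pd.DataFrame({"class": classes, "recall": ev.per_class_recall})
    return matrix, recall


def correlate_trait(
    sset: SpectrumSet, trait: dict
) -> tuple[np.ndarray, float, float]:
    """Per-band Pearson correlation of reflectance with a per-class trait.

    Each sample is assigned its class's trait value (e.g. crude protein
    content); the return is the full per-band correlation vector, the largest
    absolute correlation, and the wavelength achieving it.
    """
    missing = [c for c in sset.classes if c not in trait]
    if missing:
        raise LookupError_(f"trait table is missing class(es) {missing}")
    values = np.array([float(trait[label]) for label in sset.labels])
    if np.ptp(values) == 0:
        raise DegenerateTraitError(
            "trait is constant across classes; correlation is undefined"
        )
    X = sset.reflectance
    xc = X - X.mean(axis=0)
    tc = values - values.mean()
    denom = np.sqrt(np.sum(xc**2, axis=0) * np.sum(tc**2))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xc.T @ tc) / denom, 0.0)
    best = int(np.argmax(np.abs(r)))
    return r, float(np.abs(r[best])), float(sset.wavelengths[best])


def result_table(result: BenchmarkResult) -> pd.DataFrame:
    """Tidy one-row-per-cell summary of a benchmark run."""
    rows = []
    for triple, entry in result.entries.items():
        row = {
            "pretreatment": triple[0],
            "selector": triple[1],
            "classifier": triple[2],
            "ok": entry.ok,
            "n_features": entry.n_features,
            "runtime_s": round(entry.runtime_s, 3),
            "error": entry.error,
        }
        if entry.ok and entry.eval is not None:
            row.update(
                train_acc=entry.eval.train_accuracy,
                test_acc=entry.eval.test_accuracy,
                cv_acc=entry.eval.cv_accuracy,
            )
        rows.append(row)
    return pd.DataFrame(rows)
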