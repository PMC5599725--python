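"""ROI-state features and the cross-validated classifier x threshold x network grid.

Each (network, z-threshold) cell binarizes the subject z-maps, fits the
discriminative-ROI model, turns its ROI states into a binary feature matrix,
and evaluates three classifier families -- a linear SVM, a small multilayer
perceptron, and a C4.5-style decision tree -- with stratified 10-fold
cross-validation. Sensitivity is the true-positive rate for MHE, specificity
the true-negative rate for NMHE, and all metrics are pooled over folds and
reported in percent. Cells where no ROI validates are recorded at the
majority-class baseline so the factorial grid stays complete.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .gamma import GammaModel, GammaParams, fit_gamma, roi_states, roi_volume
from .tree import C45Tree

__all__ = [
    "CLASSIFIERS",
    "EmptyFeatureSetError",
    "CVMetrics",
    "extract_features",
    "crossval_metrics",
    "majority_baseline",
    "run_grid",
]

CLASSIFIERS = ("SVM", "MLP", "TREE")


class EmptyFeatureSetError(ValueError):
    """The model validated zero ROIs, so there are no features to extract."""


@dataclass(frozen=True)
class CVMetrics:
    acc: float  # percent
    sen: float  # percent, true-positive rate for MHE
    spe: float  # percent, true-negative rate for NMHE


def extract_features(model: GammaModel, maps: np.ndarray) -> np.ndarray:
    """Binary subjects x ROIs matrix of majority ROI states.

    ``maps`` is the (n, X, Y, Z) boolean stack of subject binary maps at the
    model's threshold.
    """
    if model.n_rois == 0:
        raise EmptyFeatureSetError(
            f"model for {model.icn} at z>{model.threshold} has no validated ROIs"
        )
    maps = np.asarray(maps).astype(bool)
    cols = [
        roi_states(maps, roi_volume(r, maps.shape[1:]), model.params.tau)
        for r in model.rois
    ]
    return np.column_stack(cols)


def _make_classifier(kind: str, n_features: int, seed: int):
    if kind == "SVM":
        return SVC(kernel="linear", C=1.0)
    if kind == "MLP":
        hidden = max(1, (n_features + 2) // 2)
        # full-batch lbfgs: converges on the small cohorts this grid sees,
        # where stochastic optimizers stall at the majority solution
        return MLPClassifier(
            hidden_layer_sizes=(hidden,), solver="lbfgs", max_iter=1000,
            random_state=seed,
        )
    if kind == "TREE":
        return C45Tree()
    raise ValueError(f"unknown classifier kind {kind!r}; expected one of {CLASSIFIERS}")


def _pooled_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> CVMetrics:
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    sen = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    spe = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    acc = 100.0 * (tp + tn) / len(y_true)
    return CVMetrics(acc=acc, sen=sen, spe=spe)


def crossval_metrics(
    features: np.ndarray,
    labels: np.ndarray,
    kind: str,
    k_folds: int = 10,
    seed: int = 0,
) -> CVMetrics:
    """Stratified k-fold cross-validation with fold-pooled predictions.

    ``labels`` is boolean/0-1 with 1 = MHE (the positive class).
    """
    features = np.asarray(features)
    y = np.asarray(labels).astype(int)
    if features.ndim != 2 or features.shape[0] != y.size:
        raise ValueError("features must be (n_subjects, n_features) aligned with labels")
    if y.size < k_folds:
        raise ValueError("need at least one subject per fold")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    pred = np.empty_like(y)
    for train, test in skf.split(features, y):
        clf = _make_classifier(kind, features.shape[1], seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MLP convergence chatter on tiny folds
            clf.fit(features[train], y[train])
        pred[test] = clf.predict(features[test])
    return _pooled_metrics(y, pred)


def majority_baseline(labels: np.ndarray) -> CVMetrics:
    """Metrics of always predicting the majority class (NMHE in this cohort)."""
    y = np.asarray(labels).astype(int)
    maj = int(y.mean() >= 0.5)
    pred = np.full_like(y, maj)
    return _pooled_metrics(y, pred)


def run_grid(
    zmaps: dict[str, np.ndarray],
    labels: np.ndarray,
    thresholds: tuple[float, ...],
    params: GammaParams | None = None,
    *,
    mask: np.ndarray | None = None,
    k_folds: int = 10,
    seed: int = 0,
    classifiers: tuple[str, ...] = CLASSIFIERS,
) -> pd.DataFrame:
    """Evaluate every (network, threshold, classifier) cell.

    ``zmaps`` maps network name -> (n_subjects, X, Y, Z) z-score stack. Returns
    a tidy frame with columns icn, threshold, classifier, acc, sen, spe,
    n_rois, baseline (True where no ROI validated and the majority baseline was
    recorded). Deterministic given ``seed``: permutation RNG and CV folds are
    seeded per (network, threshold) from the master seed.
    """
    params = params or GammaParams()
    y = np.asarray(labels).astype(bool)
    rows = []
    for ik, (icn, stack) in enumerate(sorted(zmaps.items())):
        stack = np.asarray(stack)
        for it, thr in enumerate(thresholds):
            cell_ss = np.random.SeedSequence(seed, spawn_key=(ik, it))
            gamma_seed, cv_seed = (int(s) for s in cell_ss.generate_state(2) % (2**31))
            maps = stack > thr
            cell_params = GammaParams(**{**params.__dict__, "seed": gamma_seed})
            n_rois = 0
            features = None
            try:
                model = fit_gamma(
                    maps, y, cell_params, mask=mask, icn=icn, threshold=thr
                )
                n_rois = model.n_rois
                if n_rois:
                    features = extract_features(model, maps)
            except Exception as exc:  # keep the factorial grid complete
                warnings.warn(
                    f"cell ({icn}, z>{thr}) failed ({exc}); recording baseline"
                )
            for kind in classifiers:
                if features is None:
                    m = majority_baseline(y)
                    base = True
                else:
                    try:
                        m = crossval_metrics(features, y, kind, k_folds, cv_seed)
                        base = False
                    except Exception as exc:
                        warnings.warn(
                            f"classifier {kind} failed on ({icn}, z>{thr}): {exc}"
                        )
                        m = majority_baseline(y)
                        base = True
                rows.append(
                    {
                        "icn": icn,
                        "threshold": float(thr),
                        "classifier": kind,
                        "acc": m.acc,
                        "sen": m.sen,
                        "spe": m.spe,
                        "n_rois": n_rois,
                        "baseline": base,
                    }
                )
    return pd.DataFrame(rows)
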