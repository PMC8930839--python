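"""Mean-FCS features, forward-stepwise logistic regression and ROC/AUC.

For each ROI voxel the classifier feature is the subject's mean FCS against
all ROI voxels of the other tissue (e.g. one GM voxel vs. all WM ROI voxels).
A binary logistic model (patients coded 1) is built by forward stepwise
selection with likelihood-ratio entry/removal — the convention of common
statistical packages, entry p < 0.05, removal p > 0.10 — and the model's
predicted probabilities are scored with an ROC curve and trapezoidal AUC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit
from sklearn.metrics import roc_curve

from .errors import DegenerateInputError, InsufficientDataError, ShapeError
from .fcc import FcsTensor

log = logging.getLogger(__name__)

#: |coefficient| beyond which quasi-complete separation is declared
SEPARATION_COEF = 15.0
#: deviance below which the fit is treated as perfectly separated
SEPARATION_DEVIANCE = 1e-6

MAX_ITER = 100
SCORE_TOL = 1e-8


@dataclass
class FeatureTable:
    """Subjects x features design with binary labels (HC=0, PDH=1)."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.shape != (len(self.labels), len(self.feature_names)):
            raise ShapeError("feature table shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature table contains non-finite values")
        if set(np.unique(self.labels)) - {0, 1}:
            raise ValueError("labels must be 0/1")

    def subset(self, names: list[str]) -> np.ndarray:
        cols = [self.feature_names.index(n) for n in names]
        return self.values[:, cols]


@dataclass
class LogisticModel:
    """Fitted binary logistic model with stepwise bookkeeping."""

    intercept: float
    coefficients: dict[str, float]
    included_features: list[str]
    entry_pvalues: list[float]
    converged: bool
    separation_flag: bool
    deviance: float
    n_iter: int = 0

    def predict_proba(self, table: FeatureTable) -> np.ndarray:
        """P(label=1) per subject from the included features."""
        eta = np.full(len(table.labels), self.intercept)
        if self.included_features:
            X = table.subset(self.included_features)
            beta = np.array([self.coefficients[n] for n in self.included_features])
            eta = eta + X @ beta
        return expit(eta)


@dataclass
class RocCurve:
    """ROC sweep (descending thresholds) with trapezoidal AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def mean_fcs_features(
    fcs_roi: FcsTensor, labels: np.ndarray, axis: str = "per_gm_voxel"
) -> FeatureTable:
    """Per-subject mean FCS of each ROI voxel against the other tissue's ROI.

    ``per_gm_voxel``: one feature per GM ROI voxel, the mean over WM ROI
    voxels of that subject's FCS; ``per_wm_voxel`` is symmetric.
    """
    if fcs_roi.values.shape[1] == 0 or fcs_roi.values.shape[2] == 0:
        raise DegenerateInputError("empty ROI tensor")
    if axis == "per_gm_voxel":
        values = fcs_roi.values.mean(axis=2)
        names = [f"gm_mean_fcs:{int(v)}" for v in fcs_roi.gm_voxel_indices]
    elif axis == "per_wm_voxel":
        values = fcs_roi.values.mean(axis=1)
        names = [f"wm_mean_fcs:{int(v)}" for v in fcs_roi.wm_voxel_indices]
    else:
        raise ValueError(f"unknown axis {axis!r}")
    return FeatureTable(values=values, feature_names=names, labels=np.asarray(labels))


def _irls(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool, float, int]:
    """Logistic ML fit by iteratively reweighted least squares.

    Converges when the score's max absolute entry drops below ``SCORE_TOL``;
    rank deficiency is handled with a pseudo-inverse step so duplicated
    columns do not blow up.
    """
    beta = np.zeros(X.shape[1])
    converged = False
    for it in range(1, MAX_ITER + 1):
        p = expit(X @ beta)
        score = X.T @ (y - p)
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        w = np.clip(p * (1.0 - p), 1e-10, None)
        xtwx = X.T @ (X * w[:, None])
        beta = beta + np.linalg.pinv(xtwx) @ score
    p = np.clip(expit(X @ beta), 1e-15, 1 - 1e-15)
    deviance = -2.0 * float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return beta, converged, deviance, it


def fit_logistic(
    features: FeatureTable, columns: list[str] | None = None
) -> LogisticModel:
    """Maximum-likelihood logistic fit of the given feature columns.

    If any coefficient magnitude exceeds ``SEPARATION_COEF`` or the deviance
    collapses to ~0, the separation flag is set and the coefficients are
    reported as-is with a warning.
    """
    y = features.labels
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("labels contain a single class")
    names = list(features.feature_names) if columns is None else list(columns)
    X = np.column_stack([np.ones(len(y)), features.subset(names)])
    if len(y) < X.shape[1] + 1:
        raise InsufficientDataError("too few subjects for the number of features")
    beta, converged, deviance, n_iter = _irls(X, y)
    separation = bool(
        np.any(np.abs(beta) > SEPARATION_COEF) or deviance < SEPARATION_DEVIANCE
    )
    if separation:
        warnings.warn("quasi-complete separation detected; coefficients unreliable",
                      stacklevel=2)
    return LogisticModel(
        intercept=float(beta[0]),
        coefficients={n: float(b) for n, b in zip(names, beta[1:])},
        included_features=names,
        entry_pvalues=[],
        converged=converged,
        separation_flag=separation,
        deviance=deviance,
        n_iter=n_iter,
    )


def _deviance_of(features: FeatureTable, names: list[str]) -> float:
    y = features.labels
    X = np.column_stack([np.ones(len(y))] + (
        [features.subset(names)] if names else []
    ))
    _, _, dev, _ = _irls(X, y)
    return dev


def _adds_rank(features: FeatureTable, current: list[str], candidate: str) -> bool:
    """True if the candidate column is not collinear with the current design."""
    X = np.column_stack([np.ones(len(features.labels))] + (
        [features.subset(current)] if current else []
    ))
    c = features.subset([candidate])[:, 0]
    resid = c - X @ np.linalg.lstsq(X, c, rcond=None)[0]
    return float(np.linalg.norm(resid)) > 1e-8 * max(1.0, float(np.linalg.norm(c)))


def forward_stepwise(
    features: FeatureTable,
    entry_alpha: float = 0.05,
    removal_alpha: float = 0.10,
) -> LogisticModel:
    """Forward stepwise logistic selection with likelihood-ratio entry/removal.

    At each step the candidate with the smallest LRT p versus the current
    model enters if p < ``entry_alpha`` (ties break on the smaller feature
    index); after each entry, included features whose removal LRT p exceeds
    ``removal_alpha`` are dropped.  An empty model is a legal outcome.
    """
    included: list[str] = []
    entry_ps: list[float] = []
    dev_cur = _deviance_of(features, included)
    while True:
        best_name, best_p, best_dev = None, np.inf, None
        for name in features.feature_names:
            if name in included:
                continue
            if not _adds_rank(features, included, name):
                continue  # collinear with the current design; LRT p would be 1
            dev_new = _deviance_of(features, included + [name])
            lr = max(dev_cur - dev_new, 0.0)
            p = stats.chi2.sf(lr, df=1)
            if p < best_p - 1e-15:
                best_name, best_p, best_dev = name, p, dev_new
        if best_name is None or best_p >= entry_alpha:
            break
        included.append(best_name)
        entry_ps.append(float(best_p))
        dev_cur = best_dev
        # backward check: drop features that no longer earn their keep
        changed = True
        while changed and len(included) > 1:
            changed = False
            worst_name, worst_p = None, -1.0
            for name in included:
                rest = [n for n in included if n != name]
                dev_without = _deviance_of(features, rest)
                p_rm = stats.chi2.sf(max(dev_without - dev_cur, 0.0), df=1)
                if p_rm > worst_p:
                    worst_name, worst_p = name, p_rm
            if worst_name is not None and worst_p > removal_alpha:
                included.remove(worst_name)
                dev_cur = _deviance_of(features, included)
                changed = True
    if not included:
        log.info("no predictor entered the stepwise model")
        y = features.labels
        base = float(np.mean(y))
        intercept = float(np.log(base / (1 - base))) if 0 < base < 1 else 0.0
        return LogisticModel(
            intercept=intercept, coefficients={}, included_features=[],
            entry_pvalues=[], converged=True, separation_flag=False,
            deviance=dev_cur,
        )
    model = fit_logistic(features, columns=included)
    model.entry_pvalues = entry_ps
    return model


def roc_and_auc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC over descending unique-score thresholds, patients (1) positive.

    Tied scores collapse into a single step, so the trapezoidal AUC equals the
    Mann-Whitney statistic with half credit for ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise DegenerateInputError("ROC requires both classes present")
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)
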