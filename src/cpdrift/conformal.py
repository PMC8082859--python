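"""Inductive Mondrian conformal prediction for binary classification.

The conformal layer sits on top of an arbitrary *score model* that maps a
feature vector to two per-class scores in [0, 1] summing to 1.  Strangeness
of an example under a hypothesised label y is measured with the margin
nonconformity

    nc(s, y) = 0.5 - (s_y - s_{1-y}) / 2        in [0, 1],

and class-conditional (Mondrian) p-values are rank-based against the
calibration nonconformities of that same class:

    p_y = ( #{i : nc_i >= nc_test} + 1 ) / (n_y + 1).

A prediction set at significance level epsilon contains every label whose
p-value is strictly larger than epsilon; under exchangeability the per-class
error rate is then at most epsilon.

P-values are non-smoothed by default (ties counted in the numerator, which
is conservative); a randomised-tie smoothed variant is available via
``smoothed=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC

__all__ = [
    "ScoreModelSpec",
    "NearestCentroidScorer",
    "ICPModel",
    "margin_nc",
    "mondrian_pvalue",
    "prediction_set",
    "prediction_set_matrix",
    "fit_icp",
    "predict_icp",
    "recalibrate_icp",
]

_SCORE_SUM_TOL = 1e-6


class NearestCentroidScorer(BaseEstimator, ClassifierMixin):
    """Trivial distance-to-centroid score model.

    Scores are a softmax over negative squared Euclidean distances to the
    two class centroids.  Orders of magnitude faster than an SVM and used
    throughout the fast test suite; all conformal guarantees are agnostic
    to the quality of the underlying scores.
    """

    def __init__(self, tau: float = 1.0):
        self.tau = tau

    def fit(self, X, y):
        X = np.asarray(X) if not hasattr(X, "toarray") else X.toarray()
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.centroids_ = np.vstack([X[y == c].mean(axis=0) for c in self.classes_])
        return self

    def predict_proba(self, X):
        X = np.asarray(X) if not hasattr(X, "toarray") else X.toarray()
        d2 = ((X[:, None, :] - self.centroids_[None, :, :]) ** 2).sum(axis=2)
        z = -d2 / (2.0 * self.tau * X.shape[1] ** 0.5)
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


@dataclass(frozen=True)
class ScoreModelSpec:
    """Configuration of the underlying score model.

    The default is a probability-calibrated RBF support-vector classifier
    with ``C=50`` and ``gamma=0.002``, the hyperparameters used for the
    signature-descriptor toxicity models this package re-implements.
    ``algorithm="centroid"`` selects :class:`NearestCentroidScorer`.
    """

    algorithm: str = "svm"
    C: float = 50.0
    gamma: float = 0.002

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")

    def make_estimator(self, seed: int | None = None) -> BaseEstimator:
        if self.algorithm == "svm":
            # Platt-calibrated per-class scores from the RBF SVM decision
            # values; internal CV folds are unshuffled, so fits are
            # deterministic given the data
            return CalibratedClassifierCV(
                SVC(kernel="rbf", C=self.C, gamma=self.gamma, random_state=seed),
                method="sigmoid",
                cv=3,
                ensemble=False,
            )
        if self.algorithm == "centroid":
            return NearestCentroidScorer()
        raise ValueError(f"unknown score model algorithm {self.algorithm!r}")


@dataclass
class ICPModel:
    """A fitted inductive conformal predictor.

    ``cal_nc`` maps each class label to the *sorted* margin nonconformity
    scores of the calibration examples of that class (Mondrian condition).
    """

    model: BaseEstimator
    cal_nc: dict[int, np.ndarray]
    n_features: int
    spec: ScoreModelSpec
    seed: int | None = None

    @property
    def sizes(self) -> tuple[int, int]:
        return len(self.cal_nc[0]), len(self.cal_nc[1])


def margin_nc(scores: np.ndarray, labels: np.ndarray | int) -> np.ndarray:
    """Margin nonconformity of per-class scores under hypothesised labels.

    Parameters
    ----------
    scores:
        Array of shape (n, 2) (or (2,) for a single example) of per-class
        scores; each row must be nonnegative and sum to 1.
    labels:
        Hypothesised label(s) in {0, 1}; scalar or length-n array.

    Returns
    -------
    Nonconformity values in [0, 1]; 0 is most conforming.
    """
    s = np.atleast_2d(np.asarray(scores, dtype=float))
    if s.shape[1] != 2:
        raise ValueError("margin nonconformity expects two per-class scores")
    if np.any(s < -_SCORE_SUM_TOL) or np.any(np.abs(s.sum(axis=1) - 1.0) > _SCORE_SUM_TOL):
        raise ValueError("scores must be nonnegative and sum to 1")
    y = np.broadcast_to(np.asarray(labels, dtype=int), s.shape[0])
    s_true = s[np.arange(s.shape[0]), y]
    s_other = s[np.arange(s.shape[0]), 1 - y]
    nc = 0.5 - (s_true - s_other) / 2.0
    return nc if np.ndim(scores) > 1 else float(nc[0])


def mondrian_pvalue(
    cal_nc_sorted: np.ndarray,
    test_nc: np.ndarray | float,
    smoothed: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray | float:
    """Rank-based conformal p-value(s) against one class's calibration scores.

    p = (#{cal >= test} + 1) / (n + 1), ties counted in the numerator.
    With ``smoothed=True`` ties (and the +1 for the test point itself) are
    weighted by an independent uniform draw, giving exactly uniform p-values
    under exchangeability.
    An empty calibration list yields p = 1 for any test score.
    """
    cal = np.asarray(cal_nc_sorted, dtype=float)
    t = np.atleast_1d(np.asarray(test_nc, dtype=float))
    n = len(cal)
    n_gt = n - np.searchsorted(cal, t, side="right")  # strictly greater
    n_ge = n - np.searchsorted(cal, t, side="left")   # greater or equal
    if smoothed:
        if rng is None:
            rng = np.random.default_rng()
        u = rng.random(t.shape)
        p = (n_gt + u * (n_ge - n_gt + 1)) / (n + 1)
    else:
        p = (n_ge + 1.0) / (n + 1)
    return p if np.ndim(test_nc) > 0 else float(p[0])


def prediction_set(p0: float, p1: float, epsilon: float) -> frozenset[int]:
    """Labels whose p-value strictly exceeds the significance level."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    return frozenset(y for y, p in ((0, p0), (1, p1)) if p > epsilon)


def prediction_set_matrix(pvals: np.ndarray, epsilon: float) -> np.ndarray:
    """Vectorised prediction sets: boolean (n, 2) membership matrix."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    return np.asarray(pvals) > epsilon


def _class_scores(model: BaseEstimator, X) -> np.ndarray:
    proba = model.predict_proba(X)
    classes = np.asarray(getattr(model, "classes_", [0, 1]))
    # reorder columns to (class 0, class 1)
    order = np.argsort(classes)
    return proba[:, order]


def fit_icp(
    X_proper,
    y_proper,
    X_cal,
    y_cal,
    spec: ScoreModelSpec | None = None,
    seed: int | None = None,
) -> ICPModel:
    """Fit the score model on the proper training set and calibrate.

    Calibration nonconformities are the margin scores of each calibration
    example under its *true* label, grouped by class (Mondrian).  Both
    classes must be present in the proper training set and in the
    calibration set.
    """
    spec = spec or ScoreModelSpec()
    y_proper = np.asarray(y_proper)
    y_cal = np.asarray(y_cal)
    for name, y in (("proper training", y_proper), ("calibration", y_cal)):
        present = set(np.unique(y).tolist())
        if present != {0, 1}:
            raise ValueError(f"{name} set must contain both classes, has {present}")
    model = spec.make_estimator(seed)
    model.fit(X_proper, y_proper)
    scores = _class_scores(model, X_cal)
    nc = margin_nc(scores, y_cal)
    cal_nc = {c: np.sort(nc[y_cal == c]) for c in (0, 1)}
    n_features = X_proper.shape[1]
    return ICPModel(model=model, cal_nc=cal_nc, n_features=n_features, spec=spec, seed=seed)


def recalibrate_icp(icp: ICPModel, X_cal, y_cal) -> ICPModel:
    """Replace an ICP's calibration set; the fitted score model is reused.

    This is the cheap model-update strategy: no refit, only new
    class-conditional calibration nonconformities.
    """
    y_cal = np.asarray(y_cal)
    if set(np.unique(y_cal).tolist()) != {0, 1}:
        raise ValueError("new calibration set must contain both classes")
    scores = _class_scores(icp.model, X_cal)
    nc = margin_nc(scores, y_cal)
    cal_nc = {c: np.sort(nc[y_cal == c]) for c in (0, 1)}
    return ICPModel(
        model=icp.model,
        cal_nc=cal_nc,
        n_features=icp.n_features,
        spec=icp.spec,
        seed=icp.seed,
    )


def predict_icp(
    icp: ICPModel,
    X,
    smoothed: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Class-conditional p-values for each row of ``X``.

    Returns an array of shape (n, 2): column y holds the p-value of the
    hypothesis "this example has label y", ranked against the calibration
    nonconformities of class y.
    """
    if X.shape[1] != icp.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match training ({icp.n_features})"
        )
    scores = _class_scores(icp.model, X)
    out = np.empty((scores.shape[0], 2))
    for c in (0, 1):
        nc = margin_nc(scores, c)
        out[:, c] = mondrian_pvalue(icp.cal_nc[c], nc, smoothed=smoothed, rng=rng)
    return out
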