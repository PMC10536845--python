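"""Applicability-domain analysis by the leverage approach.

The domain of a QSAR model is delimited on a Williams plot: hat-matrix
leverages h_i against standardized cross-validated residuals. Compounds with
h above the threshold h* = 3P/n (P = model variables + 1) are structural
(X) outliers; compounds with |residual| above 2.5 SD units are response (Y)
outliers; both at once are XY outliers. The model is then re-evaluated
inside the domain, and train-inside/test-outside errors quantify the cost of
extrapolating beyond it.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .models import CVMetrics, cross_validate, cv_predictions, kfold_split, _fold_metrics

DEFAULT_RES_CUT = 2.5
DEFAULT_H_STAR_MULTIPLIER = 3.0

CLASS_IN = "in_domain"
CLASS_X = "X_outlier"
CLASS_Y = "Y_outlier"
CLASS_XY = "XY_outlier"


def leverage(X, svd_tol: float | None = None) -> np.ndarray:
    """Hat-matrix diagonal of the intercept-augmented design matrix.

    Computed from the SVD with tolerance-based rank truncation, so an
    ill-conditioned (or rank-deficient) Gram matrix never has to be inverted:
    h_i = Σ_j U_ij² over the retained singular directions. Guarantees
    0 ≤ h_i ≤ 1 and Σ h_i = rank of the augmented design."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ParameterError("leverage needs a 2-D design with at least 2 rows")
    n = len(X)
    X_aug = np.hstack([np.ones((n, 1)), X])
    U, s, _ = np.linalg.svd(X_aug, full_matrices=False)
    if svd_tol is None:
        svd_tol = max(X_aug.shape) * np.finfo(float).eps * (s[0] if len(s) else 0.0)
    rank = int((s > svd_tol).sum())
    if rank == 0:  # unreachable with the intercept column, kept as a guard
        warnings.warn("rank-0 design: leverages fall back to 1/n")
        return np.full(n, 1.0 / n)
    return (U[:, :rank] ** 2).sum(axis=1)


def leverage_threshold(P: int, n: int, multiplier: float = DEFAULT_H_STAR_MULTIPLIER) -> float:
    """h* = multiplier·P/n with P = number of model variables plus one."""
    if n <= 0:
        raise ParameterError("n must be positive")
    return multiplier * P / n


def standardized_cv_residuals(
    y, yhat_cv, leverage_correction: bool = False, h: np.ndarray | None = None
) -> np.ndarray:
    """Cross-validated residuals divided by their sample SD.

    With ``leverage_correction`` each residual is additionally scaled by
    1/√(1−h_i) before standardization (off by default)."""
    y = np.asarray(y, dtype=float)
    yhat_cv = np.asarray(yhat_cv, dtype=float)
    raw = y - yhat_cv
    if leverage_correction:
        if h is None:
            raise ParameterError("leverage_correction requires the leverage vector")
        raw = raw / np.sqrt(np.clip(1.0 - np.asarray(h, dtype=float), 1e-12, None))
    s = raw.std(ddof=1)
    if s == 0:
        warnings.warn("zero residual variance: standardized residuals all 0")
        return np.zeros_like(raw)
    return raw / s


@dataclass
class ADReport:
    """Williams-plot data: leverages, threshold, standardized CV residuals
    and the per-compound domain classification."""

    h: np.ndarray
    h_star: float
    res: np.ndarray
    classes: np.ndarray
    P: int
    n: int
    res_cut: float = DEFAULT_RES_CUT
    compound_ids: list = field(default_factory=list)

    @property
    def in_domain(self) -> np.ndarray:
        return self.classes == CLASS_IN

    def summary(self) -> dict:
        vals, counts = np.unique(self.classes, return_counts=True)
        by_class = dict(zip(vals.tolist(), counts.astype(int).tolist()))
        return {
            "n": self.n,
            "P": self.P,
            "h_star": self.h_star,
            "res_cut": self.res_cut,
            "n_in_domain": int(self.in_domain.sum()),
            "pct_in_domain": 100.0 * float(self.in_domain.mean()),
            "by_class": by_class,
        }

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"h": self.h, "res": self.res, "ad_class": self.classes})
        if self.compound_ids:
            df.insert(0, "compound_id", self.compound_ids)
        return df


def williams_classify(
    h, res, h_star: float, res_cut: float = DEFAULT_RES_CUT, compound_ids=None
) -> ADReport:
    """Classify each compound by strict-inequality Williams rules: points
    exactly on a threshold stay in the domain."""
    h = np.asarray(h, dtype=float)
    res = np.asarray(res, dtype=float)
    if h.shape != res.shape:
        raise ParameterError("leverage and residual vectors are misaligned")
    high_h = h > h_star
    high_res = np.abs(res) > res_cut
    classes = np.full(len(h), CLASS_IN, dtype=object)
    classes[high_h & ~high_res] = CLASS_X
    classes[~high_h & high_res] = CLASS_Y
    classes[high_h & high_res] = CLASS_XY
    return ADReport(
        h=h, h_star=h_star, res=res, classes=classes.astype(str),
        P=0, n=len(h), res_cut=res_cut,
        compound_ids=list(compound_ids) if compound_ids is not None else [],
    )


def ad_report(
    learner, X, y,
    k: int = 10, seed: int = 42,
    multiplier: float = DEFAULT_H_STAR_MULTIPLIER,
    res_cut: float = DEFAULT_RES_CUT,
    leverage_correction: bool = False,
    compound_ids=None,
) -> ADReport:
    """Full leverage-approach AD analysis of a learner on a dataset."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    h = leverage(X)
    P = X.shape[1] + 1
    h_star = leverage_threshold(P, len(X), multiplier)
    yhat = cv_predictions(learner, X, y, k=k, seed=seed)
    res = standardized_cv_residuals(y, yhat, leverage_correction=leverage_correction, h=h)
    report = williams_classify(h, res, h_star, res_cut, compound_ids=compound_ids)
    report.P = P
    report.n = len(X)
    return report


@dataclass
class ADEvaluation:
    """Inside-domain CV metrics paired with train-inside/test-outside errors
    (absent when the domain contains every compound)."""

    inside: CVMetrics
    outside: dict | None


def ad_evaluation(learner, X, y, report: ADReport, k: int = 10, seed: int = 42) -> ADEvaluation:
    """Re-evaluate the model within its AD and on the excluded outliers."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X) != report.n:
        raise ParameterError("report was not computed on this dataset")
    inside_mask = report.in_domain
    from sklearn.base import clone

    inside = cross_validate(learner, X[inside_mask], y[inside_mask], k=k, seed=seed)
    if inside_mask.all():
        return ADEvaluation(inside=inside, outside=None)
    model = clone(learner).fit(X[inside_mask], y[inside_mask])
    metrics = _fold_metrics(y[~inside_mask], model.predict(X[~inside_mask]))
    return ADEvaluation(
        inside=inside,
        outside={"rmse": metrics["rmse"], "mae": metrics["mae"],
                 "n_outside": int((~inside_mask).sum())},
    )


class LeverageAD:
    """Estimator-style wrapper: ``fit(X, y)`` runs the full leverage-approach
    analysis; ``predict(X=None)`` returns the domain classes of the training
    compounds; the fitted :class:`ADReport` sits in ``report_``."""

    def __init__(self, learner=None, k: int = 10, seed: int = 42,
                 multiplier: float = DEFAULT_H_STAR_MULTIPLIER,
                 res_cut: float = DEFAULT_RES_CUT,
                 leverage_correction: bool = False):
        self.learner = learner
        self.k = k
        self.seed = seed
        self.multiplier = multiplier
        self.res_cut = res_cut
        self.leverage_correction = leverage_correction

    def get_params(self, deep=True):
        return {
            "learner": self.learner, "k": self.k, "seed": self.seed,
            "multiplier": self.multiplier, "res_cut": self.res_cut,
            "leverage_correction": self.leverage_correction,
        }

    def set_params(self, **params):
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def fit(self, X, y):
        from .models import KNeighborsActivityRegressor

        learner = self.learner if self.learner is not None else KNeighborsActivityRegressor()
        self.report_ = ad_report(
            learner, X, y, k=self.k, seed=self.seed,
            multiplier=self.multiplier, res_cut=self.res_cut,
            leverage_correction=self.leverage_correction,
        )
        return self

    def predict(self, X=None) -> np.ndarray:
        if not hasattr(self, "report_"):
            raise ParameterError("LeverageAD is not fitted")
        return self.report_.classes
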