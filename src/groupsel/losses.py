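"""Convex data-fit terms with gradients and diagonal Hessian approximations.

Two losses are provided.  The logistic loss treats the weight vector as a
soft feature selector: the score of a sample is the weighted sum over all
features (no intercept — w is a selection device, not a classifier).  The
class-separation loss is a linear term -c'w rewarding features with high
per-feature discriminative power, scored by a Fisher-like ratio of the
between-class mean gap to the pooled within-class spread.

Both expose value / gradient / diagonal Hessian, which is all the CCCP
subproblem and the BCGD solver need.  The Hessian diagonal is floored at a
small positive value so quadratic-model steps are always defined (the linear
loss has zero curvature).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .data import LabeledMatrix

EPS_HESSIAN = 1e-6   # floor for diagonal curvature
EPS_SCORE = 1e-8     # guard in the relevance-score denominator

LOSS_NAMES = ("logistic", "class_separation")


@dataclass
class LossEval:
    """Value, gradient and diagonal-Hessian approximation of a loss at w."""
    value: float
    gradient: np.ndarray
    hessian_diag: np.ndarray


def feature_relevance_scores(X: LabeledMatrix) -> np.ndarray:
    """Per-feature discriminative scores in [0, 1].

    c_i = |mean_+(x_i) - mean_-(x_i)| / (sd_+(x_i) + sd_-(x_i) + eps),
    rescaled by the maximum.  A constant feature scores 0; the feature with
    the largest class separation scores 1.
    """
    pos = X.values[X.labels == 1]
    neg = X.values[X.labels == -1]
    gap = np.abs(pos.mean(axis=0) - neg.mean(axis=0))
    spread = pos.std(axis=0) + neg.std(axis=0)
    c = gap / (spread + EPS_SCORE)
    top = c.max()
    return c / top if top > 0 else c


class LogisticLoss:
    """L1(w) = sum_m log(1 + exp(-y_m s_m)) with s_m = sum_i w_i x_{m,i}.

    Overflow-safe via logaddexp / expit.  Precomputes X**2 for the diagonal
    Hessian sum_m x_{m,i}^2 sigma(s_m)(1 - sigma(s_m)).
    """

    name = "logistic"

    def __init__(self, X: LabeledMatrix):
        self.X = X.values
        self.y = X.labels.astype(float)
        self._X2 = self.X ** 2

    def _check(self, w):
        w = np.asarray(w, dtype=float)
        if w.shape != (self.X.shape[1],):
            raise ValueError(f"weight length {w.shape} != N={self.X.shape[1]}")
        return w

    def value(self, w) -> float:
        s = self.X @ self._check(w)
        return float(np.logaddexp(0.0, -self.y * s).sum())

    def __call__(self, w) -> LossEval:
        w = self._check(w)
        s = self.X @ w
        margins = self.y * s
        value = float(np.logaddexp(0.0, -margins).sum())
        p = expit(-margins)                      # sigma(-y_m s_m)
        gradient = self.X.T @ (-self.y * p)
        q = expit(s)
        curv = q * (1.0 - q)                     # sigma(s)(1-sigma(s))
        hessian_diag = np.maximum(self._X2.T @ curv, EPS_HESSIAN)
        return LossEval(value, gradient, hessian_diag)


class ClassSeparationLoss:
    """L1(w) = -c'w with c the feature relevance scores: linear, convex, and
    maximized exactly by putting weight on the most separating features."""

    name = "class_separation"

    def __init__(self, X: LabeledMatrix):
        self.c = feature_relevance_scores(X)
        self._hess = np.full(self.c.size, EPS_HESSIAN)

    def _check(self, w):
        w = np.asarray(w, dtype=float)
        if w.shape != self.c.shape:
            raise ValueError(f"weight length {w.shape} != N={self.c.size}")
        return w

    def value(self, w) -> float:
        return float(-(self.c @ self._check(w)))

    def __call__(self, w) -> LossEval:
        w = self._check(w)
        return LossEval(float(-(self.c @ w)), -self.c.copy(), self._hess.copy())


def get_loss(name: str, X: LabeledMatrix):
    """Loss factory; ``name`` in {"logistic", "class_separation"}."""
    if name == "logistic":
        return LogisticLoss(X)
    if name == "class_separation":
        return ClassSeparationLoss(X)
    raise ValueError(f"unknown loss {name!r}; expected one of {LOSS_NAMES}")


def logistic_loss(w, X: LabeledMatrix) -> LossEval:
    return LogisticLoss(X)(w)


def class_separation_loss(w, X: LabeledMatrix) -> LossEval:
    return ClassSeparationLoss(X)(w)


def finite_difference_check(loss, w, h: float = 1e-6) -> float:
    """Max abs deviation between the analytic gradient and central finite
    differences; test oracle for gradient implementations.

    ``loss`` is a loss object (from :func:`get_loss`) or any object with
    ``value(w)`` and ``__call__(w) -> LossEval``.
    """
    if h <= 0:
        raise ValueError("h must be positive")
    w = np.asarray(w, dtype=float)
    grad = loss(w).gradient
    fd = np.empty_like(grad)
    for i in range(w.size):
        wp, wm = w.copy(), w.copy()
        wp[i] += h
        wm[i] -= h
        fd[i] = (loss.value(wp) - loss.value(wm)) / (2 * h)
    return float(np.max(np.abs(grad - fd)))
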