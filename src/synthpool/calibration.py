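"""Beta calibration of classifier probabilities.

Boosted trees do not emit well-calibrated probabilities, and training with
minority-class weights distorts them further. The three-parameter beta
calibration family

    mu(p) = 1 / (1 + 1 / (exp(c) * p^a * (1 - p)^(-b)))

is fitted by maximum likelihood as a logistic regression on the features
(ln p, -ln(1 - p)); (a, b, c) = (1, 1, 0) is the identity map. When the
unconstrained fit yields a negative a or b, the corresponding feature is
dropped and the model refitted so the map stays monotone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: probabilities are clipped to [EPS, 1-EPS] before the log features
EPS = 1e-6


@dataclass(frozen=True)
class BetaCalibrationMap:
    """Fitted beta-calibration parameters for one (binary or OVR) class."""

    a: float
    b: float
    c: float

    def __post_init__(self):
        if self.a < 0 or self.b < 0:
            raise ValueError("beta calibration requires a >= 0 and b >= 0")

    def __call__(self, p):
        p = np.clip(np.asarray(p, dtype=float), EPS, 1.0 - EPS)
        z = self.c + self.a * np.log(p) - self.b * np.log1p(-p)
        return 1.0 / (1.0 + np.exp(-z))

    def to_tuple(self):
        return (self.a, self.b, self.c)


IDENTITY_MAP = BetaCalibrationMap(1.0, 1.0, 0.0)


def _logistic_mle(X, y, max_iter=200, tol=1e-12):
    """Newton-Raphson MLE of an unpenalized logistic fit (intercept last).

    Solved exactly (to gradient norm ``tol``) so the intercept score
    equation holds and mean calibrated probability matches the base rate on
    the fitting sample. A tiny ridge stabilizes collinear feature sets; the
    step is damped when the likelihood is near-separable.
    """
    n, p = X.shape
    beta = np.zeros(p)
    ridge = 1e-10
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -35.0, 35.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu)
        if np.linalg.norm(grad) < tol * n:
            break
        W = mu * (1.0 - mu)
        H = (X * W[:, None]).T @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        norm = np.linalg.norm(step)
        if norm > 25.0:  # separable direction: damp
            step *= 25.0 / norm
        beta = beta + step
    return beta


def fit_beta_calibration(raw_probs, labels) -> BetaCalibrationMap:
    """Fit a beta-calibration map by maximum likelihood.

    Parameters
    ----------
    raw_probs : array-like of float
        Uncalibrated predicted probabilities of the positive class.
    labels : array-like of {0, 1}
        Observed outcomes on the same (held-out) rows.
    """
    p = np.clip(np.asarray(raw_probs, dtype=float), EPS, 1.0 - EPS)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError("raw_probs and labels must have equal length")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present to fit calibration")

    if np.ptp(p) < 1e-12:
        # constant scores carry no ranking information: intercept-only map
        # returning the observed base rate
        base = float(y.mean())
        base = min(max(base, EPS), 1.0 - EPS)
        return BetaCalibrationMap(0.0, 0.0, float(np.log(base / (1.0 - base))))

    lnp = np.log(p)
    ln1mp = -np.log1p(-p)
    ones = np.ones_like(p)
    a, b, c = _logistic_mle(np.column_stack([lnp, ln1mp, ones]), y)
    if a < 0:
        b, c = _logistic_mle(np.column_stack([ln1mp, ones]), y)
        a = 0.0
    elif b < 0:
        a, c = _logistic_mle(np.column_stack([lnp, ones]), y)
        b = 0.0
    if a < 0 or b < 0:
        # no monotone non-decreasing member fits: constant base-rate map
        base = min(max(float(y.mean()), EPS), 1.0 - EPS)
        a, b, c = 0.0, 0.0, float(np.log(base / (1.0 - base)))
    return BetaCalibrationMap(float(a), float(b), float(c))


def apply_calibration(maps, raw_probs) -> np.ndarray:
    """Calibrate per-class probabilities and renormalize rows to sum to 1.

    ``maps`` is a sequence of one-vs-rest :class:`BetaCalibrationMap`, one per
    class (column of ``raw_probs``). For two classes a single map may be
    given; it is applied to the second (positive) column and complemented.
    """
    P = np.atleast_2d(np.asarray(raw_probs, dtype=float))
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("raw class probabilities must sum to 1 per row")
    if not isinstance(maps, (list, tuple)):
        maps = [maps]
    if P.shape[1] == 2 and len(maps) == 1:
        pos = maps[0](P[:, 1])
        out = np.column_stack([1.0 - pos, pos])
    else:
        if len(maps) != P.shape[1]:
            raise ValueError("need one calibration map per class column")
        out = np.column_stack([m(P[:, k]) for k, m in enumerate(maps)])
    total = out.sum(axis=1, keepdims=True)
    return out / total
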