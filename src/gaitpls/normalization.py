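"""Box-Cox normalization of the improvement outcome.

The improvement outcome is normalized with the log-family Box-Cox power
transform t(y) = ((y + s)^lambda - 1) / lambda (log(y + s) in the
lambda -> 0 limit). Because improvements can be negative, a shift
s = eps - min(y) (eps = 1 when any value is nonpositive, else 0) makes the
data positive before transforming; the shift is recorded so the transform
is invertible and reportable. Lambda maximizes the Box-Cox profile
log-likelihood, optimized by gradient ascent with an analytic gradient
and step halving.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["BoxCoxTransformer", "fit_boxcox", "apply_boxcox", "invert_boxcox"]

_LAMBDA_ZERO = 1e-10


def _power_transform(z: np.ndarray, lam: float) -> np.ndarray:
    """((z^lam - 1)/lam, continuous log limit at lam = 0). Requires z > 0."""
    if abs(lam) < _LAMBDA_ZERO:
        return np.log(z)
    return (np.power(z, lam) - 1.0) / lam


def _power_transform_dlam(z: np.ndarray, lam: float) -> np.ndarray:
    """d/dlam of the power transform; limit (log z)^2 / 2 at lam = 0."""
    logz = np.log(z)
    if abs(lam) < _LAMBDA_ZERO:
        return 0.5 * logz**2
    zl = np.power(z, lam)
    return (zl * (lam * logz - 1.0) + 1.0) / lam**2


def _profile_loglik(z: np.ndarray, lam: float) -> float:
    """Per-observation profile log-likelihood (constants dropped).

    llf(lam)/n = (lam - 1) * mean(log z) - 0.5 * log(var(t(lam))).
    """
    t = _power_transform(z, lam)
    var = t.var()
    if var <= 0:
        return -np.inf
    return (lam - 1.0) * float(np.mean(np.log(z))) - 0.5 * float(np.log(var))


def _profile_grad(z: np.ndarray, lam: float) -> float:
    t = _power_transform(z, lam)
    dt = _power_transform_dlam(z, lam)
    tc = t - t.mean()
    var = float(np.mean(tc**2))
    cov = float(np.mean(tc * (dt - dt.mean())))
    return float(np.mean(np.log(z))) - cov / var


class BoxCoxTransformer(BaseEstimator, TransformerMixin):
    """Two-parameter Box-Cox normalizer fitted by gradient ascent.

    Parameters
    ----------
    eps : float, default 1.0
        Positivity margin: the fitted shift is ``eps - min(y)`` when any
        value is nonpositive, else 0.
    max_iter : int, default 500
        Iteration cap for the gradient ascent.
    tol : float, default 1e-6
        Convergence threshold on the lambda update magnitude.

    Attributes
    ----------
    lambda_ : float
        Fitted power parameter.
    shift_ : float
        Shift added before the power transform (percent units of y).
    loglik_ : float
        Per-observation profile log-likelihood at ``lambda_``.
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, eps: float = 1.0, max_iter: int = 500, tol: float = 1e-6):
        self.eps = eps
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None) -> "BoxCoxTransformer":
        v = np.asarray(X, dtype=float).ravel()
        if v.size < 3:
            raise ValueError(f"need at least 3 values to fit, got {v.size}")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite values in input")
        if np.ptp(v) == 0:
            raise ValueError("all input values are equal; transform undefined")
        self.shift_ = float(self.eps - v.min()) if v.min() <= 0 else 0.0
        z = v + self.shift_

        lam = 1.0
        step = 0.25
        cur = _profile_loglik(z, lam)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            g = _profile_grad(z, lam)
            moved = False
            while step >= 1e-14:
                cand = lam + step * g
                val = _profile_loglik(z, cand)
                if val > cur:
                    if abs(cand - lam) < self.tol:
                        lam, cur = cand, val
                        converged = True
                    else:
                        lam, cur = cand, val
                        step *= 1.5
                    moved = True
                    break
                step *= 0.5
            if not moved:  # no improving step: at a (numerical) optimum
                converged = True
            if converged:
                break
        if not converged:
            warnings.warn(
                "Box-Cox gradient ascent did not converge "
                f"within {self.max_iter} iterations (lambda={lam:.4g})",
                RuntimeWarning,
            )
        self.lambda_ = float(lam)
        self.loglik_ = float(cur)
        self.n_iter_ = it
        self.converged_ = converged
        return self

    def transform(self, X) -> np.ndarray:
        v = np.asarray(X, dtype=float)
        z = v + self.shift_
        if np.any(z <= 0):
            bad = float(v.ravel()[np.argwhere(z.ravel() <= 0)[0, 0]])
            raise ValueError(
                f"value {bad} is outside the transform domain "
                f"(y + shift must be > 0, shift={self.shift_})"
            )
        return _power_transform(z, self.lambda_)

    def inverse_transform(self, T) -> np.ndarray:
        t = np.asarray(T, dtype=float)
        if abs(self.lambda_) < _LAMBDA_ZERO:
            return np.exp(t) - self.shift_
        inner = self.lambda_ * t + 1.0
        if np.any(inner <= 0):
            bad = float(t.ravel()[np.argwhere(inner.ravel() <= 0)[0, 0]])
            raise ValueError(
                f"transformed value {bad} is outside the inverse domain "
                f"(lambda*t + 1 must be > 0, lambda={self.lambda_})"
            )
        return np.power(inner, 1.0 / self.lambda_) - self.shift_

    def to_dict(self) -> dict:
        """Serializable summary for run reports."""
        return {
            "lambda": self.lambda_,
            "shift": self.shift_,
            "loglik": self.loglik_,
            "iterations": self.n_iter_,
            "converged": self.converged_,
        }


def fit_boxcox(y, **config) -> BoxCoxTransformer:
    """Fit a :class:`BoxCoxTransformer` to ``y`` (thin functional wrapper)."""
    return BoxCoxTransformer(**config).fit(y)


def apply_boxcox(y, transform: BoxCoxTransformer) -> np.ndarray:
    return transform.transform(y)


def invert_boxcox(t, transform: BoxCoxTransformer) -> np.ndarray:
    return transform.inverse_transform(t)
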