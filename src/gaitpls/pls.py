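"""Partial least squares regression with a fixed, small component count.

PLSR projects the predictors onto successive orthogonal score vectors that
maximize covariance with the outcome, then regresses the outcome on those
scores. With a single outcome the iterative (NIPALS-type) algorithm is
deterministic: each weight vector is the normalized covariance X'y of the
deflated predictors with the deflated outcome, so no random initialization
or power iteration is involved. The component count is fixed by
configuration (4 throughout this pipeline) rather than tuned.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["PLSRegressor", "fit_plsr", "predict_plsr", "first_score_r2"]


def _pls_fit_core(Xc: np.ndarray, yc: np.ndarray, k: int):
    """NIPALS-style univariate-outcome PLS on pre-centered data.

    Returns (W, P, Q, T, coef, n_effective). Stops early when the
    covariance of the deflated X with the deflated y underflows.
    """
    n, p = Xc.shape
    W = np.empty((p, k))
    P = np.empty((p, k))
    Q = np.empty(k)
    T = np.empty((n, k))
    Xr = Xc.copy()
    yr = yc.copy()
    scale = max(np.abs(Xc).max(initial=0.0), 1.0) * max(np.abs(yc).max(initial=0.0), 1.0)
    tol = 1e-13 * scale
    a = 0
    for a in range(k):
        c = Xr.T @ yr
        nc = np.sqrt(c @ c)
        if nc <= tol:
            break
        w = c / nc
        t = Xr @ w
        tt = t @ t
        if tt <= tol * tol:
            break
        pl = (Xr.T @ t) / tt
        q = (yr @ t) / tt
        W[:, a] = w
        P[:, a] = pl
        Q[a] = q
        T[:, a] = t
        Xr -= np.outer(t, pl)
        yr -= q * t
    else:
        a = k
    if a == 0:
        return W[:, :0], P[:, :0], Q[:0], T[:, :0], np.zeros(p), 0
    W, P, Q, T = W[:, :a], P[:, :a], Q[:a], T[:, :a]
    # coefficients in the original column basis: B = W (P'W)^-1 q
    coef = W @ np.linalg.solve(P.T @ W, Q)
    return W, P, Q, T, coef, a


class PLSRegressor(RegressorMixin, BaseEstimator):
    """Single-outcome partial least squares regression.

    Parameters
    ----------
    n_components : int, default 4
        Number of latent components. Must satisfy
        ``n_components <= min(n_samples - 1, n_features)``.
    scale : bool, default False
        If True, z-score the predictor columns before fitting. The default
        keeps columns on their native scale (all thickness predictors share
        units of mm), with only mean-centering applied internally.

    Attributes
    ----------
    x_mean_, x_std_ : per-column centering (and, if ``scale``, scaling).
    y_mean_ : float
    x_weights_, x_loadings_ : (p, k) arrays
    y_loadings_ : (k,) array
    x_scores_ : (n, k) training score matrix; columns mutually orthogonal.
    coef_ : (p,) coefficients on the (centered/scaled) original columns.
    n_components_ : effective number of extracted components (may be less
        than requested if the residual covariance underflows).
    """

    def __init__(self, n_components: int = 4, scale: bool = False):
        self.n_components = n_components
        self.scale = scale

    def _validate(self, X, y=None, fitting=False):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        if y is None:
            return X
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != X.shape[0]:
            raise ValueError(f"X has {X.shape[0]} rows but y has {len(y)} values")
        if not np.all(np.isfinite(y)):
            raise ValueError("y contains non-finite values")
        return X, y

    def fit(self, X, y) -> "PLSRegressor":
        X, y = self._validate(X, y, fitting=True)
        n, p = X.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        k = int(self.n_components)
        if k < 1:
            raise ValueError("n_components must be >= 1")
        bound = min(n - 1, p)
        if k > bound:
            raise ValueError(
                f"n_components={k} exceeds min(n_samples - 1, n_features) = {bound}"
            )
        self.x_mean_ = X.mean(axis=0)
        Xc = X - self.x_mean_
        if self.scale:
            sd = Xc.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0  # constant columns: leave centered at zero
            self.x_std_ = sd
            Xc = Xc / sd
        else:
            self.x_std_ = np.ones(p)
        self.y_mean_ = float(y.mean())
        yc = y - self.y_mean_
        W, P, Q, T, coef, a = _pls_fit_core(Xc, yc, k)
        self.x_weights_ = W
        self.x_loadings_ = P
        self.y_loadings_ = Q
        self.x_scores_ = T
        self.coef_ = coef
        self.n_components_ = a
        self.n_features_in_ = p
        return self

    def _check_columns(self, X):
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns, model was fitted with {self.n_features_in_}"
            )

    def predict(self, X) -> np.ndarray:
        X = self._validate(X)
        self._check_columns(X)
        Xc = (X - self.x_mean_) / self.x_std_
        return self.y_mean_ + Xc @ self.coef_

    def transform(self, X) -> np.ndarray:
        """Project onto the latent components (scores)."""
        X = self._validate(X)
        self._check_columns(X)
        Xc = (X - self.x_mean_) / self.x_std_
        # scores via the direct projection R = W (P'W)^-1
        R = self.x_weights_ @ np.linalg.inv(self.x_loadings_.T @ self.x_weights_)
        return Xc @ R

    def first_score_r2(self, X, y) -> float:
        """Squared Pearson correlation of ``y`` with the first-component scores."""
        X, y = self._validate(X, y)
        self._check_columns(X)
        if self.n_components_ < 1:
            raise ValueError("model extracted no components")
        scores1 = ((X - self.x_mean_) / self.x_std_) @ self.x_weights_[:, 0]
        if scores1.std() == 0 or y.std() == 0:
            raise ValueError("zero-variance scores or outcome; correlation undefined")
        r = np.corrcoef(scores1, y)[0, 1]
        return float(r * r)

    def to_dict(self) -> dict:
        """JSON-serializable model summary."""
        return {
            "n_components": self.n_components,
            "n_components_effective": self.n_components_,
            "scale": self.scale,
            "x_mean": self.x_mean_.tolist(),
            "y_mean": self.y_mean_,
            "x_weights": self.x_weights_.tolist(),
            "x_loadings": self.x_loadings_.tolist(),
            "y_loadings": self.y_loadings_.tolist(),
            "coefficients": self.coef_.tolist(),
        }


def fit_plsr(X, y, k: int = 4, scale: bool = False) -> PLSRegressor:
    """Fit a :class:`PLSRegressor` with ``k`` components (functional wrapper)."""
    return PLSRegressor(n_components=k, scale=scale).fit(X, y)


def predict_plsr(model: PLSRegressor, X_new) -> np.ndarray:
    return model.predict(X_new)


def first_score_r2(model: PLSRegressor, X, y) -> float:
    return model.first_score_r2(X, y)
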