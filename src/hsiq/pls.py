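"""Minimal single-target partial least squares (PLS1) regression.

Wavelength selection scores tens of thousands of candidate band subsets,
each with a cross-validated latent-variable fit; this module provides a
deliberately lean NIPALS PLS1 whose per-fit cost is a handful of small
matrix products.  It reproduces the standard algorithm: components are
extracted as w = X'y/||X'y||, scores t = Xw, with rank-one deflation of X
and y, and the final coefficients map centred X to centred y.
"""

from __future__ import annotations

import numpy as np


class PLS1:
    """PLS regression with one response and ``n_components`` latent variables.

    Components stop early if the residual covariance collapses, so the
    effective number of components never exceeds the data rank.
    """

    def __init__(self, n_components: int = 5):
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        self.n_components = n_components

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PLS1":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if y.size != n:
            raise ValueError("X and y disagree on sample count")
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = y.mean()
        Xc = X - self.x_mean_
        yc = y - self.y_mean_

        a = min(self.n_components, p, max(1, n - 1))
        W = np.empty((p, a))
        P = np.empty((p, a))
        q = np.empty(a)
        Xd, yd = Xc.copy(), yc.copy()
        k = 0
        for _ in range(a):
            w = Xd.T @ yd
            norm = np.linalg.norm(w)
            if norm <= 1e-12:
                break
            w /= norm
            t = Xd @ w
            tt = t @ t
            if tt <= 1e-12:
                break
            p_load = (Xd.T @ t) / tt
            q_load = (yd @ t) / tt
            W[:, k], P[:, k], q[k] = w, p_load, q_load
            Xd -= np.outer(t, p_load)
            yd -= q_load * t
            k += 1
        if k == 0:
            # X carries no covariance with y: predict the mean
            self.coef_ = np.zeros(p)
        else:
            Wk, Pk, qk = W[:, :k], P[:, :k], q[:k]
            self.coef_ = Wk @ np.linalg.solve(Pk.T @ Wk, qk)
        self.n_components_fitted_ = k
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.y_mean_ + (X - self.x_mean_) @ self.coef_
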