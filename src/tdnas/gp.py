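"""Gaussian-process surrogate over encoded configurations.

A zero-effort, fully deterministic GP regressor: isotropic squared
exponential kernel, empirical-mean prior, and kernel hyperparameters
chosen by maximizing the log marginal likelihood over a small
lengthscale grid (multiples of the median pairwise distance). The
discrete encoding can repeat inputs, so a jitter term on the diagonal
absorbs conflicting targets; it escalates tenfold on factorization
failure up to 1e-2.

The posterior ``f(x) | data ~ Normal(mu_n(x), sigma_n^2(x))`` feeds the
expected-improvement acquisition.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["GPSurrogate", "sq_exp_kernel"]

LENGTHSCALE_GRID = (0.1, 0.2, 0.5, 1.0, 2.0)


def sq_exp_kernel(A: np.ndarray, B: np.ndarray, lengthscale: float,
                  signal_var: float) -> np.ndarray:
    """Squared-exponential kernel matrix k(a,b) = s^2 exp(-||a-b||^2 / (2 l^2))."""
    d2 = np.sum(A**2, axis=1)[:, None] + np.sum(B**2, axis=1)[None, :] \
        - 2.0 * A @ B.T
    np.maximum(d2, 0.0, out=d2)
    return signal_var * np.exp(-0.5 * d2 / lengthscale**2)


class GPSurrogate(BaseEstimator, RegressorMixin):
    """Deterministic GP regression for the search surrogate.

    Parameters
    ----------
    jitter : float
        Initial diagonal regularization; escalates x10 up to
        ``max_jitter`` if the Cholesky factorization fails.
    lengthscale_grid : tuple of float
        Candidate lengthscales as multiples of the median pairwise
        distance between training inputs; the one maximizing the log
        marginal likelihood is kept.
    max_jitter : float
        Escalation ceiling; beyond it fitting raises.

    Attributes
    ----------
    X_ : ndarray of shape (n, d)
        Training inputs (encoded configurations).
    y_ : ndarray of shape (n,)
        Training targets (judgment-criterion values).
    mean_ : float
        Prior mean: empirical mean of targets (0 with no data).
    lengthscale_ : float
        Selected kernel lengthscale.
    signal_var_ : float
        Kernel signal variance (target variance; 1.0 fallback when the
        targets are constant or absent).
    jitter_ : float
        Jitter actually used.
    log_marginal_likelihood_ : float
        At the selected lengthscale.
    """

    def __init__(self, jitter: float = 1e-6,
                 lengthscale_grid: tuple = LENGTHSCALE_GRID,
                 max_jitter: float = 1e-2,
                 fixed_lengthscale: float | None = None):
        self.jitter = jitter
        self.lengthscale_grid = lengthscale_grid
        self.max_jitter = max_jitter
        self.fixed_lengthscale = fixed_lengthscale

    # -- fitting --------------------------------------------------------

    def fit(self, X, y=None) -> "GPSurrogate":
        X = np.atleast_2d(np.asarray(X, dtype=float)) if np.size(X) else \
            np.empty((0, 1))
        y = np.asarray(y, dtype=float).ravel() if y is not None else \
            np.empty(0)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        if y.size and not np.all(np.isfinite(y)):
            raise ValueError("targets must be finite")
        self.X_, self.y_ = X, y
        n = X.shape[0]
        self.mean_ = float(y.mean()) if n else 0.0
        var = float(y.var()) if n else 0.0
        self.signal_var_ = var if var > 1e-12 else 1.0

        if n == 0:
            self.lengthscale_ = 1.0
            self.jitter_ = self.jitter
            self.log_marginal_likelihood_ = 0.0
            self._chol = None
            self._alpha = None
            return self

        med = self._median_distance(X)
        if self.fixed_lengthscale is not None:
            scales = (self.fixed_lengthscale,)
        else:
            scales = tuple(m * med for m in self.lengthscale_grid)
        best = None
        for ls in scales:
            out = self._try_factor(X, y - self.mean_, ls)
            if out is None:
                continue
            lml, chol, alpha, jit = out
            if best is None or lml > best[0]:
                best = (lml, ls, chol, alpha, jit)
        if best is None:
            raise FloatingPointError(
                "kernel factorization failed at every lengthscale even at "
                f"jitter {self.max_jitter}")
        (self.log_marginal_likelihood_, self.lengthscale_,
         self._chol, self._alpha, self.jitter_) = best
        return self

    @staticmethod
    def _median_distance(X: np.ndarray) -> float:
        n = X.shape[0]
        if n < 2:
            return 1.0
        d2 = np.sum(X**2, axis=1)[:, None] + np.sum(X**2, axis=1)[None, :] \
            - 2.0 * X @ X.T
        iu = np.triu_indices(n, 1)
        d = np.sqrt(np.maximum(d2[iu], 0.0))
        d = d[d > 0]
        return float(np.median(d)) if d.size else 1.0

    def _try_factor(self, X, yc, lengthscale):
        K = sq_exp_kernel(X, X, lengthscale, self.signal_var_)
        n = X.shape[0]
        jit = self.jitter
        while jit <= self.max_jitter:
            try:
                chol = cho_factor(K + jit * np.eye(n), lower=True)
            except LinAlgError:
                jit *= 10.0
                continue
            alpha = cho_solve(chol, yc)
            logdet = 2.0 * np.sum(np.log(np.diag(chol[0])))
            lml = -0.5 * yc @ alpha - 0.5 * logdet - 0.5 * n * np.log(2 * np.pi)
            return float(lml), chol, alpha, jit
        return None

    # -- prediction -----------------------------------------------------

    def predict(self, X, return_std: bool = False):
        """Posterior mean (and optionally standard deviation) at query points."""
        mu, var = self.posterior(X)
        return (mu, np.sqrt(var)) if return_std else mu

    def posterior(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and variance at query points.

        Variance is clamped at 0 after floating-point cancellation.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self._chol is None:
            mu = np.full(X.shape[0], self.mean_)
            return mu, np.full(X.shape[0], self.signal_var_)
        if X.shape[1] != self.X_.shape[1]:
            raise ValueError(
                f"query dimension {X.shape[1]} != training dimension "
                f"{self.X_.shape[1]}")
        Ks = sq_exp_kernel(X, self.X_, self.lengthscale_, self.signal_var_)
        mu = self.mean_ + Ks @ self._alpha
        v = cho_solve(self._chol, Ks.T)
        var = self.signal_var_ - np.einsum("ij,ji->i", Ks, v)
        return mu, np.maximum(var, 0.0)

    def posterior_point(self, x) -> tuple[float, float]:
        mu, var = self.posterior(np.atleast_2d(x))
        return float(mu[0]), float(var[0])

    def summary(self) -> dict:
        """Compact state description for the trial log."""
        return {
            "n": int(self.X_.shape[0]) if hasattr(self, "X_") else 0,
            "lengthscale": getattr(self, "lengthscale_", None),
            "signal_var": getattr(self, "signal_var_", None),
            "jitter": getattr(self, "jitter_", None),
        }
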