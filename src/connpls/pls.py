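"""Multi-response partial least squares regression (SIMPLS) and an RBF-kernel variant.

PLS projects a feature block ``X (n x N)`` and a label block ``Y (n x M)``
onto ``d`` latent components chosen to maximize the covariance between
successive pairs of X- and Y-scores,

    X = T P' + E        Y = U Q' + F,

and from the decomposition derives an explicit coefficient matrix ``B``
(N x M) with ``Y_hat = X B + intercept``, which is what prediction for unseen
subjects uses.  The extraction here is SIMPLS (de Jong 1993): weight vectors
are taken directly from the successively deflated cross-covariance
``X0' Y0``, the X-scores are orthonormal, and at full rank the fit coincides
with ordinary least squares.  Blocks are column-centered only — no variance
scaling is applied to either block; the intercept restores the offsets.

``d`` is the model's only hyper-parameter; the pipeline default is 50.  The
kernel variant replaces the linear inner product with an RBF kernel
``k(x, x') = exp(-||x - x'||^2 / (2 sigma^2))`` on a double-centered Gram
matrix (default ``sigma = 150``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PLS", "PLSResults", "KernelPLS", "KernelPLSResults",
           "pls_fit", "pls_predict", "kernel_pls_fit", "kernel_pls_predict",
           "DEFAULT_D", "DEFAULT_SIGMA"]

DEFAULT_D = 50
DEFAULT_SIGMA = 150.0

# singular values below this fraction of the first are treated as numerical
# rank exhaustion and stop the extraction early
_RANK_RTOL = 1e-12


def _as_2d(a, name):
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2:
        raise ValueError(f"{name} must be 1-D or 2-D")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains missing or non-finite values")
    return a


class PLS:
    """Multi-response partial least squares model.

    Parameters
    ----------
    endog : array, shape (n, M)
        Label block Y; binary labels enter as 0/1 numeric columns.
    exog : array, shape (n, N)
        Feature block X (e.g. vectorized connectivity edges).

    Examples
    --------
    >>> res = PLS(Y, X).fit(d=50)
    >>> y_hat = res.predict(X_new)
    """

    def __init__(self, endog, exog):
        self.endog = _as_2d(endog, "endog")
        self.exog = _as_2d(exog, "exog")
        if self.endog.shape[0] != self.exog.shape[0]:
            raise ValueError("endog and exog have different numbers of rows")
        if self.exog.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        ysd = self.endog.std(axis=0)
        dead = np.flatnonzero(ysd == 0)
        if dead.size:
            raise ValueError(f"zero-variance label column(s) {dead.tolist()}")

    @classmethod
    def from_dataframe(cls, data, y_cols, x_cols=None):
        """Build from a DataFrame; ``x_cols`` defaults to all non-label columns."""
        y_cols = list(y_cols)
        if x_cols is None:
            x_cols = [c for c in data.columns if c not in set(y_cols)]
        return cls(data[y_cols].to_numpy(float), data[list(x_cols)].to_numpy(float))

    @property
    def nobs(self) -> int:
        return self.exog.shape[0]

    def fit(self, d: int = DEFAULT_D, strict_d: bool = True) -> "PLSResults":
        """Fit with ``d`` latent components via SIMPLS.

        ``d`` must not exceed ``min(n - 1, N)``.  If the cross-covariance is
        numerically exhausted before ``d`` components (rank-deficient data),
        extraction stops early and the effective ``d`` shrinks, with a warning.
        Set ``strict_d=False`` to silently cap an over-large ``d`` instead of
        raising.
        """
        X, Y = self.exog, self.endog
        n, N = X.shape
        M = Y.shape[1]
        dmax = min(n - 1, N)
        if d < 1:
            raise ValueError("d must be >= 1")
        if d > dmax:
            if strict_d:
                raise ValueError(f"d={d} exceeds min(n-1, N)={dmax}")
            warnings.warn(f"d={d} capped at min(n-1, N)={dmax}", stacklevel=2)
            d = dmax
        if d > 200:
            warnings.warn("estimation accuracy is known to deteriorate for d > 200",
                          stacklevel=2)

        x_mean = X.mean(axis=0)
        y_mean = Y.mean(axis=0)
        X0 = X - x_mean
        Y0 = Y - y_mean

        Cov = X0.T @ Y0  # N x M cross-covariance (unnormalized)
        T = np.empty((n, d))
        U = np.empty((n, d))
        P = np.empty((N, d))
        Q = np.empty((M, d))
        W = np.empty((N, d))
        V = np.empty((N, d))  # orthonormal basis of X-loadings, for deflation

        s0 = None
        a = 0
        for i in range(d):
            ui, si, vti = np.linalg.svd(Cov, full_matrices=False)
            if s0 is None:
                s0 = si[0]
            if si[0] <= _RANK_RTOL * max(s0, 1.0):
                warnings.warn(
                    f"cross-covariance numerically exhausted after {i} components; "
                    f"shrinking d from {d} to {i}", stacklevel=2)
                break
            r = ui[:, 0]
            c = vti[0, :]
            t = X0 @ r
            t -= t.mean()
            normt = np.linalg.norm(t)
            if normt <= _RANK_RTOL * max(np.linalg.norm(X0), 1.0):
                warnings.warn(
                    f"degenerate X-score at component {i}; shrinking d to {i}",
                    stacklevel=2)
                break
            t /= normt
            T[:, a] = t
            P[:, a] = X0.T @ t
            Q[:, a] = si[0] * c / normt
            W[:, a] = r / normt
            U[:, a] = Y0 @ Q[:, a]

            # deflate Cov against the orthonormalized X-loading basis
            v = P[:, a].copy()
            if a > 0:
                v -= V[:, :a] @ (V[:, :a].T @ v)
                v -= V[:, :a] @ (V[:, :a].T @ v)  # reorthogonalize
            v /= np.linalg.norm(v)
            V[:, a] = v
            Cov = Cov - np.outer(v, v @ Cov)
            if a > 0:  # Y-scores orthogonal to preceding X-scores
                U[:, a] -= T[:, :a] @ (T[:, :a].T @ U[:, a])
            a += 1

        T, U, P, Q, W = T[:, :a], U[:, :a], P[:, :a], Q[:, :a], W[:, :a]
        B = W @ Q.T
        intercept = y_mean - x_mean @ B
        return PLSResults(model=self, d=a, x_mean=x_mean, y_mean=y_mean,
                          T_scores=T, U_scores=U, P_load=P, Q_load=Q,
                          W_weights=W, B=B, intercept=intercept)


@dataclass
class PLSResults:
    """Fitted SIMPLS decomposition and the derived linear predictor.

    ``B`` (N x M) and ``intercept`` (M,) give ``predict(X) = X B + intercept``;
    the score/loading matrices expose the latent structure (``T_scores`` has
    orthonormal columns).
    """

    model: PLS
    d: int
    x_mean: np.ndarray
    y_mean: np.ndarray
    T_scores: np.ndarray
    U_scores: np.ndarray
    P_load: np.ndarray
    Q_load: np.ndarray
    W_weights: np.ndarray
    B: np.ndarray
    intercept: np.ndarray

    def predict(self, X_new) -> np.ndarray:
        X_new = _as_2d(X_new, "X_new")
        if X_new.shape[1] != self.B.shape[0]:
            raise ValueError(
                f"X_new has {X_new.shape[1]} columns, model was trained with "
                f"{self.B.shape[0]}")
        return X_new @ self.B + self.intercept

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.exog)

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    @property
    def mse(self) -> float:
        return float(np.mean(self.resid ** 2))

    def summary(self) -> str:
        n, N = self.model.exog.shape
        M = self.model.endog.shape[1]
        var_y = self.model.endog.var(axis=0)
        r2 = 1.0 - self.resid.var(axis=0) / var_y
        lines = [
            "Partial Least Squares Regression (SIMPLS)",
            "=" * 45,
            f"n obs:            {n}",
            f"n features (N):   {N}",
            f"n labels (M):     {M}",
            f"latent comps (d): {self.d}",
            f"training MSE:     {self.mse:.6g}",
            "-" * 45,
            "label   train R^2",
        ]
        for j in range(M):
            lines.append(f"  y{j:<4d}  {r2[j]:8.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# kernel variant

def rbf_kernel(A, B, sigma: float) -> np.ndarray:
    """Gaussian kernel matrix k(a, b) = exp(-||a-b||^2 / (2 sigma^2))."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    d2 = (np.sum(A ** 2, axis=1)[:, None] + np.sum(B ** 2, axis=1)[None, :]
          - 2.0 * A @ B.T)
    np.maximum(d2, 0.0, out=d2)
    return np.exp(-d2 / (2.0 * sigma ** 2))


class KernelPLS:
    """Kernel PLS in the dual (Gram-matrix) formulation.

    Fitting extracts score pairs from the double-centered training Gram
    matrix by the dual NIPALS iteration, which with a linear kernel
    reproduces primal PLS predictions; prediction applies the dual
    coefficients to the consistently centered cross-kernel of new points
    against the retained training inputs.  The default kernel is RBF with
    ``sigma = 150``; ``kernel="linear"`` exists mainly for verification.
    """

    def __init__(self, endog, exog, sigma: float = DEFAULT_SIGMA, kernel: str = "rbf"):
        self.endog = _as_2d(endog, "endog")
        self.exog = _as_2d(exog, "exog")
        if self.endog.shape[0] != self.exog.shape[0]:
            raise ValueError("endog and exog have different numbers of rows")
        if kernel not in ("rbf", "linear"):
            raise ValueError(f"unknown kernel {kernel!r}")
        if kernel == "rbf" and sigma <= 0:
            raise ValueError("sigma must be > 0")
        self.sigma = float(sigma)
        self.kernel = kernel

    def _gram(self, A, B) -> np.ndarray:
        if self.kernel == "linear":
            return np.asarray(A, float) @ np.asarray(B, float).T
        return rbf_kernel(A, B, self.sigma)

    def fit(self, d: int = DEFAULT_D, strict_d: bool = True,
            max_iter: int = 500, tol: float = 1e-12) -> "KernelPLSResults":
        n = self.exog.shape[0]
        if d < 1:
            raise ValueError("d must be >= 1")
        if d > n - 1:
            if strict_d:
                raise ValueError(f"d={d} exceeds n-1={n - 1}")
            d = n - 1
        K = self._gram(self.exog, self.exog)
        row_mean = K.mean(axis=0)
        grand = K.mean()
        Kc = K - row_mean[None, :] - row_mean[:, None] + grand
        y_mean = self.endog.mean(axis=0)
        Y0 = self.endog - y_mean

        Kres = Kc.copy()
        Yres = Y0.copy()
        T = np.empty((n, d))
        U = np.empty((n, d))
        a = 0
        for _ in range(d):
            # t is the dominant eigenvector of Kres @ Yres @ Yres.T;
            # power iteration, one step exact when M = 1
            u = Yres[:, int(np.argmax(Yres.var(axis=0)))].copy()
            if np.linalg.norm(u) <= 1e-14:
                warnings.warn(f"label block exhausted; shrinking d to {a}",
                              stacklevel=2)
                break
            t_old = np.zeros(n)
            for _it in range(max_iter):
                t = Kres @ u
                nt = np.linalg.norm(t)
                if nt <= 1e-14:
                    break
                t /= nt
                c = Yres.T @ t
                u = Yres @ c
                if np.linalg.norm(t - t_old) < tol:
                    break
                t_old = t
            nt = np.linalg.norm(Kres @ u)
            if nt <= 1e-12 * max(np.linalg.norm(Kc), 1.0):
                warnings.warn(f"kernel matrix exhausted after {a} components; "
                              f"shrinking d from {d} to {a}", stacklevel=2)
                break
            T[:, a] = t
            U[:, a] = u
            # deflate: project both blocks off the extracted score
            Kres = Kres - np.outer(t, t @ Kres)
            Kres = Kres - np.outer(Kres @ t, t)
            Yres = Yres - np.outer(t, t @ Yres)
            a += 1
        T, U = T[:, :a], U[:, :a]
        # dual regression coefficients: Yhat = Kc_test @ alpha + y_mean
        middle = np.linalg.solve(T.T @ Kc @ U, T.T @ Y0)
        alpha = U @ middle
        return KernelPLSResults(model=self, dual_coef=alpha, y_mean=y_mean,
                                train_row_mean=row_mean, train_grand_mean=grand,
                                d=a)


@dataclass
class KernelPLSResults:
    """Dual coefficients of a fitted kernel PLS; retains the training inputs
    through ``model`` for prediction-time kernel evaluation."""

    model: KernelPLS
    dual_coef: np.ndarray  # n x M, acts on the centered cross-kernel
    y_mean: np.ndarray
    train_row_mean: np.ndarray
    train_grand_mean: float
    d: int

    def predict(self, X_new) -> np.ndarray:
        X_new = _as_2d(X_new, "X_new")
        Kx = self.model._gram(X_new, self.model.exog)  # m x n
        Kxc = (Kx - Kx.mean(axis=1, keepdims=True)
               - self.train_row_mean[None, :] + self.train_grand_mean)
        return Kxc @ self.dual_coef + self.y_mean


# ---------------------------------------------------------------------------
# functional conveniences

def pls_fit(X, Y, d: int = DEFAULT_D, **kw) -> PLSResults:
    return PLS(Y, X).fit(d=d, **kw)


def pls_predict(results: PLSResults, X_new) -> np.ndarray:
    return results.predict(X_new)


def kernel_pls_fit(X, Y, d: int = DEFAULT_D, sigma: float = DEFAULT_SIGMA,
                   kernel: str = "rbf") -> KernelPLSResults:
    return KernelPLS(Y, X, sigma=sigma, kernel=kernel).fit(d=d, strict_d=False)


def kernel_pls_predict(results: KernelPLSResults, X_new) -> np.ndarray:
    return results.predict(X_new)
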