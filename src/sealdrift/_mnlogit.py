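"""Weighted ridge-penalized multinomial logistic regression.

Small, self-contained Newton solver used by the ABC model-choice step: the
number of predictors (summary statistics) and classes (demographic scenarios)
is tiny, so the full Hessian is formed explicitly and also provides the
asymptotic covariance for delta-method confidence intervals on predicted
class probabilities.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MultinomialLogit"]


class MultinomialLogit:
    """Fit P(class | x) with a softmax-linear model, baseline = last class.

    Parameters
    ----------
    ridge : float
        L2 penalty on all coefficients (intercepts included); keeps the
        problem well-posed when classes are separable.
    """

    def __init__(self, n_classes: int, ridge: float = 1e-3, max_iter: int = 100,
                 tol: float = 1e-8):
        if n_classes < 2:
            raise ValueError("need >= 2 classes")
        self.n_classes = n_classes
        self.ridge = ridge
        self.max_iter = max_iter
        self.tol = tol
        self.coef_: np.ndarray | None = None  # (d+1, K-1)
        self.cov_: np.ndarray | None = None   # ((d+1)(K-1),)^2

    # -- internals ---------------------------------------------------------
    @staticmethod
    def _augment(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.hstack([np.ones((X.shape[0], 1)), X])

    def _probs(self, Xa: np.ndarray, B: np.ndarray) -> np.ndarray:
        eta = np.hstack([Xa @ B, np.zeros((Xa.shape[0], 1))])
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        return p / p.sum(axis=1, keepdims=True)

    def _penalized_loglik(self, Xa, y, w, B) -> float:
        p = self._probs(Xa, B)
        ll = np.sum(w * np.log(np.clip(p[np.arange(len(y)), y], 1e-300, None)))
        return ll - 0.5 * self.ridge * np.sum(B * B)

    # -- API ---------------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None):
        Xa = self._augment(X)
        y = np.asarray(y, dtype=int)
        m, d1 = Xa.shape
        K = self.n_classes
        w = np.ones(m) if weights is None else np.asarray(weights, dtype=float)
        w = w * (m / w.sum())  # normalize so ridge strength is scale-stable
        Y = np.zeros((m, K - 1))
        sel = y < K - 1
        Y[np.arange(m)[sel], y[sel]] = 1.0

        B = np.zeros((d1, K - 1))
        ll = self._penalized_loglik(Xa, y, w, B)
        for _ in range(self.max_iter):
            P = self._probs(Xa, B)
            G = Xa.T @ (w[:, None] * (Y - P[:, : K - 1])) - self.ridge * B
            H = np.zeros((d1 * (K - 1), d1 * (K - 1)))
            for j in range(K - 1):
                for k in range(j, K - 1):
                    wjk = w * (P[:, j] * ((j == k) - P[:, k]))
                    block = -(Xa * wjk[:, None]).T @ Xa
                    H[j * d1:(j + 1) * d1, k * d1:(k + 1) * d1] = block
                    if k != j:
                        H[k * d1:(k + 1) * d1, j * d1:(j + 1) * d1] = block
            H -= self.ridge * np.eye(d1 * (K - 1))
            step = np.linalg.solve(H, G.reshape(-1, order="F")).reshape(
                (d1, K - 1), order="F")
            # damped Newton: backtrack until the penalized log-likelihood improves
            scale = 1.0
            for _ in range(30):
                Bn = B - scale * step
                lln = self._penalized_loglik(Xa, y, w, Bn)
                if lln >= ll - 1e-12:
                    break
                scale *= 0.5
            moved = abs(lln - ll)
            B, ll = Bn, lln
            if moved < self.tol:
                break
        self.coef_ = B
        # asymptotic covariance = inverse negative penalized Hessian at optimum
        P = self._probs(Xa, B)
        H = np.zeros((d1 * (K - 1), d1 * (K - 1)))
        for j in range(K - 1):
            for k in range(j, K - 1):
                wjk = w * (P[:, j] * ((j == k) - P[:, k]))
                block = (Xa * wjk[:, None]).T @ Xa
                H[j * d1:(j + 1) * d1, k * d1:(k + 1) * d1] = block
                if k != j:
                    H[k * d1:(k + 1) * d1, j * d1:(j + 1) * d1] = block
        H += self.ridge * np.eye(d1 * (K - 1))
        self.cov_ = np.linalg.inv(H)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Xa = self._augment(X)
        return self._probs(Xa, self.coef_)

    def predict_proba_ci(self, x: np.ndarray, level: float = 0.95):
        """Class probabilities at one point with delta-method intervals."""
        from scipy.stats import norm

        Xa = self._augment(np.atleast_2d(x))
        pi = self._probs(Xa, self.coef_)[0]
        d1, Km1 = self.coef_.shape
        z = norm.ppf(0.5 + level / 2.0)
        lo = np.empty_like(pi)
        hi = np.empty_like(pi)
        for c in range(self.n_classes):
            # gradient of pi_c wrt vec(B) (column-major, matching cov_)
            g = np.zeros((d1, Km1))
            for j in range(Km1):
                ind = 1.0 if c == j else 0.0
                g[:, j] = pi[c] * (ind - pi[j]) * Xa[0]
            gv = g.reshape(-1, order="F")
            se = float(np.sqrt(max(gv @ self.cov_ @ gv, 0.0)))
            lo[c] = max(pi[c] - z * se, 0.0)
            hi[c] = min(pi[c] + z * se, 1.0)
        return pi, lo, hi
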