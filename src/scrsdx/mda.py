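"""Mixture discriminant analysis (MDA).

Each class is modelled as a Gaussian mixture (default 3 subclasses per
class) with a single covariance matrix shared across all subclasses of
all classes, fitted by EM with known class labels (responsibilities are
computed only within a point's own class).  With one subclass per class
the model collapses to classical LDA: Gaussian class densities with a
pooled covariance.

scikit-learn has no shared-covariance per-class mixture classifier, so
this is implemented here with the usual EM safeguards: k-means
initialization, ridge regularization of the pooled covariance, a
log-likelihood tolerance and an iteration cap.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import KMeans

__all__ = ["MDAClassifier"]


class MDAClassifier(ClassifierMixin, BaseEstimator):
    """Per-class Gaussian mixtures with shared covariance."""

    def __init__(self, n_subclasses: int = 3, max_iter: int = 100,
                 tol: float = 1e-6, reg: float = 1e-6, random_state=None):
        self.n_subclasses = n_subclasses
        self.max_iter = max_iter
        self.tol = tol
        self.reg = reg
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _log_gauss(self, X: np.ndarray, means: np.ndarray) -> np.ndarray:
        """log N(x; mu_r, Sigma) for all points x rows of X, all rows mu_r."""
        d = X.shape[1]
        diff_logdet = 2.0 * np.sum(np.log(np.diag(self._chol[0])))
        out = np.empty((X.shape[0], means.shape[0]))
        for r, mu in enumerate(means):
            dx = X - mu
            sol = cho_solve(self._chol, dx.T).T
            maha = np.einsum("ij,ij->i", dx, sol)
            out[:, r] = -0.5 * (maha + diff_logdet + d * np.log(2 * np.pi))
        return out

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, d = X.shape
        rng = np.random.RandomState(
            self.random_state if self.random_state is not None else 0
        )

        means, owners = [], []
        self.priors_ = np.zeros(len(self.classes_))
        weights = []
        for c in range(len(self.classes_)):
            Xc = X[y_idx == c]
            self.priors_[c] = len(Xc) / n
            r = min(self.n_subclasses, len(Xc))
            if r > 1:
                km = KMeans(n_clusters=r, n_init=3,
                            random_state=rng.randint(2**31)).fit(Xc)
                mu = km.cluster_centers_
                w = np.bincount(km.labels_, minlength=r).astype(float)
                w /= w.sum()
            else:
                mu = Xc.mean(axis=0, keepdims=True)
                w = np.array([1.0])
            means.append(mu)
            weights.append(w)
            owners.extend([c] * r)
        self.means_ = np.vstack(means)
        self.weights_ = weights
        self.owner_ = np.asarray(owners)

        prev_ll = -np.inf
        for _ in range(self.max_iter):
            # pooled covariance from current responsibilities
            self._update_cov(X, y_idx)
            log_g = self._log_gauss(X, self.means_)
            resp = np.zeros((n, self.means_.shape[0]))
            ll = 0.0
            for c in range(len(self.classes_)):
                rows = np.flatnonzero(y_idx == c)
                cols = np.flatnonzero(self.owner_ == c)
                lg = log_g[np.ix_(rows, cols)] + np.log(self.weights_[c] + 1e-300)
                m = lg.max(axis=1, keepdims=True)
                p = np.exp(lg - m)
                tot = p.sum(axis=1, keepdims=True)
                resp[np.ix_(rows, cols)] = p / tot
                ll += float(np.sum(m.ravel() + np.log(tot.ravel())))
            # M step
            for c in range(len(self.classes_)):
                rows = np.flatnonzero(y_idx == c)
                cols = np.flatnonzero(self.owner_ == c)
                rk = resp[np.ix_(rows, cols)]
                nk = rk.sum(axis=0) + 1e-12
                self.weights_[c] = nk / nk.sum()
                self.means_[cols] = (rk.T @ X[rows]) / nk[:, None]
            self._resp = resp
            if abs(ll - prev_ll) < self.tol * max(1.0, abs(prev_ll)):
                break
            prev_ll = ll
        self._update_cov(X, y_idx)
        return self

    def _update_cov(self, X, y_idx):
        n, d = X.shape
        if not hasattr(self, "_resp"):
            # initial pooled within-subclass covariance from hard assignment
            cov = np.zeros((d, d))
            for r, mu in enumerate(self.means_):
                rows = np.flatnonzero(y_idx == self.owner_[r])
                dx = X[rows] - mu
                cov += dx.T @ dx / len(self.means_)
            cov /= max(n, 1)
        else:
            cov = np.zeros((d, d))
            for r, mu in enumerate(self.means_):
                w = self._resp[:, r]
                dx = X - mu
                cov += (dx * w[:, None]).T @ dx
            cov /= n
        cov += self.reg * np.eye(d) * max(np.trace(cov) / d, 1.0)
        self._chol = cho_factor(cov, lower=True)
        self.covariance_ = cov

    def predict_proba(self, X):
        X = np.asarray(X, float)
        log_g = self._log_gauss(X, self.means_)
        scores = np.full((X.shape[0], len(self.classes_)), -np.inf)
        for c in range(len(self.classes_)):
            cols = np.flatnonzero(self.owner_ == c)
            lg = log_g[:, cols] + np.log(self.weights_[c] + 1e-300)
            m = lg.max(axis=1)
            scores[:, c] = (
                np.log(self.priors_[c] + 1e-300)
                + m + np.log(np.exp(lg - m[:, None]).sum(axis=1))
            )
        m = scores.max(axis=1, keepdims=True)
        p = np.exp(scores - m)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
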