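"""EM fitting of a Gaussian mixture over per-sample curve summaries.

Functional trait mapping classifies samples into latent genotype classes by
fitting a mixture model with expectation-maximization.  Here the mixture is
a full-covariance Gaussian over low-dimensional curve-summary vectors
(e.g. per-genotype interaction coefficients).  Initialization is
k-means++-style seeding with a caller-supplied seed; a component whose
variance collapses triggers a fresh restart (new derived seed, at most
five) before giving up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import multivariate_normal
from sklearn.base import BaseEstimator

from .errors import ComponentCollapseError, ValidationError

COLLAPSE_VAR = 1e-12
REG_COVAR = 1e-10
MAX_RESTARTS = 5


@dataclass
class MixtureFit:
    """Converged EM state: weights on the simplex, per-component parameters,
    responsibilities, and the (non-decreasing) log-likelihood trace."""

    K: int
    means: np.ndarray  # (K, d)
    covariances: np.ndarray  # (K, d, d)
    weights: np.ndarray  # (K,)
    responsibilities: np.ndarray  # (n, K)
    loglik_trace: np.ndarray

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def _kmeanspp_centers(X: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = [X[rng.integers(n)]]
    for _ in range(1, K):
        d2 = np.min(
            [np.sum((X - c) ** 2, axis=1) for c in centers], axis=0
        )
        total = d2.sum()
        if total <= 0:
            centers.append(X[rng.integers(n)])
            continue
        centers.append(X[rng.choice(n, p=d2 / total)])
    return np.asarray(centers)


class CurveGaussianMixture(BaseEstimator):
    """Full-covariance Gaussian mixture fitted by EM.

    Parameters
    ----------
    n_components : int
    tol : float
        Stop when the log-likelihood improves by less than this.
    max_iter : int
    random_state : int
        Seeds k-means++ initialization; restarts derive new seeds from it.

    Attributes
    ----------
    weights_, means_, covariances_, responsibilities_, loglik_trace_
    """

    def __init__(self, n_components=2, tol=1e-8, max_iter=500, random_state=0):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def _e_step(self, X, weights, means, covs):
        n, K = X.shape[0], self.n_components
        log_p = np.empty((n, K))
        for k in range(K):
            log_p[:, k] = np.log(weights[k]) + multivariate_normal.logpdf(
                X, means[k], covs[k], allow_singular=False
            )
        m = log_p.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_p - m).sum(axis=1))
        resp = np.exp(log_p - lse[:, None])
        return resp, float(lse.sum())

    def _run_once(self, X: np.ndarray, seed: int):
        n, d = X.shape
        K = self.n_components
        rng = np.random.default_rng(seed)
        centers = _kmeanspp_centers(X, K, rng)
        # hard-assignment M step to get initial parameters
        assign = np.argmin(
            ((X[:, None, :] - centers[None, :, :]) ** 2).sum(-1), axis=1
        )
        resp = np.zeros((n, K))
        resp[np.arange(n), assign] = 1.0
        trace = []
        weights = means = covs = None
        for it in range(self.max_iter):
            nk = resp.sum(axis=0)
            if np.any(nk < 1e-10):
                return None, None  # empty component: restart
            weights = nk / n
            means = (resp.T @ X) / nk[:, None]
            covs = np.empty((K, d, d))
            for k in range(K):
                Xc = X - means[k]
                covs[k] = (resp[:, k][:, None] * Xc).T @ Xc / nk[k]
                covs[k].flat[:: d + 1] += REG_COVAR
                if np.any(np.diag(covs[k]) < COLLAPSE_VAR):
                    return None, None  # collapsed component: restart
            resp, ll = self._e_step(X, weights, means, covs)
            trace.append(ll)
            if it > 0 and trace[-1] - trace[-2] < self.tol:
                break
        return (
            MixtureFit(
                K=K, means=means, covariances=covs, weights=weights,
                responsibilities=resp, loglik_trace=np.asarray(trace),
            ),
            trace,
        )

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.n_components < 1:
            raise ValidationError("n_components must be >= 1")
        if X.shape[0] < 5 * self.n_components:
            raise ValidationError(
                f"{X.shape[0]} rows cannot support {self.n_components} components "
                "(need >= 5 per component)"
            )
        for r in range(MAX_RESTARTS + 1):
            seed = int(np.random.default_rng([int(self.random_state) % (2**31), r]).integers(2**31))
            fit, trace = self._run_once(X, seed)
            if fit is not None:
                self.weights_ = fit.weights
                self.means_ = fit.means
                self.covariances_ = fit.covariances
                self.responsibilities_ = fit.responsibilities
                self.loglik_trace_ = fit.loglik_trace
                self.fit_ = fit
                self.n_restarts_ = r
                return self
        raise ComponentCollapseError(
            f"mixture component collapsed in all {MAX_RESTARTS + 1} starts"
        )

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        resp, _ = self._e_step(X, self.weights_, self.means_, self.covariances_)
        return resp

    def predict(self, X):
        return np.argmax(self.predict_proba(X), axis=1)

    def score(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        _, ll = self._e_step(X, self.weights_, self.means_, self.covariances_)
        return ll


def em_mixture_fit(observations, K: int, seed: int = 0) -> MixtureFit:
    """Fit a K-component Gaussian mixture to curve-summary rows by EM."""
    est = CurveGaussianMixture(n_components=K, random_state=seed)
    est.fit(observations)
    return est.fit_
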