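"""Unsupervised Gaussian mixture fitting with minimum-message-length selection.

A complex cell object is re-encoded as a 2-D point cloud and modelled as a
mixture of Gaussians, one per hidden cell.  The number of cells is unknown, so
model selection is built into EM: the M-step weight update is penalized as

    w_m  ∝  max(0, n_m − n_par/2),        n_m = Σ_i r_im,

(n_par = 5 free parameters for a 2-D component with full covariance), which
annihilates components that do not pay for their own description length.  A
component is also annihilated when its support n_m drops below 2·n_par points:
with fewer points than twice its parameter count a component can collapse onto
a handful of outliers with near-singular covariance, which the message-length
penalty (vanishing as w_m → 0) does not guard against.  EM
is run component-wise — one component updated at a time with incremental
renormalization — which lets the surviving components absorb the probability
mass of a dying neighbour instead of getting trapped.  After convergence the
weakest component is forcibly removed and EM resumed, down to one component;
the model minimizing the message length

    L(Θ) = (n_par/2) Σ_{m: w_m>0} log(N w_m / 12)
           + (C_nz/2) log(N/12) + C_nz (n_par+1)/2 − log p(Y|Θ)

is returned, so the fitted component count can only be at or below the
initial count.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["MMLGaussianMixture", "initial_mixture"]

_N_PAR = 5          # free parameters per 2-D full-covariance component
_LOG2PI = math.log(2.0 * math.pi)


def _component_logpdf(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    a, b, c, d = cov[0, 0], cov[0, 1], cov[1, 0], cov[1, 1]
    det = a * d - b * c
    det = max(det, 1e-300)
    inv = np.array([[d, -b], [-c, a]]) / det
    diff = X - mean
    quad = (diff[:, 0] ** 2 * inv[0, 0]
            + 2.0 * diff[:, 0] * diff[:, 1] * inv[0, 1]
            + diff[:, 1] ** 2 * inv[1, 1])
    return -0.5 * (quad + math.log(det)) - _LOG2PI


def _weighted_moments(X, r, ridge):
    n = r.sum()
    mean = (r @ X) / n
    diff = X - mean
    cov = (diff * r[:, None]).T @ diff / n
    cov[0, 0] += ridge
    cov[1, 1] += ridge
    return mean, cov


def initial_mixture(X: np.ndarray, centers: np.ndarray, ridge: float = 1e-4):
    """Hard-assignment initialization from candidate centres.

    Each point joins its nearest centre (Euclidean); a component's initial
    mean/covariance are the sample moments of its points and its weight the
    point fraction.  Centres that attract no points are dropped.
    Returns (weights, means, covariances, log_likelihood).
    """
    X = np.asarray(X, dtype=np.float64)
    centers = np.atleast_2d(np.asarray(centers, dtype=np.float64))
    if len(X) < 5 * len(centers):
        raise ValueError("need at least 5 points per candidate centre")
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    assign = d2.argmin(axis=1)
    weights, means, covs = [], [], []
    for m in range(len(centers)):
        sel = assign == m
        n_m = int(sel.sum())
        if n_m == 0:
            continue  # empty component: dropped before EM
        r = np.ones(n_m)
        if n_m < 3:
            mean = X[sel].mean(axis=0)
            cov = np.eye(2) * max(ridge, 0.3)
        else:
            mean, cov = _weighted_moments(X[sel], r, ridge)
        weights.append(n_m / len(X))
        means.append(mean)
        covs.append(cov)
    weights = np.array(weights)
    means = np.array(means)
    covs = np.array(covs)
    logp = np.stack([math.log(w) + _component_logpdf(X, mu, cv)
                     for w, mu, cv in zip(weights, means, covs)])
    from scipy.special import logsumexp

    loglik = float(logsumexp(logp, axis=0).sum())
    return weights, means, covs, loglik


class MMLGaussianMixture:
    """Gaussian mixture with message-length model selection.

    Parameters
    ----------
    max_iter : int
        Maximum component-wise EM sweeps per candidate model.
    tol : float
        Convergence threshold on the relative message-length change.
    ridge : float
        Diagonal regularizer added to every covariance update.
    min_components : int
        Smallest component count explored during forced annihilation.
    patience : int
        Stop exploring smaller models after the message length has worsened
        this many consecutive times (the optimum is unimodal in practice).
    """

    def __init__(self, max_iter: int = 500, tol: float = 1e-5,
                 ridge: float = 1e-4, min_components: int = 1,
                 patience: int = 4):
        self.max_iter = max_iter
        self.tol = tol
        self.ridge = ridge
        self.min_components = min_components
        self.patience = patience

    # minimal sklearn-style parameter plumbing
    def get_params(self, deep: bool = True) -> dict:
        return {"max_iter": self.max_iter, "tol": self.tol, "ridge": self.ridge,
                "min_components": self.min_components, "patience": self.patience}

    def set_params(self, **params) -> "MMLGaussianMixture":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- internals ---------------------------------------------------------

    def _message_length(self, weights, loglik, n):
        nz = weights[weights > 0]
        c_nz = len(nz)
        return (0.5 * _N_PAR * np.sum(np.log(n * nz / 12.0))
                + 0.5 * c_nz * math.log(n / 12.0)
                + 0.5 * c_nz * (_N_PAR + 1) - loglik)

    def _cem_sweeps(self, X, weights, means, covs):
        """Run component-wise EM until the message length stabilizes.

        Returns (weights, means, covs, loglik, msglen, history).
        """
        n = len(X)
        c = len(weights)
        weights = weights.copy()
        means = means.copy()
        covs = covs.copy()
        logp = np.stack([_component_logpdf(X, means[m], covs[m]) for m in range(c)])

        # Bookkeeping for O(n)-per-component sweeps: keep *unnormalized*
        # component masses ``mass`` (the MML-penalized responsibility sums)
        # and A_i = Σ_j mass_j · q_j(y_i) with q_j the scaled component pdf;
        # then w_j = mass_j / Σ mass and r_mi = mass_m q_m(y_i) / A_i.
        def rebuild(weights, mass=None):
            M = logp + np.log(np.maximum(weights, 1e-300))[:, None]
            off = M.max(axis=0)
            dens_u = np.where(weights[:, None] > 0, np.exp(logp - off), 0.0)
            if mass is None:
                mass = weights * n
            A = mass @ dens_u
            return dens_u, off, mass, A

        dens_u, off, mass, A = rebuild(weights)
        prev_L = np.inf
        history = []
        for _ in range(self.max_iter):
            for m in range(c):
                if mass[m] <= 0:
                    continue
                r = mass[m] * dens_u[m] / np.maximum(A, 1e-300)
                n_m = r.sum()
                new_mass_m = max(0.0, n_m - 0.5 * _N_PAR)
                # a component also needs at least as many points of support as
                # it has free parameters, else it can collapse onto outliers
                if new_mass_m <= 0 or n_m < 2 * _N_PAR:
                    # annihilate: remaining components absorb its mass share
                    A = A - mass[m] * dens_u[m]
                    mass[m] = 0.0
                    dens_u[m] = 0.0
                    continue
                if n_m < 1e-6:
                    continue
                means[m], covs[m] = _weighted_moments(X, r, self.ridge)
                logp[m] = _component_logpdf(X, means[m], covs[m])
                new_row = np.exp(logp[m] - off)
                A = A + new_mass_m * new_row - mass[m] * dens_u[m]
                dens_u[m] = new_row
                mass[m] = new_mass_m
            total = mass.sum()
            if total <= 0:
                break
            weights = mass / total
            dens_u, off, mass, A = rebuild(weights, mass)  # refresh offsets
            loglik = float((np.log(np.maximum(A / total, 1e-300)) + off).sum())
            L = self._message_length(weights, loglik, n)
            history.append(L)
            if np.isfinite(prev_L) and abs(prev_L - L) < self.tol * abs(prev_L):
                prev_L = L
                break
            prev_L = L
        total = mass.sum()
        if total <= 0:
            return (np.empty(0), np.empty((0, 2)), np.empty((0, 2, 2)),
                    -np.inf, np.inf, history)
        weights = mass / total
        loglik = float((np.log(np.maximum(A / total, 1e-300)) + off).sum())
        live = weights > 0
        return (weights[live], means[live], covs[live], loglik,
                self._message_length(weights, loglik, n), history)

    # -- API ---------------------------------------------------------------

    def fit(self, X, weights_init=None, means_init=None, covariances_init=None):
        """Fit the mixture, exploring component counts downward from init.

        When no initialization is given a single-component fit is produced.
        """
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2)")
        n = len(X)
        if means_init is None:
            means_init = X.mean(axis=0)[None, :]
        means = np.atleast_2d(np.asarray(means_init, dtype=np.float64)).copy()
        c0 = len(means)
        if weights_init is None:
            weights = np.full(c0, 1.0 / c0)
        else:
            weights = np.asarray(weights_init, dtype=np.float64).copy()
            weights = weights / weights.sum()
        if covariances_init is None:
            covs = np.array([np.cov(X.T) + self.ridge * np.eye(2)] * c0)
        else:
            covs = np.asarray(covariances_init, dtype=np.float64).copy()

        best = None
        worse = 0
        self.message_length_history_ = []
        while True:
            weights, means, covs, loglik, msglen, hist = self._cem_sweeps(
                X, weights, means, covs)
            self.message_length_history_.append(hist)
            if len(weights) == 0:
                break
            if best is None or msglen < best[4]:
                best = (weights, means, covs, loglik, msglen)
                worse = 0
            else:
                worse += 1
            if len(weights) <= self.min_components or worse >= self.patience:
                break
            # forced annihilation: drop the weakest component and refit
            kill = int(np.argmin(weights))
            keep = np.ones(len(weights), dtype=bool)
            keep[kill] = False
            weights = weights[keep] / weights[keep].sum()
            means = means[keep]
            covs = covs[keep]

        if best is None:  # degenerate data: all components annihilated
            mean = X.mean(axis=0)
            cov = np.cov(X.T) + self.ridge * np.eye(2) if n > 2 else np.eye(2) * self.ridge
            logp = _component_logpdf(X, mean, np.atleast_2d(cov))
            loglik = float(logp.sum())
            best = (np.array([1.0]), mean[None, :], np.atleast_2d(cov)[None],
                    loglik, self._message_length(np.array([1.0]), loglik, n))
        self.weights_, self.means_, self.covariances_, self.log_likelihood_, \
            self.message_length_ = best
        self.n_components_ = len(self.weights_)
        return self

    def _check_fitted(self):
        if not hasattr(self, "weights_"):
            raise RuntimeError("call fit first")

    def score_samples_components(self, X) -> np.ndarray:
        """Log of weighted component densities, shape (n_components, n)."""
        self._check_fitted()
        X = np.asarray(X, dtype=np.float64)
        return np.stack([
            math.log(max(w, 1e-300)) + _component_logpdf(X, mu, cv)
            for w, mu, cv in zip(self.weights_, self.means_, self.covariances_)])

    def predict(self, X) -> np.ndarray:
        """Maximum-responsibility component index per point."""
        return self.score_samples_components(X).argmax(axis=0)

    def score(self, X) -> float:
        from scipy.special import logsumexp

        return float(logsumexp(self.score_samples_components(X), axis=0).mean())


def _responsibility_sums(dens, S):
    """n_m = Σ_i r_im for every component, from scaled densities."""
    safe = np.maximum(S, 1e-300)
    return (dens / safe).sum(axis=1)
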