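"""Soft shape classification in log-Hu feature space.

Particles are classified by expectation-maximization of a full-covariance
Gaussian mixture model over their ``(logH1, logH2)`` features.  Soft
classification assigns each particle a responsibility for every class;
when shape classes are well separated the responsibilities collapse to
0/1 and the classification is effectively hard, while non-distinct shape
continua receive genuinely mixed assignments.  The number of classes is
selected automatically (BIC over a range of K, plus pruning of
negligible-weight components), which is how the class count "reduces to
the correct number" on distinct-shape ensembles.

EM is implemented here directly: the pipeline needs the per-iteration
log-likelihood trace (monotonicity is a contract), bit-identical seeded
refits after pruning, and the N x K responsibility matrix as a first-class
result.  Initialization uses k-means++ seeding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

__all__ = [
    "MixtureModel",
    "Classification",
    "fit_gmm",
    "select_classes",
    "soft_assign",
    "class_summary",
    "bic",
]


@dataclass
class MixtureModel:
    """Fitted Gaussian mixture: weights, means, full covariances."""

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    loglik: float
    ll_history: np.ndarray
    n_iter: int
    seed: int | None = None
    converged: bool = True

    @property
    def K(self) -> int:
        return len(self.weights)

    @property
    def d(self) -> int:
        return self.means.shape[1]


@dataclass
class Classification:
    """Responsibility matrix with per-class totals and fractions."""

    responsibilities: np.ndarray
    class_totals: np.ndarray = field(init=False)
    fractions: np.ndarray = field(init=False)
    hard_labels: np.ndarray = field(init=False)

    def __post_init__(self):
        r = np.asarray(self.responsibilities, dtype=float)
        self.responsibilities = r
        self.class_totals = r.sum(axis=0)
        self.fractions = self.class_totals / r.shape[0]
        self.hard_labels = r.argmax(axis=1)


def _log_gaussian(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = X.shape[1]
    chol = cho_factor(cov, lower=True)
    diff = X - mean
    sol = cho_solve(chol, diff.T).T
    maha = np.sum(diff * sol, axis=1)
    logdet = 2.0 * np.sum(np.log(np.diag(chol[0])))
    return -0.5 * (d * np.log(2 * np.pi) + logdet + maha)


def _log_resp(weights, means, covs, X):
    lp = np.column_stack(
        [np.log(w) + _log_gaussian(X, m, c) for w, m, c in zip(weights, means, covs)]
    )
    norm = logsumexp(lp, axis=1)
    return lp - norm[:, None], norm


def _floor_eigenvalues(cov: np.ndarray, floor: float) -> np.ndarray:
    """Clip covariance eigenvalues from below (regularization floor)."""
    w, v = np.linalg.eigh((cov + cov.T) / 2.0)
    if w[0] >= floor:
        return cov
    return (v * np.maximum(w, floor)) @ v.T


def _m_step(X, resp, reg_cov):
    n, d = X.shape
    nk = resp.sum(axis=0) + 1e-300
    weights = nk / n
    means = (resp.T @ X) / nk[:, None]
    covs = np.empty((len(nk), d, d))
    for k in range(len(nk)):
        diff = X - means[k]
        covs[k] = _floor_eigenvalues(
            (resp[:, k][:, None] * diff).T @ diff / nk[k], reg_cov
        )
    return weights, means, covs


def fit_gmm(
    features: np.ndarray,
    K: int,
    seed: int = 0,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
    reg: float = 1e-6,
) -> MixtureModel:
    """Fit a K-component full-covariance GMM by EM, best of ``n_restarts``.

    ``reg`` scales the covariance floor: ``reg * mean feature variance`` is
    added to every covariance diagonal, bounding eigenvalues away from
    zero.  Convergence is a relative log-likelihood change below ``tol``;
    the log-likelihood trace is retained and is non-decreasing.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if n <= K * d:
        raise ValueError(f"need more than K*d = {K * d} samples, got {n}")
    reg_cov = reg * float(np.mean(np.var(X, axis=0))) + 1e-300

    rng = np.random.default_rng(seed)
    restart_seeds = rng.integers(0, 2**31 - 1, size=n_restarts)
    best: MixtureModel | None = None
    for rs in restart_seeds:
        if K == 1:
            resp = np.ones((n, 1))
        else:
            centers, _ = kmeans_plusplus(X, K, random_state=int(rs))
            labels = np.argmin(
                ((X[:, None, :] - centers[None, :, :]) ** 2).sum(-1), axis=1
            )
            resp = np.zeros((n, K))
            resp[np.arange(n), labels] = 1.0
        weights, means, covs = _m_step(X, resp, reg_cov)
        ll_prev = -np.inf
        history = []
        converged = False
        for it in range(1, max_iter + 1):
            log_r, norm = _log_resp(weights, means, covs, X)
            ll = float(norm.sum())
            history.append(ll)
            if ll - ll_prev <= tol * abs(ll) and it > 1:
                converged = True
                break
            ll_prev = ll
            weights, means, covs = _m_step(X, np.exp(log_r), reg_cov)
        model = MixtureModel(
            weights=weights,
            means=means,
            covariances=covs,
            loglik=history[-1],
            ll_history=np.array(history),
            n_iter=len(history),
            seed=int(rs),
            converged=converged,
        )
        if best is None or model.loglik > best.loglik:
            best = model
    return best


def bic(model: MixtureModel, features: np.ndarray) -> float:
    """Bayesian information criterion (lower is better)."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    k, _ = model.weights.shape[0], model.means.shape
    p = (model.K - 1) + model.K * d + model.K * d * (d + 1) // 2
    _, norm = _log_resp(model.weights, model.means, model.covariances, X)
    return -2.0 * float(norm.sum()) + p * np.log(n)


def select_classes(
    features: np.ndarray,
    K_max: int,
    criterion: str = "bic",
    prune_weight: float = 0.01,
    seed: int = 0,
    **fit_kw,
) -> MixtureModel:
    """Fit a mixture with an automatically selected number of classes.

    ``bic``: fit K = 1..K_max and keep the BIC minimizer.  ``weight_prune``:
    fit at K_max and repeatedly drop components whose weight falls below
    ``prune_weight``, refitting at the reduced K.  Both paths then prune
    any residual negligible components, so on ensembles of distinct shapes
    the class count reduces to the true number.
    """
    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    # K is bounded by the N > K*d identifiability requirement
    K_max = min(K_max, max((n - 1) // d, 1))

    if criterion == "bic":
        models = [fit_gmm(X, k, seed=seed, **fit_kw) for k in range(1, K_max + 1)]
        scores = [bic(m, X) for m in models]
        model = models[int(np.argmin(scores))]
    elif criterion == "weight_prune":
        model = fit_gmm(X, K_max, seed=seed, **fit_kw)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    # prune negligible components and refit at the reduced K
    while model.K > 1 and np.min(model.weights) < prune_weight:
        model = fit_gmm(X, model.K - 1, seed=seed, **fit_kw)
    return model


def soft_assign(model: MixtureModel, features: np.ndarray) -> Classification:
    """Posterior responsibilities of every particle for every class."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != model.d:
        raise ValueError("feature dimensionality does not match the model")
    log_r, _ = _log_resp(model.weights, model.means, model.covariances, X)
    return Classification(np.exp(log_r))


def _weighted_stats(x: np.ndarray, w: np.ndarray):
    tot = w.sum()
    if tot <= 0:
        return np.nan, np.nan
    mean = float(np.sum(w * x) / tot)
    var = float(np.sum(w * (x - mean) ** 2) / tot)
    return mean, np.sqrt(max(var, 0.0))


def class_summary(
    classification: Classification, descriptors: pd.DataFrame
) -> pd.DataFrame:
    """Responsibility-weighted per-class summary table.

    Columns mirror the standard ensemble report: class index ``k`` (1 =
    largest class by total responsibility), effective number ``sigma``,
    fraction, and weighted mean +/- sd of effective diameter and aspect
    ratio.  ``component`` is the original mixture-component index.
    """
    r = classification.responsibilities
    if len(descriptors) != r.shape[0]:
        raise ValueError("descriptor table and responsibilities differ in length")
    d_eff = descriptors["d_eff_nm"].to_numpy(dtype=float)
    ar = descriptors["AR"].to_numpy(dtype=float)
    order = np.argsort(-classification.class_totals, kind="stable")
    rows = []
    for rank, comp in enumerate(order, start=1):
        w = r[:, comp]
        dm, ds = _weighted_stats(d_eff, w)
        am, asd = _weighted_stats(ar, w)
        rows.append(
            {
                "k": rank,
                "component": int(comp),
                "sigma": float(w.sum()),
                "fraction": float(w.sum() / r.shape[0]),
                "diam_mean_nm": dm,
                "diam_sd_nm": ds,
                "AR_mean": am,
                "AR_sd": asd,
            }
        )
    return pd.DataFrame(rows)
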