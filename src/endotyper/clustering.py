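"""Model-based clustering in the latent space.

Gaussian mixtures with full covariances are fitted by expectation-
maximization (best of several restarts by log-likelihood; the per-iteration
log-likelihood trace is retained so the EM monotonicity guarantee is
checkable).  The number of clusters is selected by the Calinski-Harabasz
index (higher = better), cross-checked against the Davies-Bouldin index
(lower = better); k-means serves as the sensitivity clustering method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .errors import ConfigError, DataError, DegenerateDataError, FitError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MixtureParams:
    """Parameters of a k-component Gaussian mixture: weights π, means μ,
    full covariances Σ."""

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        mu = np.asarray(self.means, dtype=float)
        cov = np.asarray(self.covariances, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", mu)
        object.__setattr__(self, "covariances", cov)
        k = w.size
        if mu.shape[0] != k or cov.shape[0] != k or cov.shape[1:] != (mu.shape[1], mu.shape[1]):
            raise DataError("inconsistent mixture parameter shapes")
        if abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
            raise DataError("mixture weights must be non-negative and sum to 1")
        for j in range(k):
            if not np.allclose(cov[j], cov[j].T, atol=1e-9):
                raise DataError(f"covariance {j} not symmetric")
            try:
                np.linalg.cholesky(cov[j])
            except np.linalg.LinAlgError as exc:
                raise DataError(f"covariance {j} not positive-definite") from exc

    @property
    def k(self) -> int:
        return self.weights.size

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureParams":
        return cls(
            weights=np.array(d["weights"], dtype=float),
            means=np.array(d["means"], dtype=float),
            covariances=np.array(d["covariances"], dtype=float),
        )


@dataclass(frozen=True)
class GMMConfig:
    """EM settings: ``n_restarts`` independent initializations are advanced
    ``burn_in`` iterations each, then the best by log-likelihood is run to
    convergence (tolerance on the mean log-likelihood)."""

    n_restarts: int = 10
    max_iter: int = 500
    tol: float = 1e-6
    reg_covar: float = 1e-6
    burn_in: int = 50


@dataclass
class GMMFit:
    """A fitted mixture plus diagnostics of the winning EM run."""

    params: MixtureParams
    mean_loglik: float
    trace: np.ndarray = field(repr=False)
    converged: bool = True
    n_iter: int = 0


def _log_weighted_prob(weights, means, covs, X) -> np.ndarray:
    """n×k matrix of log(π_j) + log N(x | μ_j, Σ_j), batched over components."""
    n, d = X.shape
    chol = np.linalg.cholesky(covs)  # (k, d, d)
    inv_chol = np.linalg.inv(chol)
    diff = X[None, :, :] - means[:, None, :]  # (k, n, d)
    y = diff @ inv_chol.transpose(0, 2, 1)  # batched BLAS
    maha = np.square(y).sum(axis=2)
    logdet = 2.0 * np.sum(np.log(np.diagonal(chol, axis1=1, axis2=2)), axis=1)
    lp = -0.5 * (d * np.log(2.0 * np.pi) + logdet[:, None] + maha)
    return (lp + np.log(weights + 1e-300)[:, None]).T


def _log_prob_matrix(params: MixtureParams, X: np.ndarray) -> np.ndarray:
    return _log_weighted_prob(params.weights, params.means, params.covariances, X)


def posterior_probs(params: MixtureParams, latent) -> np.ndarray:
    """Responsibility matrix: P(component j | point i); rows sum to 1."""
    X = np.asarray(latent, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    lp = _log_prob_matrix(params, X)
    return np.exp(lp - logsumexp(lp, axis=1, keepdims=True))


def _init_params(X: np.ndarray, k: int, rng: np.random.Generator, cfg: GMMConfig):
    """Initialize EM from a short k-means partition (fast, near a basin)."""
    n, d = X.shape
    km = KMeans(n_clusters=k, n_init=1, max_iter=10, random_state=int(rng.integers(2**31)))
    lab = km.fit_predict(X)
    means = km.cluster_centers_.copy()
    base_cov = np.cov(X, rowvar=False, ddof=1).reshape(d, d)
    covs = np.empty((k, d, d))
    weights = np.empty(k)
    for j in range(k):
        grp = X[lab == j]
        weights[j] = max(len(grp), 1) / n
        covs[j] = np.cov(grp, rowvar=False, ddof=1).reshape(d, d) if len(grp) > d else base_cov
        covs[j].flat[:: d + 1] += cfg.reg_covar
    return weights / weights.sum(), means, covs


def _em_iterate(X, state, cfg: GMMConfig, max_iter: int, trace: list, prev: float):
    """Advance EM up to ``max_iter`` iterations; mutates ``trace`` in place."""
    weights, means, covs = state
    n, d = X.shape
    k = weights.size
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lp = _log_weighted_prob(weights, means, covs, X)
        m = lp.max(axis=1)
        norm = m + np.log(np.exp(lp - m[:, None]).sum(axis=1))
        ll = float(norm.mean())
        trace.append(ll)
        resp = np.exp(lp - norm[:, None])
        nk = resp.sum(axis=0) + 10 * np.finfo(float).tiny
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        covs = np.empty((k, d, d))
        for j in range(k):
            diff = X - means[j]
            covs[j] = (resp[:, j][:, None] * diff).T @ diff / nk[j]
            covs[j].flat[:: d + 1] += cfg.reg_covar
        if ll - prev < cfg.tol and np.isfinite(prev):
            converged = True
            break
        prev = ll
    return (weights, means, covs), trace, converged, it, trace[-1]


def fit_gmm(latent, k: int, seed: int = 0, cfg: GMMConfig = GMMConfig()) -> GMMFit:
    """Fit a k-component full-covariance Gaussian mixture by EM.

    ``cfg.n_restarts`` independent initializations are each advanced
    ``cfg.burn_in`` EM iterations; the restart with the highest mean
    log-likelihood is then run to convergence.  The winning run's full
    log-likelihood trace is monotone non-decreasing.  Deterministic under a
    fixed seed.
    """
    X = np.asarray(latent, dtype=float)
    if X.ndim != 2:
        raise DataError("latent must be a 2-D array")
    n = X.shape[0]
    if k < 1 or n <= 10 * k:
        raise ConfigError(f"need k >= 1 and n > 10 k (n={n}, k={k})")
    if not np.all(np.isfinite(X)):
        raise DataError("non-finite values in latent points")
    rng = np.random.default_rng(seed)
    burn = min(cfg.burn_in, cfg.max_iter)
    candidates = []
    for _ in range(cfg.n_restarts):
        try:
            state = _init_params(X, k, rng, cfg)
            res = _em_iterate(X, state, cfg, burn, [], -np.inf)
            candidates.append(res)
        except (np.linalg.LinAlgError, DataError) as exc:
            log.warning("EM restart failed: %s", exc)
    if not candidates:
        raise FitError("all EM restarts failed (singular covariances?)")
    state, trace, conv, it, ll = max(candidates, key=lambda c: c[4])
    if not conv and it < cfg.max_iter:
        state, trace, conv, it2, ll = _em_iterate(
            X, state, cfg, cfg.max_iter - burn, trace, trace[-1]
        )
        it += it2
    weights, means, covs = state
    params = MixtureParams(weights / weights.sum(), means, covs)
    final_ll = float(logsumexp(_log_prob_matrix(params, X), axis=1).mean())
    trace.append(final_ll)
    return GMMFit(
        params=params, mean_loglik=final_ll, trace=np.array(trace), converged=conv, n_iter=it
    )


def hard_labels(params: MixtureParams, latent) -> np.ndarray:
    """Maximum-responsibility assignment (ties go to the lowest index)."""
    return np.argmax(posterior_probs(params, latent), axis=1)


def _check_partition(X: np.ndarray, labels: np.ndarray):
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise DegenerateDataError("need >= 2 non-empty clusters")
    if X.shape[0] <= uniq.size:
        raise DegenerateDataError("need more points than clusters")
    return uniq


def calinski_harabasz(points, labels) -> float:
    """Calinski-Harabasz index [B/(k−1)] / [W/(n−k)]: ratio of between- to
    within-cluster dispersion, scaled by degrees of freedom; higher = better."""
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    uniq = _check_partition(X, labels)
    n, k = X.shape[0], uniq.size
    c = X.mean(axis=0)
    B = 0.0
    W = 0.0
    for u in uniq:
        grp = X[labels == u]
        ci = grp.mean(axis=0)
        B += grp.shape[0] * float(np.sum((ci - c) ** 2))
        W += float(np.sum((grp - ci) ** 2))
    if W == 0:
        raise DegenerateDataError("within-cluster dispersion is zero; index undefined")
    return (B / (k - 1)) / (W / (n - k))


def davies_bouldin(points, labels) -> float:
    """Davies-Bouldin index (1/k) Σ_i max_{j≠i} (s_i+s_j)/d_ij with s the
    mean point-to-centroid distance and d the centroid distance; lower =
    better."""
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    uniq = _check_partition(X, labels)
    k = uniq.size
    cents = np.array([X[labels == u].mean(axis=0) for u in uniq])
    s = np.array(
        [np.mean(np.linalg.norm(X[labels == u] - cents[i], axis=1)) for i, u in enumerate(uniq)]
    )
    score = 0.0
    for i in range(k):
        worst = 0.0
        for j in range(k):
            if i == j:
                continue
            dij = float(np.linalg.norm(cents[i] - cents[j]))
            if dij == 0:
                raise DegenerateDataError("coincident centroids; index undefined")
            worst = max(worst, (s[i] + s[j]) / dij)
        score += worst
    return score / k


@dataclass
class KSelectionResult:
    """Per-k validity indices and the selected cluster count.

    ``selected_k`` maximizes Calinski-Harabasz; ``agreement`` records
    whether Davies-Bouldin independently prefers the same k."""

    table: pd.DataFrame
    selected_k: int
    agreement: bool
    fits: dict[int, GMMFit] = field(default_factory=dict, repr=False)

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["selected"] = (out["k"] == self.selected_k).astype(int)
        return out


def select_k(latent, k_range=range(2, 9), seed: int = 0, cfg: GMMConfig = GMMConfig()) -> KSelectionResult:
    """Fit a GMM for each k, score the hard partitions with both validity
    indices, and select k by maximum Calinski-Harabasz.

    Per-k fit failures are logged and excluded; if the two indices disagree
    the Calinski-Harabasz winner is kept with ``agreement=False``.
    """
    X = np.asarray(latent, dtype=float)
    ks = sorted(k_range)
    if not ks or ks[0] < 2 or ks[-1] > 10:
        raise ConfigError("k_range must lie within [2, 10]")
    rows = []
    fits: dict[int, GMMFit] = {}
    for k in ks:
        try:
            fit = fit_gmm(X, k, seed=seed, cfg=cfg)
            labels = hard_labels(fit.params, X)
            ch = calinski_harabasz(X, labels)
            db = davies_bouldin(X, labels)
        except Exception as exc:  # noqa: BLE001 - per-k failures are recorded
            log.warning("k=%d excluded from selection: %s", k, exc)
            continue
        fits[k] = fit
        rows.append({"k": k, "ch": ch, "db": db})
    if not rows:
        raise FitError("no k in the range could be fitted")
    table = pd.DataFrame(rows)
    selected = int(table.loc[table["ch"].idxmax(), "k"])
    db_best = int(table.loc[table["db"].idxmin(), "k"])
    agreement = selected == db_best
    if not agreement:
        log.warning(
            "cluster-count indices disagree: CH prefers k=%d, DB prefers k=%d; keeping CH",
            selected, db_best,
        )
    return KSelectionResult(table=table, selected_k=selected, agreement=agreement, fits=fits)


def fit_kmeans(latent, k: int, seed: int = 0, n_restarts: int = 10):
    """k-means sensitivity clustering (labels, centroids); best of
    ``n_restarts`` by within-cluster sum of squares."""
    X = np.asarray(latent, dtype=float)
    n = X.shape[0]
    if k < 1 or (k > 1 and n <= 10 * k):
        raise ConfigError(f"need k >= 1 and n > 10 k (n={n}, k={k})")
    if k == 1:
        return np.zeros(n, dtype=int), X.mean(axis=0, keepdims=True)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(X)
    return labels, km.cluster_centers_
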