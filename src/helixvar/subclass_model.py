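"""Conformational subclassing of octapeptide windows.

Invariant vectors are standardized (zero mean, unit sd per column), reduced
with PCA to the smallest number of components explaining a target variance
fraction, and modeled as a mixture of k Gaussians fitted by EM, one
component per conformational subclass.  Each window is assigned to the
subclass with the highest posterior responsibility.  Because consecutive
windows overlap in 7 residues, the same local deformation seen at shifted
positions produces distinct but redundant subclasses; these are detected by
correlating shifted per-position invariant profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

__all__ = [
    "Standardizer",
    "PCModel",
    "MixtureModel",
    "SubclassAssignment",
    "RedundancyGroup",
    "fit_standardizer",
    "fit_pca",
    "fit_gmm",
    "assign",
    "detect_shift_redundancy",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# Standardization


@dataclass
class Standardizer:
    mean: np.ndarray
    sd: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) / self.sd

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, float) * self.sd + self.mean


def fit_standardizer(X: np.ndarray) -> Standardizer:
    """Per-column mean/sd scaler; zero-variance columns get sd 1 (warned)."""
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("standardization needs an (n >= 2, p) matrix")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance column(s); sd set to 1",
                      stacklevel=2)
        sd = np.where(zero, 1.0, sd)
    return Standardizer(mean=mean, sd=sd)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCModel:
    """Full-rank loadings with a retained-component count ``s``.

    ``loadings`` columns are orthonormal; ``explained_variance_fraction``
    covers every component (sums to 1 over the full rank) and is
    non-increasing; ``s`` is the smallest count whose cumulative fraction
    reaches the requested threshold.
    """

    loadings: np.ndarray
    explained_variance_fraction: np.ndarray
    s: int

    def project(self, Z: np.ndarray, n_components: int | None = None) -> np.ndarray:
        k = self.s if n_components is None else n_components
        return np.asarray(Z, float) @ self.loadings[:, :k]

    def reconstruct(self, Y: np.ndarray) -> np.ndarray:
        k = Y.shape[1]
        return np.asarray(Y, float) @ self.loadings[:, :k].T


def fit_pca(Z: np.ndarray, variance_threshold: float = 0.80) -> PCModel:
    """PCA of a standardized matrix, retaining the fewest components whose
    cumulative explained-variance fraction meets ``variance_threshold``."""
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must be in (0, 1]")
    from sklearn.decomposition import PCA

    Z = np.asarray(Z, float)
    pca = PCA(n_components=min(Z.shape), svd_solver="full")
    pca.fit(Z)
    frac = pca.explained_variance_ratio_
    cum = np.cumsum(frac)
    if variance_threshold >= 1.0:
        # s = numerical rank of Z
        s = int(np.sum(pca.explained_variance_ > 1e-10 * pca.explained_variance_[0]))
    else:
        s = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    return PCModel(loadings=pca.components_.T.copy(),
                   explained_variance_fraction=frac.copy(), s=s)


# ---------------------------------------------------------------------------
# Gaussian mixture via EM


@dataclass
class MixtureModel:
    """k-component full-covariance Gaussian mixture in PC space."""

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    log_likelihood_trace: np.ndarray = field(default_factory=lambda: np.array([]))
    converged: bool = False

    @property
    def k(self) -> int:
        return len(self.weights)

    def _component_log_density(self, Y: np.ndarray) -> np.ndarray:
        """(n, k) log N(y | mean_j, cov_j)."""
        Y = np.atleast_2d(np.asarray(Y, float))
        n, s = Y.shape
        out = np.empty((n, self.k))
        for j in range(self.k):
            L = np.linalg.cholesky(self.covariances[j])
            dev = Y - self.means[j]
            sol = solve_triangular(L, dev.T, lower=True)
            out[:, j] = (
                -0.5 * (s * np.log(2 * np.pi) + np.sum(sol**2, axis=0))
                - np.sum(np.log(np.diag(L)))
            )
        return out

    def log_responsibilities(self, Y: np.ndarray) -> np.ndarray:
        lw = np.log(self.weights) + self._component_log_density(Y)
        return lw - logsumexp(lw, axis=1, keepdims=True)

    def predict_proba(self, Y: np.ndarray) -> np.ndarray:
        return np.exp(self.log_responsibilities(Y))

    def total_log_likelihood(self, Y: np.ndarray) -> float:
        lw = np.log(self.weights) + self._component_log_density(Y)
        return float(logsumexp(lw, axis=1).sum())


@dataclass
class SubclassAssignment:
    """Posterior responsibilities and argmax label for one window."""

    subclass_id: int
    posterior: np.ndarray


def _em_once(Y: np.ndarray, k: int, seed: int, tol: float, max_iter: int,
             reg: float) -> MixtureModel:
    from sklearn.cluster import KMeans

    n, s = Y.shape
    labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(Y)
    resp = np.zeros((n, k))
    resp[np.arange(n), labels] = 1.0

    weights = np.full(k, 1.0 / k)
    means = np.zeros((k, s))
    covs = np.stack([np.eye(s)] * k)
    model = MixtureModel(weights, means, covs)
    trace: list[float] = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        # M step
        nk = resp.sum(axis=0) + 1e-300
        model.weights = nk / n
        model.means = (resp.T @ Y) / nk[:, None]
        for j in range(k):
            dev = Y - model.means[j]
            cov = (resp[:, j, None] * dev).T @ dev / nk[j]
            cov.flat[:: s + 1] += reg
            model.covariances[j] = cov
        # E step
        lw = np.log(model.weights) + model._component_log_density(Y)
        norm = logsumexp(lw, axis=1)
        ll = float(norm.sum())
        trace.append(ll)
        resp = np.exp(lw - norm[:, None])
        if np.isfinite(prev) and abs(ll - prev) < tol * abs(prev):
            converged = True
            break
        prev = ll
    model.log_likelihood_trace = np.array(trace)
    model.converged = converged
    return model


def fit_gmm(
    Y: np.ndarray,
    k: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_init: int = 5,
    reg_covar: float = 1e-6,
) -> MixtureModel:
    """Fit a k-component Gaussian mixture by EM.

    Each restart is initialized from seeded k-means hard assignments; the
    restart with the best final log-likelihood is kept.  Covariances carry a
    ridge of ``reg_covar`` on the diagonal so degenerate clusters stay
    positive-definite.  The per-iteration total log-likelihood trace is
    retained on the returned model and is non-decreasing.
    """
    Y = np.asarray(Y, float)
    if Y.ndim != 2:
        raise ValueError("Y must be 2-D")
    n, s = Y.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k * (s + 1):
        raise ValueError(f"need n >= k*(s+1) = {k * (s + 1)} samples, got {n}")
    best: MixtureModel | None = None
    for r in range(n_init):
        m = _em_once(Y, k, seed=seed + r, tol=tol, max_iter=max_iter, reg=reg_covar)
        if best is None or m.log_likelihood_trace[-1] > best.log_likelihood_trace[-1]:
            best = m
    assert best is not None
    return best


def assign(model: MixtureModel, y: np.ndarray) -> SubclassAssignment:
    """Maximum-posterior subclass assignment; ties go to the lowest index."""
    post = model.predict_proba(np.atleast_2d(y))[0]
    return SubclassAssignment(subclass_id=int(np.argmax(post)), posterior=post)


# ---------------------------------------------------------------------------
# Shift-redundancy detection


@dataclass
class RedundancyGroup:
    members: list
    representative: object
    # best (shift, correlation) per ordered member pair
    pair_stats: dict = field(default_factory=dict)


def _shifted_correlation(prof_a: np.ndarray, prof_b: np.ndarray,
                         max_shift: int = 4, min_overlap: int = 3):
    """Best Pearson correlation between two (2, 5) position profiles under
    integer position shifts.  Both rows (d and vol profiles) are shifted
    together and the overlapping columns concatenated; shifts leaving fewer
    than ``min_overlap`` overlapping positions per row are skipped."""
    npos = prof_a.shape[1]
    best = (-np.inf, 0)
    for shift in range(-max_shift, max_shift + 1):
        lo_a, hi_a = max(0, shift), min(npos, npos + shift)
        if hi_a - lo_a < min_overlap:
            continue
        a = prof_a[:, lo_a:hi_a].ravel()
        b = prof_b[:, lo_a - shift : hi_a - shift].ravel()
        if np.std(a) == 0 or np.std(b) == 0:
            corr = 1.0 if np.allclose(a, b) else -np.inf
        else:
            corr = float(np.corrcoef(a, b)[0, 1])
        if corr > best[0]:
            best = (corr, shift)
    return best


def detect_shift_redundancy(
    labels: Sequence,
    invariants: np.ndarray,
    min_members: int = 50,
    corr_threshold: float = 0.95,
    max_shift: int = 4,
    representative_override: Mapping | None = None,
) -> list[RedundancyGroup]:
    """Group subclasses that describe the same deformation at shifted
    positions.

    For every subclass with at least ``min_members`` windows, the mean
    per-position profiles of the five d(i, i+3) distances and five
    tetrahedron volumes are compared pairwise under shifts of up to
    ``max_shift`` positions; pairs whose best shifted correlation reaches
    ``corr_threshold`` are merged into one group.  The representative is
    the largest-membership member unless overridden.
    """
    labels = np.asarray(labels)
    invariants = np.asarray(invariants, float)
    uniq = [u for u in np.unique(labels)]
    profiles, sizes = {}, {}
    for u in uniq:
        mask = labels == u
        if mask.sum() < min_members:
            warnings.warn(f"subclass {u!r} has {int(mask.sum())} members "
                          f"(< {min_members}); excluded from redundancy grouping",
                          stacklevel=2)
            continue
        mean = invariants[mask].mean(axis=0)
        profiles[u] = np.vstack([mean[2:7], mean[11:16]])  # d_i_i3, vol_i_i3
        sizes[u] = int(mask.sum())
    keys = list(profiles)
    parent = {u: u for u in keys}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    pair_stats = {}
    for i, a in enumerate(keys):
        for b in keys[i + 1 :]:
            corr, shift = _shifted_correlation(profiles[a], profiles[b], max_shift)
            pair_stats[(a, b)] = (shift, corr)
            if corr >= corr_threshold:
                parent[find(a)] = find(b)

    groups: dict = {}
    for u in keys:
        groups.setdefault(find(u), []).append(u)
    out = []
    override = dict(representative_override or {})
    for members in groups.values():
        members = sorted(members, key=lambda u: (-sizes[u], str(u)))
        rep = members[0]
        for m in members:
            if m in override.values() or override.get(frozenset(members)) == m:
                rep = m
        stats = {p: s for p, s in pair_stats.items()
                 if p[0] in members and p[1] in members}
        out.append(RedundancyGroup(members=members, representative=rep,
                                   pair_stats=stats))
    return out


# ---------------------------------------------------------------------------
# Serialization


_ARCHIVE_VERSION = 1


def save_model(path, standardizer: Standardizer, pca: PCModel,
               gmm: MixtureModel) -> None:
    """Persist standardizer + PCA + mixture as one versioned .npz archive."""
    np.savez(
        path,
        version=np.array([_ARCHIVE_VERSION]),
        std_mean=standardizer.mean,
        std_sd=standardizer.sd,
        pca_loadings=pca.loadings,
        pca_evr=pca.explained_variance_fraction,
        pca_s=np.array([pca.s]),
        gmm_weights=gmm.weights,
        gmm_means=gmm.means,
        gmm_covs=gmm.covariances,
    )


def load_model(path) -> tuple[Standardizer, PCModel, MixtureModel]:
    with np.load(path) as z:
        if int(z["version"][0]) != _ARCHIVE_VERSION:
            raise ValueError("unsupported model archive version")
        std = Standardizer(mean=z["std_mean"], sd=z["std_sd"])
        pca = PCModel(loadings=z["pca_loadings"],
                      explained_variance_fraction=z["pca_evr"],
                      s=int(z["pca_s"][0]))
        gmm = MixtureModel(weights=z["gmm_weights"], means=z["gmm_means"],
                           covariances=z["gmm_covs"])
    return std, pca, gmm
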