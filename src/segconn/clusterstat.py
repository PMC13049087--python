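"""Sensor-level dependent-samples cluster-based permutation test.

Per-subject band power is compared between Boundary and No-Boundary intervals
with a paired t-test per channel. Supra-threshold channels (two-tailed
p < cluster_alpha) additionally need at least ``min_neighbors`` supra-threshold
neighbors in the channel adjacency; surviving channels are grouped into
connected components split by t sign, each scored by the sum of its member
t-values. The null distribution of the maximum |cluster statistic| is built by
random within-subject condition swaps (sign flips of the paired differences).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from sklearn.base import BaseEstimator

from ._utils import as_rng, check_symmetric_adjacency

__all__ = ["Cluster", "ClusterResult", "ClusterPermutationTest",
           "dependent_t", "find_clusters", "permutation_test"]


@dataclass(frozen=True)
class Cluster:
    channels: tuple
    t_sum: float
    sign: int
    p: float = np.nan


@dataclass(frozen=True)
class ClusterResult:
    clusters: tuple
    t_values: np.ndarray
    n_permutations: int
    cluster_alpha: float
    alpha: float
    null_max: np.ndarray = field(repr=False, default=None)

    @property
    def significant(self):
        return tuple(c for c in self.clusters if c.p < self.alpha)


def dependent_t(data):
    """Paired t per channel for (subjects, channels, 2) condition means.

    Zero-variance differences give t = +/-inf (sign of the mean difference).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3 or data.shape[2] != 2:
        raise ValueError("data must be (subjects, channels, 2)")
    if data.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    diff = data[:, :, 0] - data[:, :, 1]
    return _t_from_diff(diff)


def _t_from_diff(diff):
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[np.isnan(t)] = 0.0  # mean 0, sd 0
    return t


def find_clusters(t, adjacency, df, cluster_alpha=0.05, min_neighbors=2):
    """Candidate clusters among supra-threshold channels.

    A channel is supra-threshold when its two-tailed p < ``cluster_alpha``;
    it survives only if at least ``min_neighbors`` of its adjacency neighbors
    are also supra-threshold. Clusters are connected components of surviving
    channels, split by t sign, scored by the sum of member t-values.
    """
    t = np.asarray(t, dtype=float)
    adjacency = check_symmetric_adjacency(adjacency)
    t_crit = stats.t.ppf(1.0 - cluster_alpha / 2.0, df)
    supra = np.abs(t) > t_crit
    n_supra_neigh = adjacency @ supra.astype(int)
    surviving = supra & (n_supra_neigh >= min_neighbors)

    clusters = []
    for sign in (1, -1):
        mask = surviving & (np.sign(t) == sign)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        sub = sparse.csr_matrix(adjacency[np.ix_(idx, idx)])
        n_comp, labels = sparse.csgraph.connected_components(sub, directed=False)
        for comp in range(n_comp):
            members = idx[labels == comp]
            clusters.append(Cluster(channels=tuple(int(c) for c in members),
                                    t_sum=float(t[members].sum()), sign=sign))
    return clusters


def permutation_test(data, adjacency, n_perm=1000, cluster_alpha=0.05,
                     alpha=0.05, min_neighbors=2, seed=None) -> ClusterResult:
    """Cluster-based permutation test on paired condition data.

    ``data`` has shape (subjects, channels, 2). Cluster p-values use the
    +1-corrected proportion of permutations whose maximum |cluster statistic|
    reaches the observed one, so p >= 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    data = np.asarray(data, dtype=float)
    rng = as_rng(seed)
    n_sub = data.shape[0]
    df = n_sub - 1
    diff = data[:, :, 0] - data[:, :, 1]

    t_obs = _t_from_diff(diff)
    observed = find_clusters(t_obs, adjacency, df, cluster_alpha, min_neighbors)

    # vectorized null: t statistics for all sign-flip permutations at once
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    t_null = _t_all_flips(diff, signs)
    t_crit = stats.t.ppf(1.0 - cluster_alpha / 2.0, df)
    null_max = np.zeros(n_perm)
    any_supra = np.any(np.abs(t_null) > t_crit, axis=1)
    for i in np.flatnonzero(any_supra):
        cl = find_clusters(t_null[i], adjacency, df, cluster_alpha, min_neighbors)
        if cl:
            null_max[i] = max(abs(c.t_sum) for c in cl)

    scored = tuple(
        Cluster(channels=c.channels, t_sum=c.t_sum, sign=c.sign,
                p=float((1 + np.sum(null_max >= abs(c.t_sum))) / (n_perm + 1)))
        for c in observed)
    return ClusterResult(clusters=scored, t_values=t_obs, n_permutations=n_perm,
                         cluster_alpha=cluster_alpha, alpha=alpha,
                         null_max=null_max)


def _t_all_flips(diff, signs):
    """Paired t per channel for many sign-flip permutations.

    Exploits that flipping signs leaves the per-channel sum of squares
    unchanged, so only the permuted means need recomputing.
    """
    n = diff.shape[0]
    ssq = np.sum(diff ** 2, axis=0)                       # (channels,)
    means = signs @ diff / n                              # (perms, channels)
    var = (ssq[None, :] - n * means ** 2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / n)
    t[~np.isfinite(t)] = 0.0
    return t


class ClusterPermutationTest(BaseEstimator):
    """Estimator wrapper around :func:`permutation_test`.

    Parameters mirror the function; ``fit(X)`` expects X of shape
    (subjects, channels, 2) and exposes ``clusters_``, ``t_values_`` and
    ``result_`` fitted attributes.
    """

    def __init__(self, adjacency=None, n_perm=1000, cluster_alpha=0.05,
                 alpha=0.05, min_neighbors=2, random_state=None):
        self.adjacency = adjacency
        self.n_perm = n_perm
        self.cluster_alpha = cluster_alpha
        self.alpha = alpha
        self.min_neighbors = min_neighbors
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.adjacency is None:
            raise ValueError("adjacency must be provided")
        self.result_ = permutation_test(
            X, self.adjacency, n_perm=self.n_perm,
            cluster_alpha=self.cluster_alpha, alpha=self.alpha,
            min_neighbors=self.min_neighbors, seed=self.random_state)
        self.clusters_ = self.result_.clusters
        self.t_values_ = self.result_.t_values
        return self
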