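"""Clustering backends: k-means, neural gas, and single-linkage hierarchical.

All three return a :class:`Partition` with labels canonicalized to 1..K by
first occurrence, so the output is stable under internal label permutations.
Objects are genes; features are samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

try:  # optional JIT for the online neural-gas loop
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass
class Partition:
    """A hard clustering of named objects into clusters 1..K."""

    object_ids: list[str]
    labels: np.ndarray  # int array in 1..K
    K: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.object_ids),):
            raise ValueError("labels must align with object_ids")
        present = np.unique(self.labels)
        if present.min() < 1 or present.max() > self.K:
            raise ValueError("labels must lie in 1..K")
        if len(present) != self.K:
            raise ValueError("every cluster index in 1..K must be non-empty")

    def members(self, k: int) -> list[str]:
        return [o for o, l in zip(self.object_ids, self.labels) if l == k]


def canonicalize_labels(labels: np.ndarray) -> np.ndarray:
    """Renumber clusters 1..K in order of first occurrence."""
    labels = np.asarray(labels)
    mapping: dict[int, int] = {}
    out = np.empty(len(labels), dtype=int)
    for i, l in enumerate(labels):
        if l not in mapping:
            mapping[l] = len(mapping) + 1
        out[i] = mapping[l]
    return out


def _check_k(X: np.ndarray, K: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (objects x features)")
    if not 1 <= K <= X.shape[0]:
        raise ValueError(f"K={K} must be in 1..{X.shape[0]} (number of objects)")
    return X


def _partition(object_ids, labels, K) -> Partition:
    if object_ids is None:
        object_ids = [str(i) for i in range(len(labels))]
    return Partition(list(object_ids), canonicalize_labels(labels), K)


def kmeans(
    X: np.ndarray,
    K: int,
    seed: int,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
    object_ids: list[str] | None = None,
) -> Partition:
    """Lloyd k-means with k-means++ seeding, best of ``n_init`` restarts.

    Deterministic given ``seed``; empty clusters are repaired internally by
    reassigning the farthest points (scikit-learn's Lloyd implementation).
    """
    X = _check_k(X, K)
    km = KMeans(
        n_clusters=K, init="k-means++", n_init=n_init, max_iter=max_iter,
        tol=tol, random_state=int(seed) % (2**32), algorithm="lloyd",
    ).fit(X)
    return _partition(object_ids, km.labels_ + 1, K)


def _ng_schedules(K, epochs, n, lambda0, lambda_final, eps0, eps_final):
    T = epochs * n
    frac = np.arange(T) / max(T - 1, 1)
    lam = lambda0 * (lambda_final / lambda0) ** frac
    eps = eps0 * (eps_final / eps0) ** frac
    return lam, eps


def _ng_loop_py(X, protos, order, lam, eps):
    for t in range(order.shape[0]):
        x = X[order[t]]
        d = ((protos - x) ** 2).sum(axis=1)
        ranks = np.argsort(np.argsort(d))
        protos += (eps[t] * np.exp(-ranks / lam[t]))[:, None] * (x - protos)
    return protos


if _HAVE_NUMBA:

    @njit(cache=False)
    def _ng_loop_jit(X, protos, order, lam, eps):  # pragma: no cover - jit
        T = order.shape[0]
        K, S = protos.shape
        for t in range(T):
            x = X[order[t]]
            d = np.empty(K)
            for j in range(K):
                acc = 0.0
                for s in range(S):
                    diff = protos[j, s] - x[s]
                    acc += diff * diff
                d[j] = acc
            idx = np.argsort(d)
            ranks = np.empty(K, dtype=np.int64)
            for r in range(K):
                ranks[idx[r]] = r
            for j in range(K):
                h = eps[t] * np.exp(-ranks[j] / lam[t])
                for s in range(S):
                    protos[j, s] += h * (x[s] - protos[j, s])
        return protos

    _ng_loop = _ng_loop_jit
else:  # pragma: no cover
    _ng_loop = _ng_loop_py


def neural_gas(
    X: np.ndarray,
    K: int,
    seed: int,
    epochs: int = 100,
    lambda0: float | None = None,
    lambda_final: float = 0.01,
    eps0: float = 0.5,
    eps_final: float = 0.005,
    object_ids: list[str] | None = None,
) -> Partition:
    """Martinetz-Schulten online neural gas.

    Prototypes start at K distinct (seeded) data points. Each presented
    sample pulls every prototype toward it with strength
    eps(t) * exp(-rank / lambda(t)), where rank orders prototypes by distance
    to the sample, and eps/lambda decay exponentially from their initial to
    final values over ``epochs`` passes through the data. The returned
    partition assigns each object to its nearest final prototype.
    """
    X = _check_k(X, K)
    n = X.shape[0]
    if lambda0 is None:
        lambda0 = max(K / 2.0, 1e-6)
    rng = np.random.default_rng(seed)
    protos = X[rng.choice(n, size=K, replace=False)].copy()
    order = np.concatenate([rng.permutation(n) for _ in range(epochs)])
    lam, eps = _ng_schedules(K, epochs, n, lambda0, lambda_final, eps0, eps_final)
    protos = _ng_loop(
        np.ascontiguousarray(X), protos, order.astype(np.int64), lam, eps
    )
    d = ((X[:, None, :] - protos[None, :, :]) ** 2).sum(axis=2)
    labels = d.argmin(axis=1)
    # repair empty prototypes: give each the point farthest from its assigned
    # prototype, never stealing the last member of another cluster
    for k in range(K):
        if not np.any(labels == k):
            own = d[np.arange(n), labels]
            sizes = np.bincount(labels, minlength=K)
            movable = sizes[labels] >= 2
            far = int(np.argmax(np.where(movable, own, -np.inf)))
            labels[far] = k
    return _partition(object_ids, labels + 1, K)


def single_linkage(
    X: np.ndarray,
    K: int,
    metric: str = "euclidean",
    object_ids: list[str] | None = None,
) -> Partition:
    """Agglomerative single-linkage dendrogram cut to exactly K clusters.

    The cut keeps the first n-K merges in merge order, so tied merge heights
    are resolved deterministically by earliest merge (a height threshold cut
    cannot guarantee exactly K clusters under ties).
    """
    if metric != "euclidean":
        raise ValueError("only euclidean distance is supported")
    X = _check_k(X, K)
    n = X.shape[0]
    if n == 1 or K == n:
        return _partition(object_ids, np.arange(1, n + 1), K)
    Z = linkage(pdist(X, metric="euclidean"), method="single")
    # replay merges with union-find, stopping after n-K merges
    parent = list(range(2 * n - 1))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for m in range(n - K):
        a, b = int(Z[m, 0]), int(Z[m, 1])
        new = n + m
        parent[find(a)] = new
        parent[find(b)] = new
    roots = [find(i) for i in range(n)]
    uniq = {r: i + 1 for i, r in enumerate(dict.fromkeys(roots))}
    labels = np.array([uniq[r] for r in roots])
    return _partition(object_ids, labels, K)


#: name -> callable with the uniform (X, K, seed, object_ids) signature
BACKENDS = {
    "kmeans": lambda X, K, seed, object_ids=None: kmeans(X, K, seed, object_ids=object_ids),
    "neuralgas": lambda X, K, seed, object_ids=None: neural_gas(X, K, seed, object_ids=object_ids),
    "single": lambda X, K, seed, object_ids=None: single_linkage(X, K, object_ids=object_ids),
}
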