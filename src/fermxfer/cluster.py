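"""Sub-source-domain partitioning by K-means and centroid matching.

The local-modelling front end: source-batch samples (in PCA space) are
partitioned into phase-specific clusters ("sub-source domains"), the cluster
count is chosen on the SSE-versus-k curve by a discrete maximum-curvature
(elbow) rule, and new target samples are matched to the sub-source domain
with the nearest centroid by Euclidean distance.

K-means is implemented as Lloyd's algorithm with greedy-spread (k-means++
style) seeding and multiple seeded restarts.  The implementation is local so that
the per-iteration WCSS trace, deterministic lowest-index tie-breaking and
the empty-cluster contract are all observable; scikit-learn's KMeans serves
as an independent cross-check in the test suite, not as the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClusterModel",
    "SubSourceDomain",
    "kmeans_fit",
    "sse_curve",
    "elbow_select",
    "partition_domains",
    "match_domain",
]


@dataclass
class ClusterModel:
    """A fitted K-means partition in feature (PCA) space."""

    K: int
    centroids: np.ndarray           # K x d
    assignment: np.ndarray          # n, cluster index of each sample
    wcss: float                     # within-cluster sum of squares
    seed: int
    wcss_history: list[float] = field(default_factory=list)
    n_iter: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return _assign(X, self.centroids)


@dataclass
class SubSourceDomain:
    """One cluster of source samples with its centroid and trained sub-model."""

    domain_id: int                  # 1-based
    samples_X: np.ndarray
    samples_y: np.ndarray
    centroid: np.ndarray
    indices: np.ndarray | None = None
    model_ref: object | None = None


def _sqdist(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    # n x K matrix of squared Euclidean distances
    return ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)


def _assign(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    # argmin takes the lowest index on ties
    return np.argmin(_sqdist(X, C), axis=1)


def _greedy_spread_init(X: np.ndarray, K: int, rng: np.random.Generator
                        ) -> np.ndarray:
    """k-means++ style seeding: subsequent centres drawn with probability
    proportional to squared distance from the nearest chosen centre."""
    n = X.shape[0]
    centers = [X[rng.integers(n)]]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for _ in range(1, K):
        total = d2.sum()
        if total <= 0:  # all remaining points coincide with a centre
            centers.append(X[rng.integers(n)])
            continue
        centers.append(X[rng.choice(n, p=d2 / total)])
        d2 = np.minimum(d2, ((X - centers[-1]) ** 2).sum(axis=1))
    return np.array(centers)


def _lloyd(X: np.ndarray, K: int, rng: np.random.Generator,
           max_iter: int, tol: float) -> tuple[np.ndarray, np.ndarray, list[float]]:
    C = _greedy_spread_init(X, K, rng)
    labels = np.full(X.shape[0], -1)
    history: list[float] = []
    for _ in range(max_iter):
        d2 = _sqdist(X, C)
        new_labels = np.argmin(d2, axis=1)
        history.append(float(d2[np.arange(len(X)), new_labels].sum()))
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        shift = 0.0
        for k in range(K):
            members = X[labels == k]
            if len(members):  # empty clusters keep their previous centre
                new_c = members.mean(axis=0)
                shift = max(shift, float(np.linalg.norm(new_c - C[k])))
                C[k] = new_c
        if shift < tol:
            # converged in centroid movement: one final assignment pass so
            # the returned labels are nearest-centroid consistent
            d2 = _sqdist(X, C)
            labels = np.argmin(d2, axis=1)
            history.append(float(d2[np.arange(len(X)), labels].sum()))
            break
    return C, labels, history


def kmeans_fit(X: np.ndarray, K: int, seed: int = 0, max_iter: int = 300,
               tol: float = 1e-8, n_init: int = 10) -> ClusterModel:
    """Lloyd's K-means, best of ``n_init`` k-means++ seeded restarts by WCSS."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n = X.shape[0]
    if not 1 <= K <= n:
        raise ValueError(f"K must be in [1, {n}] (got {K})")
    root = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, K])
    best = None
    for child in root.spawn(n_init):
        rng = np.random.default_rng(child)
        C, labels, history = _lloyd(X, K, rng, max_iter, tol)
        wcss = history[-1]
        if best is None or wcss < best[3] - 1e-15:
            best = (C, labels, history, wcss)
    C, labels, history, wcss = best
    return ClusterModel(K=K, centroids=C, assignment=labels, wcss=wcss,
                        seed=seed, wcss_history=history, n_iter=len(history))


def sse_curve(X: np.ndarray, k_max: int, seed: int = 0, n_init: int = 10
              ) -> np.ndarray:
    """WCSS of the best K-means fit for each k = 1..k_max."""
    X = np.asarray(X, dtype=float)
    if k_max > X.shape[0]:
        raise ValueError("k_max cannot exceed the sample count")
    return np.array([
        kmeans_fit(X, k, seed=seed, n_init=n_init).wcss
        for k in range(1, k_max + 1)
    ])


def elbow_select(sse: np.ndarray) -> int:
    """Cluster count at the elbow of the SSE curve.

    The elbow is operationalized as the interior k maximizing the discrete
    curvature proxy ``SSE(k-1) - 2 SSE(k) + SSE(k+1)``; ties break to the
    smallest k.
    """
    sse = np.asarray(sse, dtype=float)
    if sse.size < 3:
        raise ValueError("need SSE values for at least 3 cluster counts")
    curvature = sse[:-2] - 2 * sse[1:-1] + sse[2:]
    return int(np.argmax(curvature)) + 2  # interior k, 1-based cluster count


def partition_domains(X: np.ndarray, y: np.ndarray, model: ClusterModel
                      ) -> list[SubSourceDomain]:
    """Split (X, y) into per-cluster sub-source domains."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    domains = []
    for k in range(model.K):
        idx = np.nonzero(model.assignment == k)[0]
        if idx.size == 0:
            raise ValueError(
                f"cluster {k + 1} is empty; re-fit K-means with a different "
                "seed or a smaller K")
        domains.append(SubSourceDomain(
            domain_id=k + 1,
            samples_X=X[idx],
            samples_y=y[idx],
            centroid=X[idx].mean(axis=0),
            indices=idx,
        ))
    return domains


def match_domain(x_target: np.ndarray, domains: list[SubSourceDomain]
                 ) -> tuple[int, np.ndarray]:
    """Euclidean-nearest sub-source domain for one target sample.

    Returns the 1-based id of the minimizing domain (ties to the lowest id)
    and the vector of distances to every centroid.
    """
    x = np.asarray(x_target, dtype=float).ravel()
    cents = np.array([d.centroid for d in domains])
    if cents.shape[1] != x.size:
        raise ValueError(
            f"target has {x.size} features, centroids have {cents.shape[1]}")
    dists = np.sqrt(((cents - x) ** 2).sum(axis=1))
    return domains[int(np.argmin(dists))].domain_id, dists
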