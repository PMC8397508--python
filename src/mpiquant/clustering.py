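"""One-dimensional k-means++ clustering of pixel intensities.

MPI signal is linear in tracer mass and has essentially no tissue
background, so the segmentation problem reduces to partitioning pixel
*intensities* into tiers (background, faint shells, bright core).  The
clustering here is therefore deliberately 1-D: the feature of a pixel is
its intensity alone, and spatial structure is handled afterwards by
connected-component analysis.

The implementation is self-contained: D^2-weighted seeding (k-means++),
Lloyd iterations with empty-cluster re-seeding, best-of-``n_init``
restarts by within-cluster sum of squares (WCSS).  Centroids are sorted
ascending after fitting, so cluster ``k - 1`` is always the brightest —
a stable contract the segmentation layer relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ClusterModel", "ElbowResult", "seed_centroids", "fit_kmeans", "elbow_select_k"]


@dataclass
class ClusterModel:
    """Result of a 1-D k-means fit.

    Attributes
    ----------
    k : int
        Number of centroids.
    centroids : ndarray, shape (k,)
        Cluster centres sorted ascending; index ``k - 1`` is brightest.
    labels : ndarray of int
        Per-value cluster index after sorting; ties in the nearest-centroid
        assignment go to the lower index.
    wcss : float
        Within-cluster sum of squared deviations of the best restart.
    n_iter : int
        Lloyd iterations run by the best restart.
    converged : bool
        Whether the best restart met the shift tolerance before ``max_iter``.
    seed : int | None
        Seed recorded for reproducibility (None when a Generator was passed).
    wcss_trace : list[float]
        WCSS after each Lloyd assignment step of the best restart
        (non-increasing by construction).
    """

    k: int
    centroids: np.ndarray
    labels: np.ndarray
    wcss: float
    n_iter: int
    converged: bool
    seed: int | None = None
    wcss_trace: list = field(default_factory=list)


@dataclass
class ElbowResult:
    k: int
    ks: list
    wcss: list


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def seed_centroids(values, k: int, rng=None) -> np.ndarray:
    """Draw ``k`` initial centroids from ``values`` by D^2 weighting.

    The first centroid is uniform over the data; each subsequent one is a
    data point drawn with probability proportional to its squared distance
    to the nearest centroid already chosen.  Points coinciding with a
    chosen centroid have zero weight, so the k seeds are always distinct.

    Raises
    ------
    ValueError
        If ``k`` exceeds the number of distinct values.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot seed centroids from empty data")
    n_distinct = np.unique(x).size
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > n_distinct:
        raise ValueError(
            f"k={k} exceeds the number of distinct values ({n_distinct})"
        )
    rng = _as_rng(rng)
    centers = [x[rng.integers(x.size)]]
    d2 = (x - centers[0]) ** 2
    for _ in range(1, k):
        total = d2.sum()
        # total > 0 is guaranteed because n_distinct > len(centers)
        idx = rng.choice(x.size, p=d2 / total)
        centers.append(x[idx])
        d2 = np.minimum(d2, (x - centers[-1]) ** 2)
    return np.asarray(centers)


def _lloyd(x: np.ndarray, centroids: np.ndarray, max_iter: int, tol: float):
    """Lloyd iterations on 1-D data.  Returns (centroids, labels, wcss,
    n_iter, converged, trace).  ``tol`` is relative to the data range."""
    c = centroids.astype(float).copy()
    k = c.size
    scale = float(x.max() - x.min()) if x.size else 0.0
    if scale == 0.0:
        scale = max(abs(float(x[0])), 1.0) if x.size else 1.0
    trace = []
    labels = None
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        dist = np.abs(x[:, None] - c[None, :])
        labels = np.argmin(dist, axis=1)  # ties -> lower index
        # re-seed empty clusters at the point farthest from its centroid
        for j in range(k):
            if not np.any(labels == j):
                dmin = dist[np.arange(x.size), labels]
                far = int(np.argmax(dmin))
                c[j] = x[far]
                dist = np.abs(x[:, None] - c[None, :])
                labels = np.argmin(dist, axis=1)
        trace.append(float(np.sum((x - c[labels]) ** 2)))
        new_c = np.array([x[labels == j].mean() for j in range(k)])
        shift = float(np.max(np.abs(new_c - c))) / scale
        c = new_c
        if shift < tol:
            converged = True
            break
    wcss = float(np.sum((x - c[labels]) ** 2))
    return c, labels, wcss, n_iter, converged, trace


def fit_kmeans(
    values,
    k: int = 4,
    max_iter: int = 300,
    tol: float = 1e-6,
    n_init: int = 10,
    rng=None,
) -> ClusterModel:
    """Fit 1-D k-means with k-means++ seeding, best of ``n_init`` restarts.

    ``tol`` is the centroid shift threshold relative to the data range.
    After fitting, centroids are sorted ascending and labels recomputed
    against the sorted centroids (nearest centroid, ties to lower index).
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    x = np.asarray(values, dtype=float).ravel()
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = _as_rng(rng)
    best = None
    for _ in range(n_init):
        c0 = seed_centroids(x, k, rng)
        c, labels, wcss, n_iter, converged, trace = _lloyd(x, c0, max_iter, tol)
        if best is None or wcss < best[2]:
            best = (c, labels, wcss, n_iter, converged, trace)
    c, labels, wcss, n_iter, converged, trace = best
    order = np.argsort(c, kind="stable")
    c = c[order]
    labels = np.argmin(np.abs(x[:, None] - c[None, :]), axis=1)
    return ClusterModel(
        k=k,
        centroids=c,
        labels=labels,
        wcss=wcss,
        n_iter=n_iter,
        converged=converged,
        seed=None if seed is None else int(seed),
        wcss_trace=trace,
    )


def elbow_select_k(values, k_min: int, k_max: int, n_init: int = 10, rng=None) -> ElbowResult:
    """Select k at the point of greatest curvature of the WCSS-vs-k curve.

    Fits k-means for each k in ``[k_min, k_max]`` and returns the interior
    k maximising the second difference of the WCSS curve on a log scale —
    the sharpest relative bend of the elbow.  (On the raw scale the second
    difference is dominated by the absolute size of the first drops and
    misses elbows that bottom out near zero.)  The full curve is returned
    for inspection.
    """
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    if k_max - k_min < 2:
        raise ValueError(
            "elbow selection needs at least three k values "
            f"(got range [{k_min}, {k_max}])"
        )
    rng = _as_rng(rng)
    ks = list(range(k_min, k_max + 1))
    wcss = [fit_kmeans(values, k, n_init=n_init, rng=rng).wcss for k in ks]
    if wcss[0] == 0.0:  # already perfectly separable at k_min
        return ElbowResult(k=k_min, ks=ks, wcss=wcss)
    floor = 1e-12 * wcss[0]
    logw = np.log(np.maximum(wcss, floor))
    curv = logw[:-2] - 2.0 * logw[1:-1] + logw[2:]
    k_sel = ks[1 + int(np.argmax(curv))]
    return ElbowResult(k=k_sel, ks=ks, wcss=wcss)
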