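"""Clustering of (reconstructed) R-TFMs and cluster-to-class assignment.

The reconstructed 64x64 maps are flattened column-wise into 4096-vectors and
grouped into K = 4 clusters (K-means by default; fuzzy c-means, Gaussian
mixtures and mean-shift are drop-in alternatives).  Clusters are anonymous,
so they are mapped to event classes with the spectral centroid (SC) of each
cluster's band-passed candidate windows: HFO classes carry their energy at
higher frequencies, so ranking clusters by mean SC in descending order gives
{fast ripple, ripple, spike, artifact}.  The binary HFO flag is membership of
either of the top two clusters.  The spike/artifact ordering is a heuristic
(both live at the low end of the band) and can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import hamming
from sklearn.cluster import KMeans, MeanShift, kmeans_plusplus
from sklearn.mixture import GaussianMixture

from .ste import CandidateEvent

HFO_CLASSES = ("fast_ripple", "ripple")
CLASS_RANK = ("fast_ripple", "ripple", "spike", "artifact")


@dataclass
class ClusterResult:
    """Hard labels plus (soft) memberships; ``class_map`` maps cluster -> class."""

    labels: np.ndarray
    memberships: np.ndarray           # (n, K), rows sum to 1
    K: int
    centers: np.ndarray | None = None
    class_map: dict[int, str] = field(default_factory=dict)
    cluster_sc: dict[int, float] = field(default_factory=dict)

    def classes(self) -> np.ndarray:
        return np.asarray([self.class_map[int(c)] for c in self.labels])

    def is_hfo(self) -> np.ndarray:
        return np.isin(self.classes(), HFO_CLASSES)


def vectorize(img: np.ndarray) -> np.ndarray:
    """Column-wise (Fortran-order) flattening: element (r, c) -> index c*rows + r."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    return img.flatten(order="F")


def vectorize_stack(imgs: np.ndarray) -> np.ndarray:
    return np.stack([vectorize(im) for im in np.asarray(imgs)])


def _one_hot(labels: np.ndarray, k: int) -> np.ndarray:
    m = np.zeros((len(labels), k))
    m[np.arange(len(labels)), labels] = 1.0
    return m


def kmeans_cluster(X: np.ndarray, K: int = 4, seed: int = 0) -> ClusterResult:
    """Lloyd's algorithm with K-means++ initialisation."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < K:
        raise ValueError("need at least K samples")
    km = KMeans(n_clusters=K, init="k-means++", n_init=10, max_iter=300,
                random_state=seed)
    labels = km.fit_predict(X)
    return ClusterResult(labels=labels, memberships=_one_hot(labels, K), K=K,
                         centers=km.cluster_centers_)


def fcm_cluster(X: np.ndarray, K: int = 4, m: float = 2.0, seed: int = 0,
                max_iter: int = 300, tol: float = 1e-5) -> ClusterResult:
    """Fuzzy c-means: memberships u_ik ~ (1/d_ik^2)^(1/(m-1)), power-mean centroids.

    Centroids start from a K-means++ draw; iteration stops when the largest
    membership change falls below ``tol``.  A sample coincident with a
    centroid receives membership 1 there (the m -> limit convention).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < K:
        raise ValueError("need at least K samples")
    if m <= 1:
        raise ValueError("fuzziness m must exceed 1")
    centers, _ = kmeans_plusplus(X, n_clusters=K, random_state=seed)
    u = np.full((n, K), 1.0 / K)
    expo = 1.0 / (m - 1.0)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None]) ** 2).sum(-1)
        zero = d2 < 1e-24
        u_new = np.where(zero.any(axis=1, keepdims=True),
                         zero / np.maximum(zero.sum(1, keepdims=True), 1),
                         0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-expo)
            reg = inv / inv.sum(1, keepdims=True)
        regular = ~zero.any(axis=1)
        u_new[regular] = reg[regular]
        um = u_new ** m
        centers = (um.T @ X) / np.maximum(um.sum(0)[:, None], 1e-30)
        if np.max(np.abs(u_new - u)) < tol:
            u = u_new
            break
        u = u_new
    labels = u.argmax(1)
    return ClusterResult(labels=labels, memberships=u, K=K, centers=centers)


def gmm_cluster(X: np.ndarray, K: int = 4, seed: int = 0) -> ClusterResult:
    """Diagonal-covariance Gaussian mixture fit by EM."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < K:
        raise ValueError("need at least K samples")
    gm = GaussianMixture(n_components=K, covariance_type="diag", reg_covar=1e-6,
                         random_state=seed, max_iter=300)
    labels = gm.fit_predict(X)
    return ClusterResult(labels=labels, memberships=gm.predict_proba(X), K=K,
                         centers=gm.means_)


def _median_pairwise(X: np.ndarray, seed: int, cap: int = 400) -> float:
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(X), size=min(cap, len(X)), replace=False)
    sub = X[idx]
    d = np.sqrt(((sub[:, None] - sub[None]) ** 2).sum(-1))
    vals = d[np.triu_indices(len(sub), k=1)]
    return float(np.median(vals)) if vals.size else 1.0


def meanshift_cluster(X: np.ndarray, bandwidth: float | None = None,
                      seed: int = 0, reduce_to: int | None = 4) -> ClusterResult:
    """Mean-shift modes, optionally merged down to ``reduce_to`` clusters."""
    X = np.asarray(X, dtype=float)
    if bandwidth is None:
        bandwidth = _median_pairwise(X, seed)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    ms = MeanShift(bandwidth=bandwidth)
    labels = ms.fit_predict(X)
    centers = ms.cluster_centers_
    while reduce_to is not None and centers.shape[0] > reduce_to:
        d = np.sqrt(((centers[:, None] - centers[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        i, j = min(i, j), max(i, j)
        ni, nj = (labels == i).sum(), (labels == j).sum()
        centers[i] = (centers[i] * ni + centers[j] * nj) / max(ni + nj, 1)
        centers = np.delete(centers, j, axis=0)
        labels = np.where(labels == j, i, labels)
        labels = np.where(labels > j, labels - 1, labels)
    k = centers.shape[0]
    return ClusterResult(labels=labels, memberships=_one_hot(labels, k), K=k,
                         centers=centers)


def spectral_centroid(x: np.ndarray, fs: float) -> float:
    """Power-weighted mean frequency of the Hamming-windowed spectrum (Hz).

    SC = sum_k f_k |M[k]|^2 / sum_k |M[k]|^2 over k = 0..N/2, where M is the
    DFT of the Hamming-windowed signal.  An all-zero signal returns 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    w = hamming(x.size, sym=True)
    p = np.abs(rfft(x * w)) ** 2
    total = p.sum()
    if total == 0:
        return 0.0
    freqs = rfftfreq(x.size, d=1.0 / fs)
    return float((freqs * p).sum() / total)


def assign_classes(result: ClusterResult, events: list[CandidateEvent],
                   class_rank: tuple[str, ...] = CLASS_RANK) -> ClusterResult:
    """Map clusters to event classes by mean spectral centroid, descending.

    The SC of each member's band-passed 150 ms window is averaged per
    cluster; clusters are ranked by mean SC (ties broken by cluster size,
    larger first) and assigned ``class_rank`` in order.  Empty clusters are
    excluded from the ranking and mapped to 'artifact'.
    """
    if len(events) != len(result.labels):
        raise ValueError("one event per clustered sample required")
    sc = np.asarray([spectral_centroid(ev.filtered_window, ev.fs_hz) for ev in events])
    order_stats = []
    for c in range(result.K):
        mask = result.labels == c
        size = int(mask.sum())
        if size == 0:
            warnings.warn(f"cluster {c} is empty; mapped to 'artifact'")
            result.class_map[c] = "artifact"
            result.cluster_sc[c] = float("nan")
            continue
        mean_sc = float(sc[mask].mean())
        result.cluster_sc[c] = mean_sc
        order_stats.append((mean_sc, size, c))
    ranked = sorted(order_stats, key=lambda t: (-t[0], -t[1], t[2]))
    if len({round(t[0], 9) for t in order_stats}) == 1 and len(order_stats) > 1:
        warnings.warn("all clusters share the same mean SC; ranking falls back "
                      "to cluster size")
        ranked = sorted(order_stats, key=lambda t: (-t[1], t[2]))
    for rank, (_, _, c) in enumerate(ranked):
        result.class_map[c] = class_rank[rank] if rank < len(class_rank) else "artifact"
    return result
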