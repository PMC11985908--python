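"""Scintillation-spot identification and clustering scores.

The number of spots on a detector frame is not known in advance, so spots are
found with a G-means-style algorithm: start from a single cluster, refine
with k-means, and test every cluster for unimodality by projecting its points
on their first principal axis and applying the Hartigan dip test against the
uniform null.  Clusters whose projection rejects unimodality (p < alpha,
default 0.001) are split in two along the principal axis, the new centroids
placed at +/- sqrt(2 * lambda / pi) times the principal direction (the mean
absolute deviation of a Gaussian with variance lambda); the loop terminates
when no cluster splits.  The procedure is deterministic for a fixed seed.

Per-spot features feed the energy classifier: the centroid, the effective
radius r_c (mean Euclidean distance of the spot's points to the centroid --
a depth proxy, since deeper absorption events spread their light over a
larger footprint), and the dominant emission channel.

Clusterings are scored against ground truth with the Fowlkes-Mallows index,
the geometric mean of pairwise precision and recall computed from the label
contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from ._dip import critical_value, dip_statistic, dip_test
from .errors import ValidationError

__all__ = ["Clustering", "ClusterFeatures", "dip_test", "dip_statistic",
           "gmeans", "cluster_features", "fm_index"]

CHANNELS = ("R", "G", "B")


@dataclass(frozen=True)
class Clustering:
    """A hard partition of a point set with its centroids."""

    points: np.ndarray          # (n, d)
    labels: np.ndarray          # (n,) ints in [0, k)
    centroids: np.ndarray       # (k, d)

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]


@dataclass(frozen=True)
class ClusterFeatures:
    """Features of one scintillation spot used for energy inference."""

    centroid: tuple[float, float]
    radius: float                       # r_c, mean distance to centroid (mm)
    channel: str                        # dominant emission channel
    channel_counts: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.radius < 0:
            raise ValidationError("effective radius must be non-negative")


def _principal_axis(pts: np.ndarray) -> tuple[np.ndarray, float]:
    """First principal direction (sign-fixed) and its variance."""
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / max(len(pts) - 1, 1)
    vals, vecs = np.linalg.eigh(cov)
    v = vecs[:, -1]
    nz = np.flatnonzero(np.abs(v) > 1e-12)
    if nz.size and v[nz[0]] < 0:   # deterministic sign convention
        v = -v
    return v, float(vals[-1])


def gmeans(points, alpha: float = 0.001, seed: int = 0,
           max_clusters: int | None = None, n_boot: int = 2000,
           min_split_size: int = 4) -> Clustering:
    """Cluster points without a preset k by dip-tested k-means splitting.

    ``alpha`` is the split significance; unimodality is judged against
    cached uniform-null critical dip values (``n_boot`` draws per sample
    size, fixed seed), so repeated runs are reproducible.  Clusters smaller
    than ``min_split_size`` are declared unimodal by decision.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return Clustering(pts.reshape(0, 2), np.empty(0, dtype=int),
                          np.empty((0, pts.shape[1] if pts.ndim == 2 else 2)))
    if pts.ndim != 2:
        raise ValidationError("points must be an (n, d) array")
    n = len(pts)
    if n == 1:
        return Clustering(pts, np.zeros(1, dtype=int), pts.copy())

    centroids = pts.mean(axis=0, keepdims=True)
    stable = np.zeros(1, dtype=bool)     # clusters already judged unimodal
    labels = np.zeros(n, dtype=int)
    while True:
        km = KMeans(n_clusters=len(centroids), init=centroids, n_init=1,
                    max_iter=100, tol=1e-6, random_state=seed)
        labels = km.fit_predict(pts)
        centroids = km.cluster_centers_
        if len(stable) != len(centroids):
            stable = np.zeros(len(centroids), dtype=bool)
        new_centroids = []
        new_stable = []
        split_any = False
        for c in range(len(centroids)):
            members = pts[labels == c]
            if len(members) == 0:
                continue
            if stable[c] or len(members) < min_split_size or (
                    max_clusters is not None
                    and len(centroids) >= max_clusters):
                new_centroids.append(centroids[c])
                new_stable.append(True)
                continue
            axis, lam = _principal_axis(members)
            proj = members @ axis
            d = dip_statistic(proj)
            if d > critical_value(len(proj), alpha, n_boot=n_boot):
                offset = np.sqrt(2.0 * lam / np.pi) * axis
                new_centroids.append(centroids[c] + offset)
                new_centroids.append(centroids[c] - offset)
                new_stable.extend([False, False])
                split_any = True
            else:
                new_centroids.append(centroids[c])
                new_stable.append(True)
        centroids = np.asarray(new_centroids)
        stable = np.asarray(new_stable)
        if not split_any:
            break
    # final assignment consistent with returned centroids
    km = KMeans(n_clusters=len(centroids), init=centroids, n_init=1,
                max_iter=100, tol=1e-6, random_state=seed)
    labels = km.fit_predict(pts)
    return Clustering(pts, labels, km.cluster_centers_)


def cluster_features(points, channels=None,
                     centroid: np.ndarray | None = None) -> ClusterFeatures:
    """Centroid, effective radius and dominant channel of one spot.

    ``channels`` holds the emission channel of each point ("R"/"G"/"B" or
    channel indices); ties on the dominant channel resolve to the lowest
    channel index.  r_c is the mean Euclidean distance to the centroid.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValidationError("cluster must contain at least one point")
    pts = np.atleast_2d(pts)
    ctr = pts.mean(axis=0) if centroid is None else np.asarray(centroid)
    r_c = float(np.mean(np.linalg.norm(pts - ctr, axis=1)))
    counts = {ch: 0 for ch in CHANNELS}
    if channels is not None:
        ch_arr = np.asarray(channels)
        for i, ch in enumerate(CHANNELS):
            if ch_arr.dtype.kind in "iu":
                counts[ch] = int(np.count_nonzero(ch_arr == i))
            else:
                counts[ch] = int(np.count_nonzero(ch_arr == ch))
        dominant = CHANNELS[int(np.argmax([counts[ch] for ch in CHANNELS]))]
    else:
        dominant = CHANNELS[0]
    return ClusterFeatures(centroid=(float(ctr[0]), float(ctr[1])),
                           radius=r_c, channel=dominant,
                           channel_counts=counts)


def fm_index(labels_a, labels_b) -> float:
    """Fowlkes-Mallows index between two clusterings of the same points.

    FM = sqrt( TP/(TP+FP) * TP/(TP+FN) ) with TP/FP/FN counted over point
    pairs, evaluated from the label contingency table in O(n k).  TP = 0
    (e.g. all-singletons vs one-cluster) gives FM = 0.
    """
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape != b.shape:
        raise ValidationError("clusterings must label the same point set")
    n = a.size
    if n == 0:
        raise ValidationError("empty clusterings cannot be compared")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    nb = bi.max() + 1
    pair_codes = ai.astype(np.int64) * nb + bi
    nij = np.bincount(pair_codes).astype(float)
    ni = np.bincount(ai).astype(float)
    nj = np.bincount(bi).astype(float)
    tp = float(np.sum(nij * (nij - 1)) / 2.0)
    same_a = float(np.sum(ni * (ni - 1)) / 2.0)   # TP + FN
    same_b = float(np.sum(nj * (nj - 1)) / 2.0)   # TP + FP
    if tp == 0.0:
        return 0.0
    return float(np.sqrt((tp / same_b) * (tp / same_a)))
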