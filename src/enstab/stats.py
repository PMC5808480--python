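"""Statistical machinery: mean-shift clustering, correlations, KS, FDR.

Thin, explicitly-parameterised wrappers: the clustering backends come from
scikit-learn / scipy, while the bandwidth estimator and the BH step-up are
spelled out in-package so that results are pinned to a stated procedure
rather than to a library version.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats
from scipy.spatial.distance import pdist, squareform


@dataclass
class ClusteringResult:
    labels: np.ndarray  # dense ids from 0, one per item
    bandwidth: float
    centers: np.ndarray  # n_clusters x dim

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def estimate_bandwidth(points: np.ndarray, quantile: float = 0.3) -> float:
    """k-NN bandwidth estimate: mean distance to the ceil(quantile*n)-th
    nearest neighbour over all points.

    Homogeneous of degree one in the data scale.  Identical points (zero
    bandwidth) are rejected because a flat-kernel mean shift cannot move.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < 2:
        raise ValueError("need >= 2 points")
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    # k counts the point itself among its neighbours (the convention of the
    # mean-shift implementation this estimator is pinned to)
    k = min(max(2, int(quantile * n)), n)
    d = squareform(pdist(points))
    kth = np.sort(d, axis=1)[:, k - 1]
    bw = float(kth.mean())
    if bw == 0:
        raise ValueError(
            "estimated bandwidth is 0 (identical points); supply a bandwidth explicitly"
        )
    return bw


def mean_shift(points: np.ndarray, bandwidth: float) -> ClusteringResult:
    """Flat-kernel mean shift with every point as a seed.

    Each seed iterates to its mode (shift < 1e-5 * bandwidth or 300
    iterations); modes closer than the bandwidth are merged and items are
    labelled by their nearest surviving mode.  Deterministic given the input
    order.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    from sklearn.cluster import MeanShift

    points = np.asarray(points, dtype=float)
    ms = MeanShift(bandwidth=bandwidth, bin_seeding=False, max_iter=300)
    ms.fit(points)
    return ClusteringResult(
        labels=ms.labels_.astype(int),
        bandwidth=float(bandwidth),
        centers=ms.cluster_centers_,
    )


def rank_outliers_hierarchical(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rank items by mean Euclidean distance to all other items (descending).

    Returns ``(order, linkage)`` where ``order`` lists item indices from most
    to least isolated (ties broken by item id, stable) and ``linkage`` is the
    average-linkage merge table for dendrogram inspection.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 2:
        raise ValueError("need >= 2 points")
    from scipy.cluster.hierarchy import linkage

    d = squareform(pdist(points))
    mean_dist = d.sum(axis=1) / (points.shape[0] - 1)
    order = np.lexsort((np.arange(points.shape[0]), -mean_dist))
    z = linkage(pdist(points), method="average")
    return order, z


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    res = scipy.stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def bh_fdr(pvalues: dict, q: float = 0.05) -> dict:
    """Benjamini-Hochberg step-up at FDR level q.

    Returns ``{test: bool}``; a test is rejected iff its p-value is at or
    below the largest p_(k) with p_(k) <= k/m * q.
    """
    keys = list(pvalues)
    p = np.array([pvalues[k] for k in keys], dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p)
    threshold = 0.0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank / m * q:
            threshold = p[idx]
    return {k: bool(pv <= threshold) and threshold > 0 for k, pv in zip(keys, p)}


def binned_occupancy(positions, n_bins: int = 10, universe: int = 306) -> np.ndarray:
    """Count positions into n_bins equal-width bins over [0, universe).

    Bin i (1-based) covers [universe/n_bins*(i-1), universe/n_bins*i); for a
    153-residue two-chain protein, chain-F positions are mapped to 154..306
    before calling.
    """
    positions = np.asarray(list(positions), dtype=float)
    if positions.size and (positions.min() < 1 or positions.max() > universe):
        raise ValueError(f"positions must lie in [1, {universe}]")
    width = universe / n_bins
    bins = np.minimum(np.floor(positions / width).astype(int), n_bins - 1)
    return np.bincount(bins, minlength=n_bins)


def binned_position_correlation(
    list_a, list_b, n_bins: int = 10, universe: int = 306
) -> tuple[float, float]:
    """Pearson correlation between the binned occupancy vectors of two
    residue-position lists."""
    va = binned_occupancy(list_a, n_bins, universe)
    vb = binned_occupancy(list_b, n_bins, universe)
    return pearson(va, vb)


def intersection_test(list_a, list_b, universe_size: int) -> tuple[set, float]:
    """Overlap of two position lists with hypergeometric enrichment p-value.

    p is the upper-tail probability of drawing at least the observed overlap
    when ``|list_a|`` items are sampled without replacement from a universe
    containing ``|list_b|`` marked items.
    """
    if universe_size <= 0:
        raise ValueError("universe must be non-empty")
    a, b = set(list_a), set(list_b)
    overlap = a & b
    k = len(overlap)
    # P(X >= k), X ~ Hypergeom(universe, |b|, |a|)
    p = float(scipy.stats.hypergeom.sf(k - 1, universe_size, len(b), len(a)))
    return overlap, min(p, 1.0)
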