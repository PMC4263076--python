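"""Counting the repertoire of distinct global states.

Final T = 0 quench patterns are spatially smoothed (mean spin within a
radius on the cortical sheet, suppressing single-site noise), compared by
Pearson correlation, and grouped by agglomerative hierarchical clustering
with complete linkage at distance 1 - similarity.  Cutting a complete-
linkage dendrogram at height 1 - s certifies that every within-cluster pair
of patterns has similarity >= s, which is exactly the "distinct at s
similarity" semantics the repertoire count requires.

A pattern and its global flip (S -> -S) have similarity -1 and are counted
as distinct states: UP and DOWN maps are signed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance

__all__ = [
    "PatternEnsemble",
    "ClusterResult",
    "spatial_smooth",
    "pattern_similarity",
    "similarity_matrix",
    "cluster_patterns",
    "repertoire_summary",
]

DEFAULT_RADIUS_MM = 15.0
DEFAULT_SIMILARITY = 0.99
_MAX_EXACT_PATTERNS = 10_000


@dataclass
class PatternEnsemble:
    """Final quench configurations (one +/-1 row per run) with provenance."""

    patterns: np.ndarray
    converged: np.ndarray | None = None
    seeds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=np.int8)
        if self.patterns.ndim != 2 or self.patterns.shape[0] < 1:
            raise ValueError("patterns must be a non-empty (m, n) matrix")
        if not np.isin(self.patterns, (-1, 1)).all():
            raise ValueError("patterns must be +/-1")
        if self.converged is None:
            self.converged = np.ones(self.patterns.shape[0], dtype=bool)
        self.converged = np.asarray(self.converged, dtype=bool)
        if self.converged.size != self.patterns.shape[0]:
            raise ValueError("converged flags must match the number of patterns")

    @property
    def m(self) -> int:
        return self.patterns.shape[0]


@dataclass
class ClusterResult:
    """Hierarchical-clustering outcome for one ensemble."""

    labels: np.ndarray            # cluster id per pattern, 0 = most frequent
    n_clusters: int
    frequencies: np.ndarray       # descending, sums to 1
    centroids: np.ndarray         # cluster means of the smoothed patterns
    similarity: float
    radius_mm: float

    def __post_init__(self) -> None:
        if not np.isclose(self.frequencies.sum(), 1.0):
            raise ValueError("frequencies must sum to 1")
        if self.n_clusters != len(np.unique(self.labels)):
            raise ValueError("n_clusters inconsistent with labels")


def _check_distance_matrix(D: np.ndarray, n: int | None = None) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if n is not None and D.shape[0] != n:
        raise ValueError("distance matrix does not cover all sites")
    if not np.isfinite(D).all():
        raise ValueError("distance matrix has missing entries")
    return D


def spatial_smooth(
    patterns: np.ndarray, D: np.ndarray, radius: float
) -> np.ndarray:
    """Mean spin within ``radius`` mm around each site.

    Accepts a single pattern (1-D) or a stack (m, n); the neighbourhood of
    site i always includes i itself, so radius 0 returns the input and the
    smoothed values stay in [-1, 1].
    """
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    P = np.atleast_2d(np.asarray(patterns, dtype=float))
    D = _check_distance_matrix(D, P.shape[1])
    within = (D <= radius).astype(float)   # diagonal D=0 keeps self in
    smoothed = (P @ within.T) / within.sum(axis=1)
    return smoothed[0] if np.asarray(patterns).ndim == 1 else smoothed


def pattern_similarity(p: np.ndarray, q: np.ndarray) -> float:
    """Pearson correlation of two spatial patterns with degenerate-case rules.

    Both vectors constant: 1 if identical, -1 if exact opposites (the signed
    all-UP vs all-DOWN case), else 0.  Exactly one constant: 0 (correlation
    undefined; treated as unrelated).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("patterns must be 1-D vectors of equal length")
    sp, sq = p.std(), q.std()
    if sp == 0 and sq == 0:
        if np.array_equal(p, q):
            return 1.0
        if np.array_equal(p, -q):
            return -1.0
        return 0.0
    if sp == 0 or sq == 0:
        return 0.0
    return float(np.clip(np.corrcoef(p, q)[0, 1], -1.0, 1.0))


def similarity_matrix(X: np.ndarray) -> np.ndarray:
    """All-pairs pattern similarity for the rows of X (vectorised Pearson)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    ok = norms > 0
    safe = np.where(ok, norms, 1.0)
    S = (Xc / safe[:, None]) @ (Xc / safe[:, None]).T
    S = np.clip(S, -1.0, 1.0)
    # constant rows: apply the degenerate-case rules pairwise
    const = np.flatnonzero(~ok)
    for i in const:
        S[i, :] = 0.0
        S[:, i] = 0.0
        for j in const:
            if np.array_equal(X[i], X[j]):
                S[i, j] = S[j, i] = 1.0
            elif np.array_equal(X[i], -X[j]):
                S[i, j] = S[j, i] = -1.0
        S[i, i] = 1.0
    return S


def cluster_patterns(
    ensemble: PatternEnsemble | np.ndarray,
    D: np.ndarray,
    radius: float = DEFAULT_RADIUS_MM,
    similarity: float = DEFAULT_SIMILARITY,
    include_nonconverged: bool = True,
    max_patterns: int = _MAX_EXACT_PATTERNS,
    subsample_seed: int = 0,
) -> ClusterResult:
    """Smooth, then cluster hierarchically at the similarity threshold.

    Complete linkage on distance 1 - similarity, dendrogram cut at height
    1 - threshold.  Ensembles larger than ``max_patterns`` are clustered on
    a seeded random subsample (all-pairs dendrograms are quadratic in m).
    """
    if not isinstance(ensemble, PatternEnsemble):
        ensemble = PatternEnsemble(np.atleast_2d(ensemble))
    if not -1 <= similarity <= 1:
        raise ValueError("similarity must lie in [-1, 1]")
    patterns = ensemble.patterns
    if not include_nonconverged:
        patterns = patterns[ensemble.converged]
        if patterns.shape[0] == 0:
            raise ValueError("no converged patterns to cluster")
    if patterns.shape[0] > max_patterns:
        rng = np.random.default_rng(subsample_seed)
        keep = np.sort(rng.choice(patterns.shape[0], max_patterns, replace=False))
        patterns = patterns[keep]

    smoothed = spatial_smooth(patterns, D, radius)
    m = smoothed.shape[0]
    if m == 1:
        return ClusterResult(
            labels=np.zeros(1, dtype=int), n_clusters=1,
            frequencies=np.array([1.0]), centroids=smoothed.copy(),
            similarity=similarity, radius_mm=radius,
        )
    dist = 1.0 - similarity_matrix(smoothed)
    np.fill_diagonal(dist, 0.0)
    condensed = scipy.spatial.distance.squareform(np.maximum(dist, 0.0), checks=False)
    Z = sch.linkage(condensed, method="complete")
    raw = sch.fcluster(Z, t=(1.0 - similarity) + 1e-12, criterion="distance")

    # relabel so that cluster 0 is the most frequent; ties by first occurrence
    ids, counts = np.unique(raw, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    remap = {int(ids[o]): rank for rank, o in enumerate(order)}
    labels = np.array([remap[int(r)] for r in raw], dtype=int)
    frequencies = counts[order] / m
    centroids = np.stack([smoothed[labels == c].mean(axis=0) for c in range(len(ids))])
    return ClusterResult(
        labels=labels, n_clusters=len(ids), frequencies=frequencies,
        centroids=centroids, similarity=similarity, radius_mm=radius,
    )


def repertoire_summary(result: ClusterResult, top_m: int = 40) -> pd.DataFrame:
    """Tabulate the most frequent states as UP-probability maps.

    Returns one row per reported cluster: id, size share, and the centroid
    rescaled from mean spin in [-1, 1] to P(UP) in [0, 1].
    """
    if top_m < 1:
        raise ValueError("top_m must be >= 1")
    k = min(top_m, result.n_clusters)
    rows = []
    for c in range(k):
        rows.append({
            "cluster": c,
            "frequency": result.frequencies[c],
            "up_probability_map": (result.centroids[c] + 1.0) / 2.0,
        })
    df = pd.DataFrame(rows)
    df.attrs["n_clusters"] = result.n_clusters
    return df
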