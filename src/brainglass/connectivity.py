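"""Functional connectivity and the long-range interaction graph.

The simulation is constrained by empirical (or synthetic) resting-state
functional connectivity: site-mapped time courses are reduced to a pairwise
Pearson correlation matrix, correlation matrices from several subjects are
averaged into a group matrix, and each site is wired to its ``k`` most
strongly correlated partners.  The resulting binary, generally asymmetric
adjacency matrix is the only coupling structure the spin model sees —
correlation magnitudes are not used as weights.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.io
import scipy.sparse

__all__ = [
    "TimeCourses",
    "InteractionGraph",
    "pairwise_correlation",
    "group_average_connectivity",
    "global_connectivity_map",
    "build_interaction_graph",
    "validate_connectivity",
    "save_graph",
    "load_graph",
]


@dataclass
class TimeCourses:
    """Site-mapped multivariate time courses for one subject.

    Parameters
    ----------
    data : ndarray, shape (n_sites, n_timepoints)
        One row per site; arbitrary signal units.
    site_ids : sequence of str
        Unique site identifiers, one per row.
    coordinates : ndarray, shape (n_sites, 3), optional
        Site positions in mm.
    """

    data: np.ndarray
    site_ids: Sequence[str] = field(default=None)  # type: ignore[assignment]
    coordinates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (n_sites, n_timepoints) array")
        n = self.data.shape[0]
        if self.site_ids is None:
            self.site_ids = [f"site{i}" for i in range(n)]
        self.site_ids = list(map(str, self.site_ids))
        if len(self.site_ids) != n:
            raise ValueError("site_ids length does not match number of rows")
        if len(set(self.site_ids)) != n:
            raise ValueError("site_ids must be unique")
        if self.data.shape[1] < 3:
            raise ValueError("need at least 3 timepoints per site")
        if not np.isfinite(self.data).all():
            raise ValueError("time courses contain missing/non-finite values")
        if self.coordinates is not None:
            self.coordinates = np.asarray(self.coordinates, dtype=float)
            if self.coordinates.shape != (n, 3):
                raise ValueError("coordinates must have shape (n_sites, 3)")

    @property
    def n_sites(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class InteractionGraph:
    """Binary directed interaction structure.

    ``A[i, k] = 1`` iff site ``k`` influences site ``i`` (``k`` is among the
    ``k_neighbors`` sites most correlated with ``i``).  Every row sums to
    exactly ``k_neighbors``; the matrix is generally not symmetric.
    """

    A: np.ndarray
    k_neighbors: int

    def __post_init__(self) -> None:
        self.A = np.ascontiguousarray(self.A, dtype=np.int8)
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("A must be square")
        if np.any(np.diag(self.A) != 0):
            raise ValueError("A must have a zero diagonal")
        if not np.isin(self.A, (0, 1)).all():
            raise ValueError("A must be binary")
        if np.any(self.A.sum(axis=1) != self.k_neighbors):
            raise ValueError(f"every row must sum to k_neighbors={self.k_neighbors}")

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def in_neighbors_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR (indptr, indices) listing, per site i, the sites that influence i."""
        sp = scipy.sparse.csr_array(self.A)
        return sp.indptr.astype(np.int64), sp.indices.astype(np.int64)

    def fingerprint(self) -> str:
        return hashlib.sha1(self.A.tobytes() + str(self.n).encode()).hexdigest()


def pairwise_correlation(tc: TimeCourses | np.ndarray) -> np.ndarray:
    """Pearson correlation between all site pairs.

    Returns an (n, n) matrix with unit diagonal, symmetric by construction.
    A site with zero temporal variance is an error (its correlation is
    undefined), reported by name.
    """
    if not isinstance(tc, TimeCourses):
        tc = TimeCourses(np.asarray(tc))
    sd = tc.data.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ", ".join(tc.site_ids[i] for i in dead[:5])
        raise ValueError(f"zero-variance site(s): {names}")
    C = np.corrcoef(tc.data)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return C


def validate_connectivity(C: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Check connectivity-matrix invariants; returns the validated array."""
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    if C.ndim != 2 or C.shape != (n, n):
        raise ValueError("connectivity matrix must be square")
    if not np.allclose(C, C.T, atol=atol):
        raise ValueError("connectivity matrix must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=atol):
        raise ValueError("connectivity diagonal must be 1")
    if C.min() < -1 - atol or C.max() > 1 + atol:
        raise ValueError("correlations must lie in [-1, 1]")
    return C


def group_average_connectivity(
    matrices: Sequence[np.ndarray], fisher_z: bool = False
) -> np.ndarray:
    """Elementwise average of per-subject connectivity matrices.

    With ``fisher_z=True`` the average is taken on arctanh-transformed
    off-diagonals and mapped back through tanh; the default is the plain
    arithmetic mean of raw correlations.
    """
    if len(matrices) == 0:
        raise ValueError("need at least one connectivity matrix")
    mats = [validate_connectivity(m) for m in matrices]
    shape = mats[0].shape
    for m in mats[1:]:
        if m.shape != shape:
            raise ValueError("all connectivity matrices must have identical shape")
    if fisher_z:
        eps = 1e-12
        z = np.mean([np.arctanh(np.clip(m, -1 + eps, 1 - eps)) for m in mats], axis=0)
        C = np.tanh(z)
    else:
        C = np.mean(mats, axis=0)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return C


def global_connectivity_map(C: np.ndarray) -> np.ndarray:
    """Per-site mean correlation with every other site (diagonal excluded)."""
    C = validate_connectivity(C)
    n = C.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sites")
    return (C.sum(axis=1) - np.diag(C)) / (n - 1)


def build_interaction_graph(C: np.ndarray, k_neighbors: int) -> InteractionGraph:
    """Wire each site to its ``k_neighbors`` most correlated partners.

    Selection uses the largest *signed* correlations (self excluded); ties
    are broken deterministically in favour of the lowest site index.
    """
    C = validate_connectivity(C)
    n = C.shape[0]
    if not 0 < k_neighbors < n:
        raise ValueError(f"k_neighbors must be in (0, {n}); got {k_neighbors}")
    work = C.copy()
    np.fill_diagonal(work, -np.inf)
    # stable argsort on the negated row keeps ties in index order
    order = np.argsort(-work, axis=1, kind="stable")[:, :k_neighbors]
    A = np.zeros((n, n), dtype=np.int8)
    rows = np.repeat(np.arange(n), k_neighbors)
    A[rows, order.ravel()] = 1
    return InteractionGraph(A=A, k_neighbors=k_neighbors)


def save_graph(graph: InteractionGraph, path: str | Path) -> None:
    """Write the adjacency as MatrixMarket plus a JSON sidecar."""
    path = Path(path)
    if path.suffix != ".mtx":
        path = path.with_suffix(".mtx")
    scipy.io.mmwrite(str(path), scipy.sparse.coo_array(graph.A))
    sidecar = {
        "n": graph.n,
        "k_neighbors": graph.k_neighbors,
        "tie_rule": "lowest-site-index",
        "fingerprint": graph.fingerprint(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_graph(path: str | Path) -> InteractionGraph:
    path = Path(path)
    A = scipy.io.mmread(str(path)).toarray()
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        k = int(meta["k_neighbors"])
    else:
        k = int(A.sum(axis=1)[0])
    return InteractionGraph(A=A, k_neighbors=k)
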