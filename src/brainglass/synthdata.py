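"""Synthetic inputs with the statistical structure the pipeline assumes.

The original resting-state recordings are not distributable, so the package
carries a generative stand-in that reproduces the features the analysis
actually consumes: sites embedded on a cortical-sheet-like surface,
spatially contiguous functional modules, distance-decaying local
correlation, and unstructured noise.  Site activity is a static Gaussian
factor model

    x_i(t) = a * g_m(i)(t) + b * sum_j K_ij eta_j(t) / Z_i + c * eps_i(t)

with independent unit-variance white series g (one per module), eta (one
per site, mixed through the spatial kernel K_ij = exp(-d_ij / lambda)) and
eps (site-private noise).  Z_i is the L2 norm of kernel row i, so each term
contributes a^2, b^2, c^2 to the unit site variance and the model-implied
correlation matrix is available in closed form (`implied_connectivity`),
giving an exact oracle for parameter-recovery tests.

The latent series are temporally white: the downstream model only consumes
static correlations, so temporal spectra are deliberately not emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.spatial.distance

from .connectivity import InteractionGraph, TimeCourses

__all__ = [
    "SyntheticModelSpec",
    "generate_sites",
    "generate_reference_network",
    "module_assignments",
    "generate_modular_bold",
    "implied_connectivity",
]

MEAN_NN_SPACING_MM = 2.5    # ~20 mm^2 patches => ~2.5 mm between patch centres


@dataclass
class SyntheticModelSpec:
    """Parameters of the synthetic resting-state model.

    Weights (a, b, c) are normalised so a^2 + b^2 + c^2 = 1, keeping the
    per-site variance at 1.  Defaults describe a strongly modular cortex
    (module signal dominates, a = 0.8 after normalisation) with a 10 mm
    spatial correlation length.
    """

    n_sites: int = 400
    geometry: str = "sphere"            # "sphere" | "grid"
    n_modules: int = 8
    module_signal_weight: float = 0.8   # a
    spatial_kernel_weight: float = 0.45  # b
    noise_weight: float = 0.45          # c
    decay_length_mm: float = 10.0       # lambda
    n_timepoints: int = 500
    seed: int = 0

    a: float = field(init=False)
    b: float = field(init=False)
    c: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if self.geometry not in ("sphere", "grid"):
            raise ValueError("geometry must be 'sphere' or 'grid'")
        if not 1 <= self.n_modules <= self.n_sites:
            raise ValueError("need 1 <= n_modules <= n_sites")
        if self.decay_length_mm <= 0:
            raise ValueError("decay_length_mm must be positive")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        w = np.array([
            self.module_signal_weight,
            self.spatial_kernel_weight,
            self.noise_weight,
        ], dtype=float)
        if np.any(w < 0) or not w.any():
            raise ValueError("weights must be nonnegative and not all zero")
        w = w / np.linalg.norm(w)
        self.a, self.b, self.c = map(float, w)


def generate_sites(spec: SyntheticModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Site coordinates and the inter-site distance matrix (mm).

    Sphere: quasi-uniform Fibonacci lattice; the radius is scaled so the
    mean nearest-neighbour spacing is ~2.5 mm and distances are great-
    circle arcs (the cortical-surface analogue of geodesic distance).
    Grid: a near-square planar lattice at 2.5 mm pitch with Euclidean
    distances.
    """
    n = spec.n_sites
    if spec.geometry == "sphere":
        # radius such that area-per-site ~ (mean spacing)^2
        R = MEAN_NN_SPACING_MM * np.sqrt(n / (4.0 * np.pi))
        i = np.arange(n)
        golden = np.pi * (3.0 - np.sqrt(5.0))
        z = 1.0 - 2.0 * (i + 0.5) / n
        r = np.sqrt(1.0 - z * z)
        theta = golden * i
        unit = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
        coords = R * unit
        cosang = np.clip(unit @ unit.T, -1.0, 1.0)
        D = R * np.arccos(cosang)
    else:
        side = int(np.ceil(np.sqrt(n)))
        xy = np.array([(i % side, i // side) for i in range(n)], dtype=float)
        coords = np.column_stack([xy * MEAN_NN_SPACING_MM, np.zeros(n)])
        D = scipy.spatial.distance.squareform(
            scipy.spatial.distance.pdist(coords)
        )
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return coords, D


def generate_reference_network(
    kind: str, n: int, k: int, seed: int = 0
) -> InteractionGraph:
    """Reference coupling graphs with known structure for model validation.

    ``ring``: k/2 bidirectional neighbours on each side.  ``lattice2d``: a
    periodic square nearest-neighbour lattice (row sum 4, the classical
    2-D Ising topology).  ``random_regular``: a directed graph with
    in-degree exactly k and no self-loops.
    """
    if not 0 < k < n:
        raise ValueError("need 0 < k < n")
    A = np.zeros((n, n), dtype=np.int8)
    if kind == "ring":
        if k % 2:
            raise ValueError("ring requires even k")
        for off in range(1, k // 2 + 1):
            idx = np.arange(n)
            A[idx, (idx + off) % n] = 1
            A[idx, (idx - off) % n] = 1
    elif kind == "lattice2d":
        side = int(round(np.sqrt(n)))
        if side * side != n:
            raise ValueError("lattice2d requires a square number of sites")
        if k != 4:
            raise ValueError("lattice2d is the nearest-neighbour lattice (k = 4)")
        idx = np.arange(n)
        row, col = idx // side, idx % side
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nb = ((row + dr) % side) * side + (col + dc) % side
            A[idx, nb] = 1
    elif kind == "random_regular":
        rng = np.random.default_rng(seed)
        for i in range(n):
            others = np.delete(np.arange(n), i)
            A[i, rng.choice(others, size=k, replace=False)] = 1
    else:
        raise ValueError(f"unknown reference network kind: {kind!r}")
    return InteractionGraph(A=A, k_neighbors=k)


def module_assignments(spec: SyntheticModelSpec, D: np.ndarray) -> np.ndarray:
    """Spatially contiguous modules by nearest-seed assignment.

    Module seed sites are drawn from the site set with the spec's seed;
    every site joins the module of its nearest seed (ties to the
    lowest-indexed seed), so modules are contiguous patches on the surface.
    """
    rng = np.random.default_rng(spec.seed)
    seeds = np.sort(rng.choice(spec.n_sites, size=spec.n_modules, replace=False))
    return np.argmin(D[:, seeds], axis=1)


def _kernel_rows(spec: SyntheticModelSpec, D: np.ndarray) -> np.ndarray:
    K = np.exp(-D / spec.decay_length_mm)
    Z = np.linalg.norm(K, axis=1, keepdims=True)
    return K / Z


def generate_modular_bold(
    spec: SyntheticModelSpec,
    sites: tuple[np.ndarray, np.ndarray] | None = None,
) -> TimeCourses:
    """Draw one subject's synthetic site time courses from the factor model."""
    if sites is None:
        sites = generate_sites(spec)
    coords, D = sites
    modules = module_assignments(spec, D)
    rng = np.random.default_rng(spec.seed + 1)
    tp = spec.n_timepoints
    g = rng.standard_normal((spec.n_modules, tp))
    eta = rng.standard_normal((spec.n_sites, tp))
    eps = rng.standard_normal((spec.n_sites, tp))
    Kn = _kernel_rows(spec, D)
    data = spec.a * g[modules] + spec.b * (Kn @ eta) + spec.c * eps
    return TimeCourses(data=data, coordinates=coords)


def implied_connectivity(
    spec: SyntheticModelSpec,
    sites: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Exact model-implied correlation matrix of `generate_modular_bold`.

    The three latent families are independent, so the covariance is the sum
    a^2 [same module] + b^2 (Kn Kn^T) + c^2 I with unit diagonal.
    """
    if sites is None:
        sites = generate_sites(spec)
    _, D = sites
    modules = module_assignments(spec, D)
    Kn = _kernel_rows(spec, D)
    C = (
        spec.a**2 * (modules[:, None] == modules[None, :])
        + spec.b**2 * (Kn @ Kn.T)
        + spec.c**2 * np.eye(spec.n_sites)
    )
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return C
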