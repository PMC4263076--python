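"""Metropolis UP/DOWN dynamics on the interaction graph.

Each site i carries a binary state S_i in {+1 (UP), -1 (DOWN)} and interacts
with the sites listed in row i of the interaction graph.  The cost of
flipping site i is the activation energy

    dE_i = 1/2 * S_i * sum_k A[i, k] * S_k

and a flip is accepted with the Metropolis probability min(1, exp(-dE/T)),
where T is the global activation level (the temperature analogue).  At T = 0
the dynamics are strict descent: a flip is accepted iff dE < 0, so every
quench terminates in an absorbing configuration with dE_i >= 0 at all sites.

One time step ("sweep") attempts one update of every site, visiting the
sites in a fresh uniformly random permutation, each attempt evaluated
against the current, partially updated configuration (asynchronous
updating).  Randomness per sweep is consumed in a fixed order: first the
visit permutation, then one uniform draw per attempt with dE > 0 (attempts
with dE <= 0 are accepted without consuming a draw).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.sparse
from numba import njit

from .connectivity import InteractionGraph

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "delta_energy",
    "flip_probability",
    "random_configuration",
    "sweep",
    "simulate",
    "quench",
    "quench_ensemble",
]

_SEED_MOD = 2**31 - 1


def _adjacency(graph: InteractionGraph | np.ndarray) -> np.ndarray:
    """Dense binary adjacency from an InteractionGraph or a raw matrix.

    Raw matrices let tests and reference topologies (e.g. symmetrised
    graphs with unequal in-degrees) drive the same dynamics.
    """
    if isinstance(graph, InteractionGraph):
        return graph.A
    A = np.ascontiguousarray(graph, dtype=np.int8)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    if not np.isin(A, (0, 1)).all():
        raise ValueError("adjacency must be binary")
    return A


def _graph_csr(graph: InteractionGraph | np.ndarray):
    if isinstance(graph, InteractionGraph):
        indptr, indices = graph.in_neighbors_csr()
        return indptr, indices, graph.n, graph.fingerprint()
    A = _adjacency(graph)
    sp = scipy.sparse.csr_array(A)
    fp = hashlib.sha1(A.tobytes() + str(A.shape[0]).encode()).hexdigest()
    return sp.indptr.astype(np.int64), sp.indices.astype(np.int64), A.shape[0], fp


@dataclass
class SimulationConfig:
    """Run parameters for :func:`simulate`.

    T is the global activation level (>= 0); ``n_steps`` counts sweeps;
    ``record_every`` thins the recorded trajectory; ``burn_in`` is carried as
    metadata for downstream metrics (all sweeps are still recorded).
    """

    T: float
    n_steps: int
    seed: int
    burn_in: int = 0
    record_every: int = 1

    def __post_init__(self) -> None:
        if self.T < 0:
            raise ValueError("T must be nonnegative")
        if self.n_steps < 0:
            raise ValueError("n_steps must be nonnegative")
        if self.record_every < 1:
            raise ValueError("record_every must be positive")
        if self.burn_in < 0 or (self.n_steps > 0 and self.burn_in >= self.n_steps):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_steps")


@dataclass
class Trajectory:
    """Recorded state evolution: one +/-1 row per recorded sweep.

    The first record is always the initial configuration; ``sweep_index``
    gives the sweep number of each record in increasing order.
    """

    states: np.ndarray
    sweep_index: np.ndarray
    config: SimulationConfig
    graph_hash: str = ""
    flips_per_sweep: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        self.sweep_index = np.asarray(self.sweep_index, dtype=np.int64)
        if self.states.ndim != 2 or self.states.shape[0] != self.sweep_index.size:
            raise ValueError("states and sweep_index are inconsistent")
        if np.any(np.diff(self.sweep_index) <= 0):
            raise ValueError("sweep_index must be strictly increasing")

    @property
    def n_recorded(self) -> int:
        return self.states.shape[0]

    @property
    def n_sites(self) -> int:
        return self.states.shape[1]

    def recorded_after_burn_in(self) -> np.ndarray:
        """Records with sweep_index >= config.burn_in."""
        return self.states[self.sweep_index >= self.config.burn_in]


def _validate_state(S: np.ndarray, n: int | None = None) -> np.ndarray:
    S = np.ascontiguousarray(S, dtype=np.int8)
    if S.ndim != 1:
        raise ValueError("spin configuration must be a 1-D vector")
    if n is not None and S.size != n:
        raise ValueError(f"spin configuration must have length {n}")
    if not np.isin(S, (-1, 1)).all():
        raise ValueError("spins must be +1 or -1")
    return S


def delta_energy(S: np.ndarray, graph: InteractionGraph | np.ndarray, i: int) -> float:
    """Activation energy of flipping site i: 1/2 * S_i * sum of in-neighbour spins."""
    A = _adjacency(graph)
    S = _validate_state(S, A.shape[0])
    if not 0 <= i < A.shape[0]:
        raise IndexError(f"site index {i} out of range for n={A.shape[0]}")
    return 0.5 * float(S[i]) * float(A[i] @ S.astype(np.int64))


def flip_probability(dE: float, T: float) -> float:
    """Metropolis acceptance min(1, exp(-dE/T)); strict descent at T = 0."""
    if T < 0:
        raise ValueError("T must be nonnegative")
    if T == 0:
        return 1.0 if dE < 0 else 0.0
    return min(1.0, math.exp(-dE / T))


def random_configuration(n: int, rng: np.random.Generator) -> np.ndarray:
    """Each spin independently +1 or -1 with probability 1/2."""
    return (rng.random(n) < 0.5).astype(np.int8) * 2 - 1


def sweep(
    S: np.ndarray,
    graph: InteractionGraph | np.ndarray,
    T: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """One asynchronous Metropolis sweep (reference implementation).

    Returns the updated configuration and the number of accepted flips.
    The compiled kernel behind :func:`simulate` implements the same update
    rule; this NumPy version is the readable single-step path used by tests
    and by callers that need fine-grained control.
    """
    A = _adjacency(graph)
    S = _validate_state(S, A.shape[0]).copy()
    if T < 0:
        raise ValueError("T must be nonnegative")
    accepted = 0
    for i in rng.permutation(A.shape[0]):
        dE = 0.5 * float(S[i]) * float(A[i] @ S.astype(np.int64))
        if T == 0.0:
            flip = dE < 0
        elif dE <= 0:
            flip = True
        else:
            flip = rng.random() < math.exp(-dE / T)
        if flip:
            S[i] = -S[i]
            accepted += 1
    return S, accepted


@njit(cache=True)
def _run_kernel(indptr, indices, S, T, n_steps, record_every, seed, states, flips):
    np.random.seed(seed)
    n = S.shape[0]
    states[0] = S
    rec = 1
    for step in range(1, n_steps + 1):
        perm = np.random.permutation(n)
        acc = 0
        for j in range(n):
            i = perm[j]
            ssum = 0
            for p in range(indptr[i], indptr[i + 1]):
                ssum += S[indices[p]]
            dE = 0.5 * S[i] * ssum
            if T == 0.0:
                flip = dE < 0.0
            elif dE <= 0.0:
                flip = True
            else:
                flip = np.random.random() < np.exp(-dE / T)
            if flip:
                S[i] = -S[i]
                acc += 1
        flips[step - 1] = acc
        if step % record_every == 0:
            states[rec] = S
            rec += 1
    return rec


@njit(cache=True)
def _quench_kernel(indptr, indices, S, max_sweeps, seed):
    np.random.seed(seed)
    n = S.shape[0]
    for sweep_no in range(1, max_sweeps + 1):
        perm = np.random.permutation(n)
        acc = 0
        for j in range(n):
            i = perm[j]
            ssum = 0
            for p in range(indptr[i], indptr[i + 1]):
                ssum += S[indices[p]]
            if 0.5 * S[i] * ssum < 0.0:
                S[i] = -S[i]
                acc += 1
        if acc == 0:
            return sweep_no, True
    return max_sweeps, False


def simulate(
    graph: InteractionGraph | np.ndarray,
    config: SimulationConfig,
    init: np.ndarray | Literal["random"] = "random",
) -> Trajectory:
    """Evolve the system for ``config.n_steps`` sweeps at activation level T.

    A deterministic function of (graph, config, init): the initial state (if
    "random") is drawn from a generator seeded with ``config.seed`` and the
    sweep randomness comes from the compiled kernel's stream seeded with a
    value derived from the same seed.
    """
    indptr, indices, n, fingerprint = _graph_csr(graph)
    rng = np.random.default_rng(config.seed)
    if isinstance(init, str):
        if init != "random":
            raise ValueError("init must be a configuration or 'random'")
        S = random_configuration(n, rng)
    else:
        S = _validate_state(init, n).copy()
    n_rec = 1 + config.n_steps // config.record_every
    states = np.empty((n_rec, n), dtype=np.int8)
    flips = np.zeros(config.n_steps, dtype=np.int64)
    kernel_seed = int(rng.integers(_SEED_MOD))
    _run_kernel(
        indptr, indices, S.copy(), float(config.T), int(config.n_steps),
        int(config.record_every), kernel_seed, states, flips,
    )
    sweep_index = np.concatenate(
        ([0], np.arange(config.record_every, config.n_steps + 1, config.record_every))
    )
    return Trajectory(
        states=states,
        sweep_index=sweep_index,
        config=config,
        graph_hash=fingerprint,
        flips_per_sweep=flips,
    )


def quench(
    graph: InteractionGraph | np.ndarray,
    init: np.ndarray | Literal["random"] = "random",
    rng: np.random.Generator | int | None = None,
    max_sweeps: int = 1000,
) -> tuple[np.ndarray, bool, int]:
    """T = 0 strict descent until an absorbing configuration.

    Repeats T=0 sweeps until one full sweep accepts no flip, or
    ``max_sweeps`` is reached (reported via the flag, never an exception).
    A converged output satisfies dE_i >= 0 at every site.
    """
    if max_sweeps < 1:
        raise ValueError("max_sweeps must be positive")
    indptr, indices, n, _ = _graph_csr(graph)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if isinstance(init, str):
        if init != "random":
            raise ValueError("init must be a configuration or 'random'")
        S = random_configuration(n, rng)
    else:
        S = _validate_state(init, n).copy()
    kernel_seed = int(rng.integers(_SEED_MOD))
    sweeps_used, converged = _quench_kernel(indptr, indices, S, int(max_sweeps), kernel_seed)
    return S, bool(converged), int(sweeps_used)


def quench_ensemble(
    graph: InteractionGraph | np.ndarray,
    n_runs: int,
    seed: int,
    max_sweeps: int = 1000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Independent seeded quenches from random initial configurations.

    Each run owns a child seed derived from ``seed``, so results do not
    depend on execution order.  Returns (patterns, converged flags, seeds).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be positive")
    n = _adjacency(graph).shape[0]
    run_seeds = np.random.SeedSequence(seed).generate_state(n_runs) % _SEED_MOD
    patterns = np.empty((n_runs, n), dtype=np.int8)
    converged = np.empty(n_runs, dtype=bool)
    for r in range(n_runs):
        S, conv, _ = quench(graph, "random", int(run_seeds[r]), max_sweeps)
        patterns[r] = S
        converged[r] = conv
    return patterns, converged, run_seeds.astype(np.int64)
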