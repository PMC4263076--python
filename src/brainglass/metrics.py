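"""Metastability statistics on simulated trajectories.

All statistics are built from Pearson correlations between whole-brain
patterns at different time points:

* lagged correlation series  cc_t = corr(S_t, S_{t+lag});
* homogeneity index  H = <cc> / SD(cc), the reciprocal coefficient of
  variation of the lagged correlations (high H = stereotyped dynamics);
* the slope of log10 H vs log10 lag (scale-free decay of pattern memory);
* dispersion index  D = K <1 - cc> / var(cc) over the off-diagonal entries
  of the all-pairs time-point correlation matrix, with K = 1/12 (the
  variance of the uniform distribution on [0, 1]).  D is small both for
  frozen dynamics (1 - cc -> 0) and for random dynamics (var(cc) large),
  and peaks at the critical activation level;
* metastable-state lifetimes: a maximal run of r consecutive lag-1
  correlations >= a threshold is one state persisting r + 1 time points.

Sample (n-1 denominator) standard deviations and variances are used
throughout.  Undefined statistics (zero spread) are returned as NaN, the
explicit undefined flag, never as an arbitrary number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .repertoire import pattern_similarity, similarity_matrix
from .spinglass import Trajectory

__all__ = [
    "LaggedCorrelationSeries",
    "LifetimeResult",
    "MetricsResult",
    "state_correlation",
    "lagged_correlation_series",
    "state_correlation_matrix",
    "homogeneity_index",
    "powerlaw_slope",
    "dispersion_from_cc",
    "dispersion_index",
    "metastable_lifetimes",
    "compute_metrics",
]

K_UNIFORM = 1.0 / 12.0          # population variance of U(0, 1)
_DEGENERATE_SPREAD = 1e-12      # below this, a spread is rounding, not signal
DEFAULT_CC_THRESHOLD = 0.95
DEFAULT_MS_PER_STEP = 10.0      # labelling only: avalanche-scale ms per sweep
DEFAULT_LAGS = (1, 2, 4, 8, 16, 32)
_MAX_EXACT_RECORDS = 2000


def _as_states(traj: Trajectory | np.ndarray, burn_in: int | None = None) -> np.ndarray:
    if isinstance(traj, Trajectory):
        states = traj.states
        if burn_in is None:
            burn_in = 0
    else:
        states = np.atleast_2d(np.asarray(traj))
        burn_in = burn_in or 0
    if burn_in < 0 or burn_in >= states.shape[0]:
        raise ValueError("burn_in out of range for this trajectory")
    return states[burn_in:]


def state_correlation(s1: np.ndarray, s2: np.ndarray) -> float:
    """Pearson correlation of two global patterns (NaN-free by convention).

    All-UP vs all-UP is 1, all-UP vs all-DOWN is -1, one-sided constants
    correlate 0 with anything non-constant.
    """
    s1 = np.asarray(s1)
    s2 = np.asarray(s2)
    if s1.shape != s2.shape:
        raise ValueError("patterns must have equal length")
    if s1.size < 2:
        raise ValueError("need at least 2 sites")
    return pattern_similarity(s1, s2)


@dataclass
class LaggedCorrelationSeries:
    """cc_t = corr(S_t, S_{t+lag}) for every valid t after burn-in."""

    lag: int
    values: np.ndarray
    burn_in: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.lag < 1:
            raise ValueError("lag must be a positive integer")


def lagged_correlation_series(
    traj: Trajectory | np.ndarray, lag: int = 1, burn_in: int = 0
) -> LaggedCorrelationSeries:
    """Correlation between each pattern and the pattern ``lag`` records later."""
    states = _as_states(traj, burn_in)
    if lag < 1:
        raise ValueError("lag must be a positive integer")
    if lag >= states.shape[0]:
        raise ValueError(
            f"lag {lag} too large for {states.shape[0]} post-burn-in records"
        )
    X = states.astype(float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    vals = np.empty(states.shape[0] - lag)
    for t in range(vals.size):
        a, b = t, t + lag
        if norms[a] == 0 or norms[b] == 0:
            vals[t] = pattern_similarity(X[a], X[b])
        else:
            vals[t] = np.clip(Xc[a] @ Xc[b] / (norms[a] * norms[b]), -1.0, 1.0)
    return LaggedCorrelationSeries(lag=lag, values=vals, burn_in=burn_in)


def state_correlation_matrix(
    traj: Trajectory | np.ndarray, burn_in: int = 0, stride: int = 1
) -> np.ndarray:
    """Full time x time pattern-correlation matrix (optionally thinned)."""
    states = _as_states(traj, burn_in)
    if stride < 1:
        raise ValueError("stride must be positive")
    return similarity_matrix(states[::stride])


def homogeneity_index(series: LaggedCorrelationSeries | np.ndarray) -> float:
    """H = mean / sample SD of the lagged correlations; NaN if SD is 0."""
    values = series.values if isinstance(series, LaggedCorrelationSeries) else np.asarray(series, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 correlation values")
    sd = values.std(ddof=1)
    if sd <= _DEGENERATE_SPREAD:
        return float("nan")
    return float(values.mean() / sd)


def powerlaw_slope(
    H_by_lag: dict[int, float], lag_range: tuple[int, int] = (1, 20)
) -> tuple[float, float]:
    """Least-squares slope of log10 H vs log10 lag over ``lag_range``.

    Returns (slope, R^2).  A constant H is an exact zero-slope fit.  Lags
    with undefined H (NaN) are ignored; a nonpositive H in range is an
    error because its log is meaningless.
    """
    lo, hi = lag_range
    lags = np.array(sorted(l for l in H_by_lag if lo <= l <= hi), dtype=float)
    if lags.size < 2:
        raise ValueError("need H at >= 2 distinct lags in range")
    H = np.array([H_by_lag[int(l)] for l in lags], dtype=float)
    keep = ~np.isnan(H)
    lags, H = lags[keep], H[keep]
    if lags.size < 2:
        raise ValueError("need >= 2 defined H values in range")
    if np.any(H <= 0):
        raise ValueError("power-law fit requires positive H values")
    if np.allclose(H, H[0]):
        return 0.0, 1.0
    fit = scipy.stats.linregress(np.log10(lags), np.log10(H))
    return float(fit.slope), float(fit.rvalue**2)


def dispersion_from_cc(cc: np.ndarray) -> float:
    """D = K <1 - cc> / var(cc) for a given set of correlation elements."""
    cc = np.asarray(cc, dtype=float)
    if cc.size < 2:
        raise ValueError("need at least 2 correlation elements")
    v = cc.var(ddof=1)
    if v <= _DEGENERATE_SPREAD**2:
        return float("nan")
    return float(K_UNIFORM * np.mean(1.0 - cc) / v)


def dispersion_index(
    traj: Trajectory | np.ndarray,
    burn_in: int = 0,
    pair_stride: int | None = None,
) -> float:
    """Dispersion index over all pairs of recorded time points.

    cc is the upper triangle (diagonal excluded) of the all-pairs pattern
    correlation matrix.  For long runs the recorded states are thinned
    deterministically by ``pair_stride`` (every stride-th record); the
    default stride keeps at most 2000 records, so runs up to that length
    are computed exactly.
    """
    states = _as_states(traj, burn_in)
    m = states.shape[0]
    if m < 3:
        raise ValueError("need at least 3 recorded states after burn-in")
    if pair_stride is None:
        pair_stride = max(1, int(np.ceil(m / _MAX_EXACT_RECORDS)))
    if pair_stride < 1:
        raise ValueError("pair_stride must be positive")
    sim = similarity_matrix(states[::pair_stride])
    cc = sim[np.triu_indices(sim.shape[0], k=1)]
    return dispersion_from_cc(cc)


@dataclass
class LifetimeResult:
    """Run-length distribution of metastable states along a trajectory."""

    lifetimes: np.ndarray           # time points per state, each >= 1
    cc_threshold: float
    median_lifetime: float = field(init=False)
    median_lifetime_ms: float | None = None

    def __post_init__(self) -> None:
        self.lifetimes = np.asarray(self.lifetimes, dtype=int)
        self.median_lifetime = float(np.median(self.lifetimes))


def lifetimes_from_cc(cc: np.ndarray, cc_threshold: float = DEFAULT_CC_THRESHOLD) -> np.ndarray:
    """Segment a consecutive-cc series into state lifetimes (time points).

    A maximal run of r consecutive values >= threshold is a state that
    lived r + 1 time points; a record whose neighbouring correlations are
    all below threshold is a state of lifetime 1.
    """
    cc = np.asarray(cc, dtype=float)
    lifetimes = []
    current = 1
    for v in cc:
        if v >= cc_threshold:
            current += 1
        else:
            lifetimes.append(current)
            current = 1
    lifetimes.append(current)
    return np.asarray(lifetimes, dtype=int)


def metastable_lifetimes(
    traj: Trajectory | np.ndarray,
    cc_threshold: float = DEFAULT_CC_THRESHOLD,
    burn_in: int = 0,
    ms_per_step: float | None = None,
) -> LifetimeResult:
    """Lifetimes of metastable states at a cross-correlation threshold.

    ``ms_per_step`` only labels the median in milliseconds (sweeps are
    dimensionless); it never enters the computation.
    """
    states = _as_states(traj, burn_in)
    if states.shape[0] < 2:
        raise ValueError("need at least 2 recorded states")
    cc = lagged_correlation_series(states, lag=1).values
    lifetimes = lifetimes_from_cc(cc, cc_threshold)
    result = LifetimeResult(lifetimes=lifetimes, cc_threshold=cc_threshold)
    if ms_per_step is not None:
        result.median_lifetime_ms = result.median_lifetime * ms_per_step
    return result


@dataclass
class MetricsResult:
    """Bundle of metastability statistics for one trajectory."""

    H_by_lag: dict[int, float]
    powerlaw_slope: float
    powerlaw_r2: float
    D: float
    lifetimes: LifetimeResult
    T: float | None = None

    def to_dict(self) -> dict:
        return {
            "T": self.T,
            "H_by_lag": {str(k): v for k, v in self.H_by_lag.items()},
            "powerlaw_slope": self.powerlaw_slope,
            "powerlaw_r2": self.powerlaw_r2,
            "D": self.D,
            "median_lifetime": self.lifetimes.median_lifetime,
            "median_lifetime_ms": self.lifetimes.median_lifetime_ms,
            "cc_threshold": self.lifetimes.cc_threshold,
        }


def compute_metrics(
    traj: Trajectory,
    lags: tuple[int, ...] = DEFAULT_LAGS,
    burn_in: int | None = None,
    cc_threshold: float = DEFAULT_CC_THRESHOLD,
    pair_stride: int | None = None,
    lag_range: tuple[int, int] = (1, 20),
    ms_per_step: float | None = DEFAULT_MS_PER_STEP,
) -> MetricsResult:
    """All metastability statistics for one trajectory in one pass."""
    if burn_in is None:
        burn_in = int(np.searchsorted(traj.sweep_index, traj.config.burn_in))
    H_by_lag: dict[int, float] = {}
    for lag in lags:
        series = lagged_correlation_series(traj, lag=lag, burn_in=burn_in)
        H_by_lag[lag] = homogeneity_index(series)
    try:
        slope, r2 = powerlaw_slope(H_by_lag, lag_range)
    except ValueError:
        slope, r2 = float("nan"), float("nan")
    D = dispersion_index(traj, burn_in=burn_in, pair_stride=pair_stride)
    lt = metastable_lifetimes(traj, cc_threshold, burn_in=burn_in, ms_per_step=ms_per_step)
    return MetricsResult(
        H_by_lag=H_by_lag, powerlaw_slope=slope, powerlaw_r2=r2,
        D=D, lifetimes=lt, T=traj.config.T,
    )
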