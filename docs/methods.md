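# Methods

## Model

Each of `n` cortical sites carries a binary state `S_i ∈ {+1 (UP), −1
(DOWN)}`. A binary, generally asymmetric interaction graph `A` (row `i`
lists the `k` sites that influence site `i`) defines the activation energy
of flipping site `i`:

    ΔE_i = ½ S_i Σ_k A_ik S_k .

For `k = 16` the possible values are the integers −8 … 8. Dynamics are
single-site Metropolis: a proposed flip is accepted with probability
`min(1, exp(−ΔE_i/T))`, where `T ≥ 0` is the global activation level. For
a *symmetric* graph this chain satisfies detailed balance with respect to
the Boltzmann distribution of the pair energy

    E(S) = −¼ Σ_{i<k} A_ik S_i S_k ,

whose single-flip differences are exactly `ΔE_i`; equivalently, the model
is an Ising system with coupling `J = ¼` per (unordered) coupled pair.
Both facts are exercised directly by the validation suite: exact
enumeration of the 256 states of an 8-spin system reproduces the sampled
distribution to total-variation distance < 0.01, and on the 32×32 periodic
nearest-neighbour lattice the order–disorder crossover brackets the
closed-form critical point `T_c = 2J/ln(1+√2) ≈ 0.567` (mean
|magnetisation| ≈ 0.96 at `T = 0.45`, ≈ 0.08 at `T = 0.75`). For the
asymmetric top-k graphs used in production runs no energy function exists
and the dynamics are taken as the definition of the model.

### Update schedule and randomness

One time step (sweep) attempts one update of every site, visiting sites in
a fresh uniformly random permutation and evaluating each `ΔE_i` against
the current, partially updated configuration. Asynchronous updating was
chosen because synchronous whole-field updates of Ising-type systems have
well-known artificial 2-cycles. Randomness is consumed in a fixed order —
per sweep: the visit permutation first, then one uniform draw per attempt
with `ΔE > 0` (attempts with `ΔE ≤ 0` are accepted without a draw) — so
every run is a deterministic function of its seed. The compiled (numba)
kernel seeds its own stream from the `SimulationConfig` seed; the
pure-NumPy `sweep()` is the readable reference path for single steps.

### T = 0 rule

At `T = 0` flips are accepted iff `ΔE < 0` (strict descent). Accepting
`ΔE = 0` flips would make absorbing configurations impossible on graphs
with balanced neighbourhoods; with strict descent every quench terminates,
and a converged quench certifies `ΔE_i ≥ 0` at every site. Quenches cap at
`max_sweeps = 1000` full sweeps and report convergence via a flag rather
than an exception; in practice quenches on the default networks converge
in well under ten sweeps.

## Interaction graph

The graph is built from a site-by-site Pearson correlation matrix
(empirical or synthetic): row `i` selects the `k = 16` sites with the
largest *signed* correlation to site `i` (self excluded). Ties are broken
toward the lowest site index for reproducibility. Correlation magnitudes
are not used as coupling weights — the adjacency is strictly binary.
Group matrices average per-subject correlation matrices elementwise (a
Fisher-z option exists but is off by default, matching the plain-average
convention). A zero-variance site is an error naming the site, never a
silently propagated NaN.

## Repertoire counting

Quench patterns are smoothed spatially — entry `i` becomes the mean spin
over all sites within `radius` mm of site `i` (self included; radius 0 is
the identity) — and clustered by agglomerative hierarchical clustering
with distance `1 − r` (Pearson correlation of smoothed patterns) and
**complete linkage**, cutting the dendrogram at height `1 − s`. Complete
linkage is the one linkage whose cut certifies that *every* within-cluster
pair has similarity ≥ `s`, which is the semantics "distinct at `s`
similarity" requires; the certificate is checked exhaustively in the test
suite. Defaults are `radius = 15` mm and `s = 0.99`. A pattern and its
global flip have similarity −1 and are distinct states (UP/DOWN maps are
signed). Degenerate correlations follow explicit rules: two equal constant
vectors → 1, exact opposite constants → −1, one constant → 0. Ensembles
larger than 10,000 patterns are clustered on a seeded random subsample
(the all-pairs dendrogram is quadratic in memory); non-converged quenches
are included but flagged, with an exclusion option.

## Metastability statistics

All statistics use sample (n−1) standard deviations and variances, and
undefined values (spread below 1e−12) are returned as NaN rather than an
arbitrary number.

- **Lagged correlation** `cc_t = corr(S_t, S_{t+lag})`, with the same
  degenerate-case rules as pattern similarity.
- **Homogeneity index** `H = ⟨cc⟩ / SD(cc)` per lag (the reciprocal
  coefficient of variation of the lagged correlations).
- **Power-law slope**: least-squares slope of `log₁₀H` vs `log₁₀lag` over
  lags 1–20 by default, with R²; constant `H` is an exact zero-slope fit.
- **Dispersion index** `D = K·⟨1 − cc⟩ / var(cc)` over the upper triangle
  (diagonal excluded) of the all-pairs time-point correlation matrix, with
  `K = 1/12`, the population variance of the uniform distribution on
  [0, 1]. (The size-matched sample variance of uniform draws converges to
  the same constant and only adds noise.) Long runs are thinned
  deterministically (every `pair_stride`-th record); runs of ≤ 2000
  records are computed exactly, and the thinned path is tested against
  brute force.
- **Lifetimes**: along the lag-1 correlation series, a maximal run of `r`
  consecutive values ≥ the threshold (default 0.95) is one state that
  lived `r + 1` time points; an isolated below-threshold record is a state
  of lifetime 1. The optional millisecond labelling multiplies by
  `ms_per_step` (default 10 ms, the neuronal-avalanche timescale) and
  never enters any computation.

### Behaviour of D across T

On the default synthetic modular network (below), the components of `D`
behave as follows, computed by `scripts/acceptance.py` over
`T ∈ [0.5, 4.0]`: the *variance* of the pairwise state correlations peaks
at the network's order–disorder transition (`T ≈ 2.5`), where the cc
distribution is broadest — frozen runs concentrate cc near 1 and
fully decorrelated runs concentrate cc near 0, so `var(cc)` is the
natural criticality marker here. Because `var(cc)` sits in the
*denominator* of `D`, the ratio itself is small near the transition and
grows monotonically on the disordered side (as `T → ∞`, `var(cc)` falls
toward the O(1/n) floor of independent patterns and `D → K/var` rises
without bound); at very low `T` with a post-transient window, `D` is
undefined (0/0) once the dynamics freeze completely. `D` as defined
therefore does **not** show an interior maximum over the grid on this
network — its argmax is the `T = 4` grid end — and the validation test
that encodes an interior-peak expectation for `D` fails by design rather
than being weakened; the acceptance script reports both the `D` curve and
the cc-variance peak location so the two criticality readouts can be
compared. For the `D` sweep the correlation matrix covers the whole
10,000-sweep run from the random initial configuration (no burn-in), which
keeps `D` defined at low `T` through the ordering transient.

## Synthetic data generator

The generator emulates exactly the features the analysis consumes and no
more. Sites are a Fibonacci lattice on a sphere (radius scaled so the mean
nearest-neighbour spacing is ≈ 2.5 mm, the centre-to-centre distance of
~20 mm² patches) with great-circle distances, or a planar grid with
Euclidean distances. Activity is a static Gaussian factor model

    x_i(t) = a·g_{m(i)}(t) + b·Σ_j K_ij η_j(t)/Z_i + c·ε_i(t),

with one shared white series per module (modules are spatially contiguous
nearest-seed patches), a distance kernel `K_ij = exp(−d_ij/λ)` with rows
normalised to unit L2 norm, and site-private noise. Weights are normalised
so `a² + b² + c² = 1`, making every site unit-variance and the implied
correlation matrix available in closed form
(`a²·[same module] + b²·(K̂K̂ᵀ)`), which serves as the exact oracle for
parameter recovery (empirical correlations at 20,000 timepoints match it
to < 0.03 everywhere, tested at ±0.05). Defaults: 400 sites, 8 modules,
`a : b : c = 0.8 : 0.45 : 0.45` before normalisation (a strongly modular
cortex whose top-16 wiring stays > 80% within modules when modules are
larger than the neighbourhood), `λ = 10` mm, 500 timepoints.

What the generator does *not* emulate: temporal autocorrelation and
hemodynamics (the model consumes only static correlations), scanner noise,
subject variability, and the hub-dominated degree structure of real
cortical connectivity. Passing tests therefore validate the machinery and
its statistical contracts, not the empirical claim that real-brain
connectivity produces any particular repertoire size or critical level —
those quantities depend on the (non-distributable) group fMRI matrix.

## Protocol defaults and problem sizes

The pipeline's quench protocol defaults to 10,000 runs (the repertoire
protocol scale); validation runs use 150–1,000 quenches on 120–400-site
networks, which already resolve the module-combination repertoire. The
temperature sweep defaults to `T ∈ [0, 4]` in steps of 0.1 with 3 seed
replicates and 10,000 sweeps per run; the validation sweep uses a 0.5-step
grid over [0.5, 4.0]. Every run derives all child seeds from a single
configured seed (`SeedSequence` splitting, values kept below 2³¹), so
reports are bit-reproducible and independent of execution order.

## Known limitations

- For asymmetric graphs there is no Lyapunov/energy function; "quench
  convergence" means an absorbing configuration of the dynamics, not a
  minimum of a global objective.
- At high `T` the Metropolis cap (`p = 1` for `ΔE ≤ 0`) makes most
  attempts succeed, producing anti-persistent consecutive patterns
  (negative lag-1 correlation) rather than ideal white randomness.
- The dispersion index inherits the definitional issue described above;
  treat `var(cc)` (reported alongside) as the robust criticality marker
  on synthetic networks.
- Complete-linkage clustering of very large ensembles uses a subsample;
  counts at the default 10,000-pattern cap are exact.
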