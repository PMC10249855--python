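# Methods

`mhnet` analyses panels of daily, state-level survey indicators (the
percentage of respondents reporting anxiety, depression, or financial
worry) as weighted signed networks, and summarizes how the strength and
structure of inter-state similarity evolved across the epidemic waves of
2021. This note records the model assumptions, the numerical choices,
and what the synthetic benchmark does and does not establish.

## Static analysis

**Correlation network.** For each indicator, every pair of states
(x, y) is scored by the Pearson correlation of their daily series over
the analysis range,

    P[x,y] = Σ_t (x_t − x̄)(y_t − ȳ) / √( Σ_t (x_t − x̄)² · Σ_t (y_t − ȳ)² ).

All coefficients are kept — no magnitude cut-off — so the adjacency is
the full signed matrix. Correlations are computed on the raw daily
values; an optional per-unit linear `detrend` exists but defaults off,
because shared slow trends are part of the similarity being measured.
Exact zeros are absent edges. A constant series leaves the coefficient
undefined and raises by default.

**Signed split.** The network is decomposed into a positive layer
(`max(P, 0)`, zero diagonal) and a negative layer (`max(−P, 0)`). The
decomposition is exact: `positive − negative` equals the off-diagonal
matrix bit-for-bit.

**Community detection.** Communities are found by Leiden optimization of
a two-layer multiplex quality: configuration-null (Newman–Girvan at
resolution 1; the resolution is exposed) modularity on the positive
layer with weight +1 and on the negative layer with weight −1, via
`leidenalg.find_partition_multiplex`. This rewards dense positive
connectivity within communities and penalizes internal anticorrelation.

**Consensus clustering.** Leiden output is stochastic, so a partition is
stabilized by iterated consensus: `n_runs` independent runs (default
300; run seeds are drawn from a master seed by a counter scheme, so the
whole procedure is reproducible), a co-assignment frequency matrix F,
then re-clustering of F as an all-positive weighted network, repeated
until every entry of F is within 1e−12 of 0 or 1 (at most `max_iter`=10
cycles; non-convergence returns the last partition with a flag). F is
re-clustered unthresholded by default; a Lancichinetti–Fortunato style
τ-threshold is available. When F is binary its connected components are
the consensus communities. Singleton communities are allowed.

**Allegiance.** The final consensus partitions of the three indicators
combine into an allegiance matrix A — the fraction of indicators in
which two states share a community (entries in {0, 1/3, 2/3, 1}) —
which is clustered by the same consensus procedure, treating A as an
all-positive network.

## Dynamic connectome

A 30-day window slides across the range in 1-day steps (both
configurable; a 315-day range yields 286 windows). Per window the
correlation network is rebuilt and summarized per group (Census region
or 2020-party grouping) by

* the unweighted mean of P[x,y] over unordered within-group pairs, and
* the group mean of eigenvector centrality.

Windows are labeled by their start date, and a window belongs to an
epidemic wave iff its start date lies inside the wave interval; windows
starting before the first wave belong to no wave and are excluded from
wave summaries (their count is logged). Per (group, wave, indicator,
metric) the curve's minimum and maximum are tabulated.

**Centrality conventions.** Eigenvector centrality needs a nonnegative
matrix, and the signed network keeps every coefficient, so the default
connectivity is |P| with zeroed diagonal; a positive-part-only mode is
available. The leading eigenvector is computed by dense symmetric
eigendecomposition (`numpy.linalg.eigh`; networks have ≤ ~51 nodes), its
sign fixed so all entries are ≥ 0 (Perron–Frobenius), and it is
normalized to unit Euclidean norm — under which the maximum entry of a
51-state network is typically well below 1, rather than being pinned to
1 as max-norm would force.

**Degenerate windows.** A unit constant within one window would poison
that window only; by default its coefficients are set to 0 for that
window with a warning, while `strict=True` raises instead.

## Synthetic benchmark

The generator plants the structure the analysis is meant to find. Unit
*i* in group *g* follows

    x_i(t) = baseline_g + wave(t)·scale_g
             + noise_sd · ( √snr_g(t) · s_g(t) + √(1−snr_g(t)) · ε_i(t) ),

with `s_g` a standardized Gaussian AR(1) (φ = 0.9 — smooth, trend-like
series; white latents would make 30-day windows behave unlike slowly
varying survey curves) and ε i.i.d. standard normal. Both processes
have unit variance, so the expected within-group correlation equals
`snr` and the expected between-group correlation is 0. Values are
clipped to the percent scale [0, 100] after calibration; calibration
tests keep baselines far from the bounds so clipping is inactive.
`snr` can be overridden on day intervals per group, which plants a
time-localized connectivity change for the sliding window to detect.

Study-scale defaults: 51 units, 315 daily values starting 2021-03-02,
baselines 19 / 12 / 35 percent for the three indicators (typical survey
levels), noise_sd 2 percentage points, snr 0.8, and three shared
half-sine wave bumps (amplitudes 4–6 points) at the configured wave
dates. Waves are national with per-group amplitude multipliers.

**What the benchmark does not emulate:** survey sampling error and
respondent counts, platform-recruitment bias, spatial autocorrelation
beyond group membership, heavy-tailed or skewed indicator noise, and
reporting artifacts (weekday effects, holidays). Recovery of planted
groups therefore demonstrates correctness of the pipeline, not that
real survey panels contain equally clean structure.

**Problem sizes.** The packaged tests and the acceptance script run the
full pipeline at the study scale (51 units × 315 days × 3 indicators)
but with 50-run consensus and 10–20 replicates — sizes at which every
stage's behaviour is already stable, as the run-count stability test
shows (25- vs 75-run consensus agree exactly on planted networks).

## Known limitations

* With only ~300 days of highly autocorrelated signal, the sample
  correlation between two *independent* group latents has standard
  deviation ≈ √((1+φ²)/((1−φ²)·n)) ≈ 0.18; occasionally two planted
  groups correlate ≈ 0.3 by chance across most of the range, and the
  consensus clustering then genuinely (and correctly, given the data)
  merges them for that indicator. The allegiance step usually repairs a
  single merged indicator; a replicate where two indicators merge
  different pairs can leave the allegiance partition coarser than
  planted. This is a small-sample property of autocorrelated series,
  visible in the acceptance report as an occasional min-ARI below the
  median.
* Wave membership is keyed to window start dates; a window near a wave
  boundary mixes days from two waves, so extrema near boundaries are
  smoothed. The first ~30 days of the analysis range produce windows
  assigned to no wave.
* Modularity at resolution 1 carries the usual resolution limit; very
  small planted groups inside a large network may not separate. The
  resolution parameter is exposed throughout.
* The regional and party groupings ship as editable CSV fixtures; the
  party table uses the 2020 presidential winner per state and can be
  replaced where a senate/registration-adjusted classification is
  preferred.
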