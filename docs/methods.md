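# Methods

This note documents the models, estimators and design choices behind
`hprw`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, with
which defaults, and where the genuinely open choices were made.

## Track model and units

Tracks live on a regular acquisition grid: frame `k` occurs at
`k · Δt` minutes, with `Δt = 0.5` min by default (two-photon/confocal
volumes every ~30 s). Positions are micrometres. A track stores only its
observed frames; interior frames missing from the file are *gaps*,
reconstructed on read and represented explicitly by a per-slot mask in
memory. Timestamps (when the export carries time rather than frame
indices) are snapped to the nearest grid frame; a deviation beyond 25% of
`Δt` is an error rather than a new frame, because acquisition grids are
regular and larger deviations indicate a wrong `Δt` or a corrupted export.
Duration is the frame span times `Δt` (gaps included), matching how
tracking software reports track length.

## The heterogeneous persistent random walk

Velocities evolve as `u_t = q_t u_{t−1} + a_t n_t` with `n_t` standard 3D
Gaussian noise, persistence `q_t ∈ [−1, 1]` and activity `a_t ≥ 0`
(µm/min). The model is Markovian at the frame scale; all statistics below
are exact consequences used as test oracles:

- stationary per-component velocity variance `a²/(1−q²)` for `|q| < 1`;
- for `q = 0`, speeds are chi(3)-distributed with mean `a·√(8/π)`;
- for `q = 0`, ensemble MSD after `n` steps is `3a²Δt²n`;
- `(q, a) = (1, 0)` gives straight constant-speed motion with
  `MSD(τ) = (vτ)²`.

The simulator integrates positions forward-Euler,
`x_{t+1} = x_t + u_t Δt` — the simplest scheme consistent with a model
stated on velocities. Initial velocities are drawn from the stationary
distribution by default so short tracks carry no transient; a zero mode
and an explicit `u0` exist for closed-form tests. Gaps are i.i.d. per
interior slot (no burst model; no gap statistics are available to fit
one), and endpoints are never removed so gap injection preserves duration.
Dead cells are generated as `(q, a) = (0, 0)` and carry a population
label; their removal downstream is an explicit, logged filter — the
package's substitute for the manual dead-cell curation done on real data.

The default cohort mixes a fast persistent mode (q = 0.7, a = 3 µm/min),
a slow persistent mode (0.7, 1), a slow meandering mode (0.2, 0.6) and a
10% immobile fraction, with track durations uniform between 8 and 60
frames (4–30 min) and a 2% gap rate — values chosen once to bracket the
motility modes of activated T cells in collagen at 30 s framing.

What the generator deliberately does *not* emulate: localization noise on
positions, confinement or matrix geometry, cell–cell interactions, and
burst-like acquisition dropouts. Passing tests therefore demonstrate
correctness of the estimators under the model's own assumptions, not
robustness to every artifact of real imaging data.

## Velocity estimators — a deliberate pair

Two estimators coexist, and the distinction matters:

- **Frame speeds / forward velocities** `(x_{t+1} − x_t)/Δt` over
  consecutive observed pairs — the tracking-software convention. Used for
  mean track speed and the arrest coefficient, and (as `scheme="forward"`,
  the default) for the model likelihood.
- **Centered velocities** `(x_{t+1} − x_{t−1})/(2Δt)`, valid only where
  three consecutive slots are observed — the second-order instantaneous
  velocity estimate. Used for eligibility counting (a "valid velocity
  measurement" requires three consecutive positions; any gap invalidates
  its neighbors) and selectable for inference (`scheme="central"`).

For finely sampled, smoothly varying motion the centered scheme is the
better velocity estimate. But when velocity decorrelates on the frame
scale — which is exactly the regime of the discrete AR(1) model — the
centered difference equals the two-step average `(u_{t−1} + u_t)/2`, an
MA(1)-smoothed series whose lag-1 correlation is `(1+q)/2` rather than
`q`. Fitting the AR(1) to it systematically inflates persistence (a true
q of 0.6 reads as ≈ 0.78) and deflates activity. The forward difference,
by contrast, recovers the model velocity exactly under per-frame
integration, so it is the default for inference; the choice is exposed so
users working with oversampled data can switch.

## Motility metrics and filters

Arrest uses a strict `< 2 µm/min` threshold on frame speeds (a speed of
exactly 2 is not arrested). The ensemble MSD is referenced to each
track's first observed frame and averages squared displacements across
tracks observed gap-free for at least 10 min (configurable); a
time-averaged sliding-origin variant exists behind a flag. Turning angles
are computed between successive displacement vectors over consecutive
observed triples and skip steps shorter than 0.2 µm, where the angle
would be dominated by localization noise; degenerate zero-length steps
therefore never produce NaN.

Filter presets: `speed_2d3d` (≥ 4 min and ≥ 15 µm net displacement),
`blebbistatin` (≥ 4 min only), `clustering` (≥ 240 s and ≥ 15 valid
velocity measurements), `invivo` (≥ 5 min). The displacement criterion is
*net* (start→end) displacement; path length is an alternative reading and
the threshold field is configurable. All exclusions are logged per track
with the failed criteria.

## Sequential inference

The `(q, a)` plane is discretized uniformly: 101 q-nodes on `[−1, 1]` and
100 a-nodes on `(0, 10]` µm/min. `a = 0` is excluded because the
Gaussian likelihood is singular there; the smallest activity is one grid
spacing (0.1 µm/min). The 10 µm/min ceiling is roughly twice the mean
speed of fast T cells; inference spans the full `q ∈ [−1, 1]` even though
contour reporting conventionally restricts to `[0, 1]`.

Filtering is forward-only (no backward smoothing): the prior at the first
update is uniform; at each slot with a consecutive valid velocity pair the
posterior is `normalize(prior × likelihood)` (computed in log space with a
max-shift, so long runs cannot underflow); the prior for the next slot is
the posterior convolved with a separable boxcar kernel, reflected at the
grid edges and renormalized. Slots without a valid pair propagate the
spread prior, so the posterior keeps diffusing across a gap without
fabricating an update. Pairs are only formed from velocities at adjacent
slots. Point estimates are posterior means — stabler than the MAP on
plateaued posteriors — and the per-cell summary `(q̄, ā)` is the
arithmetic mean of the per-step estimates.

**Kernel width.** The boxcar half-width controls the bias–responsiveness
trade-off: width 0 is static-parameter Bayes (the posterior cannot move),
larger widths let the estimate track drift at the cost of extra smoothing
bias in constant regimes. The default half-width is 4 grid cells per
axis: it is the smallest boxcar for which an abrupt persistence switch
(0.8 → 0.2) is registered by the windowed estimate within ±20 steps on
essentially all simulated tracks (96–100% across seeds; half-width 2
manages only ~66%), while constant-regime recovery of `(0.6, 2 µm/min)`
remains within ±0.03 in q and ~4% in a. The width is a configuration
knob recorded in run manifests.

Change points are read off with `detect_persistence_crossing`: the
per-step `q̂` series is smoothed with a centered 21-step moving average
(edge-padded so early estimates are not diluted toward zero) and the last
downward crossing of the threshold is reported. Forward filtering has an
intrinsic detection lag of roughly 10–15 steps at the default settings.

## Sub-population clustering

Features `(q̄, ā)` are z-standardized before both DBSCAN and k-means
because persistence is unitless while activity is in µm/min; centroids
are reported back in original units. DBSCAN (eps = 0.5 standardized
units, min_pts = 5 — unspecified upstream, so defaults are logged and
tunable) only flags noise points as outliers; it never defines clusters.
k-means runs with 10 seeded restarts, keeping the lowest
within-cluster sum of squares; mean silhouette widths for k = 2..6 are
reported as a diagnostic only — k is an explicit configuration choice
(presets: 4 for matrix-density experiments, merged to three modes; 3 for
inhibitor experiments).

Cluster→mode labelling is a deterministic geometric rule, because modes
are named but no assignment rule exists to inherit: with k = 4 the two
lowest-activity centroids merge into `↓a↓q` (one of them is typically the
near-immobile mode), the highest-activity centroid is `↑a↑q`, the
remaining one `↓a↑q`; with k = 3, highest activity is `↑a↑q` and the
higher-persistence centroid of the rest is `↓a↑q`. Activity ties break by
persistence (lower q merges first) and are noted. Because the rule
depends only on centroid geometry it is invariant to cluster index
permutation and makes bootstrap repetitions comparable without centroid
matching — this tag-identity convention is this package's answer to an
otherwise unstated matching problem.

The bootstrap resamples cells with replacement (same n), reruns the whole
procedure — outlier removal included — per repetition (100 by default),
and reports mean and SD of the merged proportions and of their cumulative
sums (the quantity drawn as stacked bars; both SDs are emitted since
either may be wanted for whiskers). Degenerate resamples (fewer inliers
than clusters) are redrawn and counted. A faster fixed-inlier mode is a
flag away for large cohorts.

Condition contrasts use the two-population proportion z-test with pooled
variance; when the pooled proportion is 0 or 1 the statistic is undefined
and p = 1 is returned.

## Highest-density-region contours

Per-step `(q̂, â)` pairs are binned on a bivariate histogram
(default 25 × 25 over `q ∈ [0, 1]` and `a ∈ (0, a_max]`; out-of-domain
pairs are excluded and counted) and normalized to probability mass.
For each level (50/80/95%) the HDR is built greedily: bins are added in
decreasing mass order — ties broken deterministically by bin index — until
the accumulated mass first reaches the level. This makes the region
*minimal* (dropping its lowest-mass bin falls below the level), which the
alternative "include the whole tied density class" rule cannot guarantee
on integer-count histograms; determinism is preserved by the stable tie
order. Thresholds (mass of the last included bin) are non-increasing from
the 50% to the 95% level, and marginal histograms are row/column sums.

## Pipeline and reproducibility

One global seed drives everything; per-stage generators are derived by
seed-sequence spawning, so changing the bootstrap repetition count cannot
perturb simulation draws. Run manifests echo the configuration, package
version, per-stage counts (which must reconcile: tracks read = analyzed +
excluded) and wall-clock timings. Identical configurations produce
byte-identical artifact files: track CSVs are written with `%.17g` and
read with round-trip float parsing, so positions survive a write/read
cycle exactly.

## Problem sizes and known limitations

Verification runs use desk-scale sizes chosen to make the statistical
bounds sharp at interactive runtimes: 100 tracks × 300 steps for
constant-regime recovery, 50 tracks for regime tracking, 1000 short
tracks for the Brownian MSD, 300 cells × 100 bootstrap repetitions for
mixture recovery, 10⁴ points for contour mass.

Limitations worth knowing: the inference is forward-only, so estimates
lag regime changes by ~10–15 steps and no retrospective smoothing is
offered yet; measurement noise on positions is neither simulated nor
modelled (a noise-aware likelihood is a natural extension); the grid
ceiling `a_max = 10 µm/min` must be raised for faster cells; and the
bootstrap treats cells as exchangeable, ignoring any within-experiment
correlation structure.
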