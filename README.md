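# hprw — heterogeneous persistent random walk analysis of 3D cell tracks

`hprw` analyzes cohorts of tracked migrating cells — T cells moving through
collagen matrices or lymph node tissue are the motivating case — from
position tables exported by tracking software. It provides, as one tested
pipeline:

- **Classical motility metrics** with the standard eligibility filters:
  mean track speed, arrest coefficient (fraction of timepoints below
  2 µm/min), ensemble mean squared displacement, turning angles.
- **Per-cell, time-resolved Bayesian inference** of migratory *persistence*
  and *activity* under a heterogeneous persistent random walk model.
- **Sub-population analysis**: DBSCAN outlier removal, k-means clustering
  of cells in parameter space, deterministic mode labelling, bootstrap
  stability of mode proportions, two-population proportion z-tests, and
  highest-density-region contour summaries.
- **A synthetic cohort generator** implementing the same model with ground
  truth, so every stage is testable end to end.

## The model

The cell velocity follows a first-order autoregressive (AR(1)) process,

```
u_t = q_t · u_{t−1} + a_t · n_t
```

where `q_t ∈ [−1, 1]` is the instantaneous **persistence** (directional
memory between successive velocity vectors: `(q, a) = (1, 0)` is straight
constant-speed motion, `q = 0` is velocity-memoryless Brownian motion),
`a_t ≥ 0` (µm/min) is the **activity** setting the amplitude of velocity
fluctuations, and `n_t` is standard 3D Gaussian noise with no temporal
memory. Because `(q_t, a_t)` may vary in time and across cells, the walk
is *heterogeneous*.

Given a track's velocity series, one consecutive velocity pair has
likelihood `L(q, a) = (2π a²)^{−3/2} exp(−‖u_t − q u_{t−1}‖² / (2a²))`.
The `(q, a)` plane is discretized (101 × 100 grid by default, `q ∈ [−1, 1]`,
`a ∈ (0, 10]` µm/min) and filtered sequentially: each posterior, convolved
with a small boxcar kernel, becomes the prior for the next step, so the
estimate can follow parameter drift. Per-step posterior means `(q̂_t, â_t)`
are averaged into one `(q̄, ā)` per cell for cells tracked ≥ 240 s with
≥ 15 valid velocity measurements; k-means in that plane (k = 4, or k = 3
for inhibitor-style experiments) yields three motility modes —
`↑a↑q`, `↓a↑q`, `↓a↓q` — whose proportions are compared across conditions.

## Worked example

`examples/03_random_walk_inference.py` simulates one cell whose persistence
drops from 0.8 to 0.2 at step 150 of 300 (e.g. a cell entering a denser
matrix region) and runs the filter:

```
steps   0- 49: q_hat = 0.73  a_hat = 2.20 µm/min
steps  50- 99: q_hat = 0.79  a_hat = 1.97 µm/min
steps 100-149: q_hat = 0.73  a_hat = 2.07 µm/min
steps 150-199: q_hat = 0.37  a_hat = 2.07 µm/min
steps 200-249: q_hat = 0.17  a_hat = 2.07 µm/min
steps 250-299: q_hat = 0.15  a_hat = 2.10 µm/min

True switch at step 150; windowed estimate crosses q = 0.5 at step 165.
```

The persistence estimate sits near the true 0.8 before the switch, falls to
the true 0.2 after it, and the detected change point lands 15 steps after
the truth (the intrinsic lag of forward filtering), while the activity
estimate stays at the true 2 µm/min throughout.

`examples/04_subpopulations.py` takes a 150-cell mixed cohort through
inference and clustering:

```
122 of 150 cells eligible for clustering
1 density outliers removed
↑a↑q: 0.40   ↓a↑q: 0.25   ↓a↓q: 0.36
bootstrap (100 reps): 0.395 ± 0.042 / 0.248 ± 0.042 / 0.357 ± 0.051
```

matching the generator's 40/25/35 mixture (the low mode pools the slow
meandering and dead-cell populations).

The other examples cover cohort simulation with validation
(`01_simulate_cohort.py`), motility metrics and filters
(`02_motility_metrics.py`) and the one-call pipeline
(`05_full_pipeline.py`). A CLI mirrors the stages:
`hprw simulate | metrics | infer | cluster | run`.

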