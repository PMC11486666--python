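"""Synthetic trajectory cohorts from the heterogeneous persistent random walk.

The velocity of a cell evolves as a first-order autoregressive process

    u_t = q_t * u_{t-1} + a_t * n_t,

with persistence ``q_t`` in [-1, 1], activity ``a_t`` >= 0 (µm/min) and
``n_t`` standard 3D Gaussian noise with no temporal memory.  ``(q, a) =
(1, 0)`` is straight constant-speed motion, ``q = 0`` is velocity-memoryless
(Brownian) motion.  Positions are integrated forward-Euler:
``x_{t+1} = x_t + u_t * dt``.

Cohorts mix sub-populations with distinct ``(q, a)`` plus an optional
immobile ("dead-cell") fraction, and can drop interior observations to
emulate acquisition gaps.  Every draw is controlled by an explicit seed so
identical configurations give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .tracks import AcquisitionSpec, Track, TrackTable

__all__ = [
    "ParamPath",
    "PopulationSpec",
    "SimulationConfig",
    "sample_parameter_path",
    "simulate_track",
    "simulate_cohort",
    "inject_gaps",
    "default_cohort_config",
]


@dataclass
class ParamPath:
    """Per-step (q, a) values driving one simulated track."""

    q: np.ndarray
    a: np.ndarray
    regime: str = "constant"

    def __post_init__(self) -> None:
        self.q = np.atleast_1d(np.asarray(self.q, dtype=float))
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        if self.q.shape != self.a.shape:
            raise ValueError("q and a paths must have equal length")
        if np.any((self.q < -1) | (self.q > 1)):
            raise ValueError("persistence q must lie in [-1, 1]")
        if np.any(self.a < 0):
            raise ValueError("activity a must be >= 0")

    @property
    def n_steps(self) -> int:
        return int(self.q.size)


def sample_parameter_path(
    regime: str, params: dict, n_steps: int, rng: np.random.Generator | None = None
) -> ParamPath:
    """Build a (q_t, a_t) path for one track.

    Regimes
    -------
    ``constant``: ``params = {"q": float, "a": float}``.
    ``step``: ``{"q0", "a0", "q1", "a1", "switch_step"}`` — values switch at
    ``switch_step`` (0-based; steps before it use the initial values).
    ``smooth``: ``{"q0", "a0", "q1", "a1"}`` — linear interpolation from the
    first step to the last.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if regime == "constant":
        q = np.full(n_steps, float(params["q"]))
        a = np.full(n_steps, float(params["a"]))
    elif regime == "step":
        s = int(params["switch_step"])
        q = np.where(np.arange(n_steps) < s, float(params["q0"]), float(params["q1"]))
        a = np.where(np.arange(n_steps) < s, float(params["a0"]), float(params["a1"]))
    elif regime == "smooth":
        q = np.linspace(float(params["q0"]), float(params["q1"]), n_steps)
        a = np.linspace(float(params["a0"]), float(params["a1"]), n_steps)
    else:
        raise ValueError(f"unknown regime {regime!r}")
    return ParamPath(q=q, a=a, regime=regime)


def _initial_velocity(
    q0: float, a0: float, mode: str, rng: np.random.Generator
) -> np.ndarray:
    if mode == "zero":
        return np.zeros(3)
    if mode == "stationary":
        # per-component stationary variance a^2 / (1 - q^2) for |q| < 1
        if abs(q0) < 1:
            sigma = a0 / np.sqrt(1.0 - q0 * q0)
            return rng.normal(0.0, sigma, size=3)
        return np.zeros(3)
    raise ValueError(f"unknown initial_speed_mode {mode!r}")


def simulate_track(
    path: ParamPath,
    acquisition: AcquisitionSpec | None = None,
    rng: np.random.Generator | None = None,
    initial_speed_mode: str = "stationary",
    track_id: str = "sim-0",
    condition: dict[str, str] | None = None,
    u0: np.ndarray | None = None,
) -> tuple[Track, np.ndarray]:
    """Simulate one track; returns ``(track, u)``.

    ``u`` holds the true velocities ``u_0 .. u_n`` (µm/min); the track has
    ``n + 1`` positions starting at the origin, one per frame slot, with
    ``x_{t+1} = x_t + u_t * dt``.  The initial velocity is drawn from the
    stationary distribution N(0, a0²/(1-q0²)) per component by default
    (zero when |q0| = 1), set to zero in ``"zero"`` mode, or fixed
    explicitly via ``u0`` (useful for the straight-line limit q=1, a=0).
    """
    acquisition = acquisition or AcquisitionSpec()
    rng = rng if rng is not None else np.random.default_rng()
    n = path.n_steps
    dt = acquisition.frame_interval

    u = np.empty((n + 1, 3))
    if u0 is not None:
        u[0] = np.asarray(u0, dtype=float)
    else:
        u[0] = _initial_velocity(path.q[0], path.a[0], initial_speed_mode, rng)
    noise = rng.standard_normal((n, 3))
    for t in range(n):
        u[t + 1] = path.q[t] * u[t] + path.a[t] * noise[t]

    x = np.vstack([np.zeros(3), np.cumsum(u[:-1] * dt, axis=0)])
    track = Track(
        track_id=track_id,
        frames=np.arange(n + 1),
        positions=x,
        condition=dict(condition or {}),
    )
    return track, u


@dataclass
class PopulationSpec:
    """One sub-population of a simulated cohort.

    ``n_steps`` may be a single step count or an inclusive ``(lo, hi)``
    range sampled uniformly per cell.  ``immobile`` forces (q, a) = (0, 0),
    emulating dead cells that tracking software picks up but a manual
    curation pass would discard.
    """

    label: str
    fraction: float
    q: float = 0.0
    a: float = 0.0
    n_steps: int | tuple[int, int] = 20
    immobile: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.fraction <= 1:
            raise ValueError(f"fraction must be in [0, 1], got {self.fraction}")
        if self.immobile:
            self.q = 0.0
            self.a = 0.0
        if not -1 <= self.q <= 1:
            raise ValueError("q must lie in [-1, 1]")
        if self.a < 0:
            raise ValueError("a must be >= 0")

    def draw_n_steps(self, rng: np.random.Generator) -> int:
        if isinstance(self.n_steps, tuple):
            lo, hi = self.n_steps
            return int(rng.integers(lo, hi + 1))
        return int(self.n_steps)


@dataclass
class SimulationConfig:
    populations: list[PopulationSpec]
    n_cells: int = 100
    frame_interval: float = 0.5
    gap_rate: float = 0.0
    seed: int = 0
    initial_speed_mode: str = "stationary"

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0 <= self.gap_rate < 1:
            raise ValueError("gap_rate must be in [0, 1)")
        total = sum(p.fraction for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"population fractions must sum to 1, got {total}")


def allocate_counts(fractions: Sequence[float], n: int) -> list[int]:
    """Largest-remainder allocation of ``n`` cells to population fractions."""
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def inject_gaps(
    track: Track, gap_rate: float, rng: np.random.Generator
) -> Track:
    """Remove interior observations independently with probability ``gap_rate``.

    The first and last observations are never removed, so the track's span
    and duration are preserved.
    """
    if not 0 <= gap_rate < 1:
        raise ValueError("gap_rate must be in [0, 1)")
    if gap_rate == 0 or track.n_observed <= 2:
        return track
    keep = rng.random(track.n_observed) >= gap_rate
    keep[0] = True
    keep[-1] = True
    return Track(
        track_id=track.track_id,
        frames=track.frames[keep],
        positions=track.positions[keep],
        condition=dict(track.condition),
    )


def simulate_cohort(config: SimulationConfig) -> tuple[TrackTable, pd.DataFrame]:
    """Simulate a cohort; returns ``(table, ground_truth)``.

    Cells are allocated to populations by largest-remainder rounding of the
    fractions.  The ground-truth table records, per cell and step, the true
    ``(q, a)`` and the population label
    (columns ``track_id,population,step,q_true,a_true``).
    Identical config (including seed) gives identical output.
    """
    acquisition = AcquisitionSpec(frame_interval=config.frame_interval)
    root = np.random.SeedSequence(config.seed)
    rng_pop, rng_gap = [np.random.default_rng(s) for s in root.spawn(2)]

    counts = allocate_counts([p.fraction for p in config.populations], config.n_cells)
    tracks: list[Track] = []
    truth_rows = []
    cell = 0
    for pop, count in zip(config.populations, counts):
        for _ in range(count):
            n_steps = pop.draw_n_steps(rng_pop)
            path = sample_parameter_path("constant", {"q": pop.q, "a": pop.a}, n_steps)
            tid = f"sim-{cell:04d}"
            track, _ = simulate_track(
                path,
                acquisition,
                rng_pop,
                initial_speed_mode=config.initial_speed_mode,
                track_id=tid,
                condition={"population": pop.label},
            )
            track = inject_gaps(track, config.gap_rate, rng_gap)
            tracks.append(track)
            for step in range(n_steps):
                truth_rows.append(
                    {
                        "track_id": tid,
                        "population": pop.label,
                        "step": step,
                        "q_true": path.q[step],
                        "a_true": path.a[step],
                    }
                )
            cell += 1

    table = TrackTable(
        tracks=tracks,
        acquisition=acquisition,
        provenance={"generator": "hprw.simulate", "seed": config.seed},
    )
    truth = pd.DataFrame(
        truth_rows, columns=["track_id", "population", "step", "q_true", "a_true"]
    )
    return table, truth


def default_cohort_config(seed: int = 0, n_cells: int = 120) -> SimulationConfig:
    """A realistic mixed cohort: three motile modes plus a dead-cell fraction.

    Sub-population (q, a) values bracket the motility modes seen in
    collagen-embedded T cells — a fast persistent mode, a slow persistent
    mode and a slow meandering mode — at 30 s frame interval with track
    durations between 4 and 30 min and sparse acquisition gaps.
    """
    return SimulationConfig(
        populations=[
            PopulationSpec("high-aq", 0.40, q=0.7, a=3.0, n_steps=(8, 60)),
            PopulationSpec("low-a-high-q", 0.25, q=0.7, a=1.0, n_steps=(8, 60)),
            PopulationSpec("low-aq", 0.25, q=0.2, a=0.6, n_steps=(8, 60)),
            PopulationSpec("dead", 0.10, immobile=True, n_steps=(8, 60)),
        ],
        n_cells=n_cells,
        frame_interval=0.5,
        gap_rate=0.02,
        seed=seed,
    )
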