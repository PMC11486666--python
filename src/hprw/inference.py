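"""Grid-based sequential Bayesian inference of (q_t, a_t) per cell.

Under the heterogeneous persistent random walk the velocity obeys
``u_t = q_t u_{t-1} + a_t n_t`` with ``n_t`` standard 3D Gaussian, so a
consecutive velocity pair has likelihood

    L(q, a) = (2 pi a^2)^{-3/2} exp(-|u_t - q u_{t-1}|^2 / (2 a^2)).

The parameter plane is discretized on a uniform (q, a) grid and filtered
forward in time: the posterior after each update is convolved with a small
separable boxcar kernel (reflected at the grid edges) to become the prior
for the next step, which lets the estimate track slow parameter drift; with
kernel width zero the filter reduces to static-parameter Bayes.  Point
estimates are posterior means, which are stable on plateaued posteriors.

Velocity pairs must occupy consecutive frame slots — a pair separated by a
gap is never formed, since each centered velocity already consumes three
consecutive positions and the pair itself requires two consecutive
velocities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .metrics import (
    FILTER_PRESETS,
    FilterPolicy,
    VelocitySeries,
    centered_velocities,
    forward_velocities,
)
from .tracks import Track, TrackTable

__all__ = [
    "ParameterGrid",
    "SpreadKernel",
    "PosteriorSequence",
    "CellParamSummary",
    "make_grid",
    "step_likelihood",
    "sequential_filter",
    "summarize_cell",
    "detect_persistence_crossing",
    "infer_cells",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ParameterGrid:
    """Uniform discretization of the (q, a) parameter plane.

    ``q_values`` spans [-1, 1] by default (101 points).  ``a_values`` spans
    an interval open at the lower end — the likelihood is singular at a = 0,
    so the smallest activity on the grid is one grid spacing (0.1 µm/min by
    default, 100 points up to 10 µm/min).
    """

    q_values: np.ndarray
    a_values: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return (self.q_values.size, self.a_values.size)

    def uniform(self) -> np.ndarray:
        p = np.full(self.shape, 1.0 / (self.shape[0] * self.shape[1]))
        return p

    def posterior_mean(self, p: np.ndarray) -> tuple[float, float]:
        q_hat = float(p.sum(axis=1) @ self.q_values)
        a_hat = float(p.sum(axis=0) @ self.a_values)
        return q_hat, a_hat


def make_grid(
    q_bounds: tuple[float, float] = (-1.0, 1.0),
    a_bounds: tuple[float, float] = (0.0, 10.0),
    n_q: int = 101,
    n_a: int = 100,
) -> ParameterGrid:
    """Build the inference grid.

    ``q_bounds`` are inclusive and must lie within [-1, 1] (the model's
    admissible persistence range).  ``a_bounds`` is treated as the
    half-open interval ``(lo, hi]``: the first activity node sits one grid
    spacing above ``lo`` so that a = 0 is excluded.
    """
    q_lo, q_hi = q_bounds
    a_lo, a_hi = a_bounds
    if not (q_lo < q_hi and a_lo < a_hi):
        raise ValueError("grid bounds must be ordered")
    if n_q < 2 or n_a < 2:
        raise ValueError("grid needs at least 2 points per axis")
    if q_lo < -1 or q_hi > 1:
        raise ValueError("q bounds must lie within [-1, 1]")
    if a_lo < 0:
        raise ValueError("a lower bound must be >= 0")
    q = np.linspace(q_lo, q_hi, n_q)
    spacing = (a_hi - a_lo) / n_a
    a = a_lo + spacing * np.arange(1, n_a + 1)
    return ParameterGrid(q_values=q, a_values=a)


@dataclass(frozen=True)
class SpreadKernel:
    """Separable boxcar kernel coupling posteriors across time.

    Half-widths are in grid cells; total width along an axis is
    ``2*half_width + 1``.  Width zero disables spreading (static Bayes).
    The default half-width of 4 cells is the smallest boxcar that lets the
    filter register an abrupt persistence change within a ~20-step response
    window on essentially every simulated track, while keeping
    constant-regime recovery bias well inside the estimation budget;
    narrower kernels track constant parameters marginally better but lag
    behind regime switches.
    """

    half_width_q: int = 4
    half_width_a: int = 4
    shape: str = "boxcar"

    def __post_init__(self) -> None:
        if self.half_width_q < 0 or self.half_width_a < 0:
            raise ValueError("kernel half-widths must be >= 0")
        if self.shape != "boxcar":
            raise ValueError(f"unsupported kernel shape {self.shape!r}")

    def apply(self, p: np.ndarray) -> np.ndarray:
        """Convolve a (q, a) mass array, reflect at edges, renormalize."""
        out = p
        if self.half_width_q > 0:
            out = uniform_filter1d(out, 2 * self.half_width_q + 1, axis=0, mode="reflect")
        if self.half_width_a > 0:
            out = uniform_filter1d(out, 2 * self.half_width_a + 1, axis=1, mode="reflect")
        # the filter can produce tiny negative round-off near zero mass
        out = np.maximum(out, 0.0)
        s = out.sum()
        return out / s if s > 0 else out


def step_likelihood(
    u_prev: np.ndarray, u_curr: np.ndarray, grid: ParameterGrid
) -> np.ndarray:
    """Likelihood surface of one consecutive velocity pair over the grid."""
    u_prev = np.asarray(u_prev, dtype=float)
    u_curr = np.asarray(u_curr, dtype=float)
    if not (np.all(np.isfinite(u_prev)) and np.all(np.isfinite(u_curr))):
        raise ValueError("velocities must be finite")
    return np.exp(_log_step_likelihood(u_prev, u_curr, grid))


def _log_step_likelihood(
    u_prev: np.ndarray, u_curr: np.ndarray, grid: ParameterGrid
) -> np.ndarray:
    q = grid.q_values
    a = grid.a_values
    # |u_curr - q u_prev|^2 expanded in q avoids forming a (nq, 3) array
    r2 = (
        float(u_curr @ u_curr)
        - 2.0 * q * float(u_curr @ u_prev)
        + q * q * float(u_prev @ u_prev)
    )
    inv2a2 = 1.0 / (2.0 * a * a)
    return (-1.5 * _LOG_2PI - 3.0 * np.log(a))[None, :] - r2[:, None] * inv2a2[None, :]


@dataclass
class PosteriorSequence:
    """Filtered posteriors and point estimates along one track.

    ``steps`` are the frame slots (track-local, on the regular grid) at
    which a likelihood update happened; ``q_hat``/``a_hat`` are the
    posterior means at those steps.  ``posteriors`` is ``(n_steps, nq, na)``
    or None when not retained.
    """

    grid: ParameterGrid
    steps: np.ndarray
    q_hat: np.ndarray
    a_hat: np.ndarray
    posteriors: np.ndarray | None = None

    @property
    def n_updates(self) -> int:
        return int(self.steps.size)


def sequential_filter(
    vs: VelocitySeries,
    grid: ParameterGrid | None = None,
    kernel: SpreadKernel | None = None,
    keep_posteriors: bool = True,
) -> PosteriorSequence:
    """Forward-filter the (q, a) posterior along one velocity series.

    The prior at the first update is uniform.  At each slot ``t`` where the
    velocities at ``t-1`` and ``t`` are both valid, the posterior is
    ``normalize(prior * step_likelihood)``; the prior for the next slot is
    the boxcar-spread posterior.  Slots without a valid pair propagate the
    spread prior with no likelihood update.  Fewer than two valid
    velocities yield an empty sequence.
    """
    grid = grid or make_grid()
    kernel = kernel or SpreadKernel()
    valid = vs.valid
    if valid.sum() < 2:
        empty = np.empty(0)
        return PosteriorSequence(
            grid=grid, steps=np.empty(0, dtype=np.int64), q_hat=empty, a_hat=empty,
            posteriors=np.empty((0, *grid.shape)) if keep_posteriors else None,
        )

    pair_slots = np.flatnonzero(valid[1:] & valid[:-1]) + 1
    steps: list[int] = []
    q_hats: list[float] = []
    a_hats: list[float] = []
    stored: list[np.ndarray] = []

    prior = grid.uniform()
    pair_set = set(int(t) for t in pair_slots)
    start = int(pair_slots[0]) if pair_slots.size else len(valid)
    for t in range(start, len(valid)):
        if t in pair_set:
            logl = _log_step_likelihood(vs.u[t - 1], vs.u[t], grid)
            with np.errstate(divide="ignore"):
                logp = np.log(np.maximum(prior, 0.0)) + logl
            logp -= logp.max()
            post = np.exp(logp)
            post /= post.sum()
            q_hat, a_hat = grid.posterior_mean(post)
            steps.append(t)
            q_hats.append(q_hat)
            a_hats.append(a_hat)
            if keep_posteriors:
                stored.append(post)
            prior = kernel.apply(post)
        else:
            prior = kernel.apply(prior)

    return PosteriorSequence(
        grid=grid,
        steps=np.asarray(steps, dtype=np.int64),
        q_hat=np.asarray(q_hats),
        a_hat=np.asarray(a_hats),
        posteriors=np.asarray(stored) if keep_posteriors else None,
    )


def detect_persistence_crossing(
    ps: PosteriorSequence, threshold: float = 0.5, window: int = 21
) -> int | None:
    """Frame slot where the windowed mean of ``q_hat`` drops below a threshold.

    The per-step persistence estimates are smoothed with a centered moving
    average of ``window`` steps (edge-padded, so early estimates are not
    diluted), and the step following the last smoothed value at or above
    ``threshold`` is returned — i.e. the final downward crossing, which for
    a single regime switch marks the detected change point.  Returns None
    when the series never sits above the threshold or never drops below it.
    """
    if ps.n_updates == 0:
        return None
    w = uniform_filter1d(ps.q_hat, window, mode="nearest")
    above = np.flatnonzero(w >= threshold)
    if above.size == 0 or above[-1] == w.size - 1:
        return None
    return int(ps.steps[above[-1] + 1])


@dataclass
class CellParamSummary:
    """Per-cell average persistence and activity with eligibility metadata."""

    track_id: str
    q_bar: float
    a_bar: float
    n_updates: int
    n_valid_velocities: int
    duration_min: float
    eligible: bool
    condition: dict[str, str] = field(default_factory=dict)


def summarize_cell(
    ps: PosteriorSequence,
    vs: VelocitySeries,
    policy: FilterPolicy | str = "clustering",
    track_id: str = "",
    condition: dict[str, str] | None = None,
) -> CellParamSummary:
    """Average the per-step posterior means into one (q_bar, a_bar) per cell.

    Eligibility follows the policy: by default at least 15 valid velocity
    measurements and at least 240 s (4 min) of tracking.
    """
    if isinstance(policy, str):
        policy = FILTER_PRESETS[policy]
    n_valid = vs.n_valid
    duration = vs.duration
    eligible = duration >= policy.min_duration
    if policy.min_valid_velocities is not None:
        eligible = eligible and n_valid >= policy.min_valid_velocities
    q_bar = float(np.mean(ps.q_hat)) if ps.n_updates else math.nan
    a_bar = float(np.mean(ps.a_hat)) if ps.n_updates else math.nan
    return CellParamSummary(
        track_id=track_id,
        q_bar=q_bar,
        a_bar=a_bar,
        n_updates=ps.n_updates,
        n_valid_velocities=n_valid,
        duration_min=duration,
        eligible=bool(eligible),
        condition=dict(condition or {}),
    )


def infer_cells(
    table: TrackTable,
    grid: ParameterGrid | None = None,
    kernel: SpreadKernel | None = None,
    policy: FilterPolicy | str = "clustering",
    keep_steps: bool = False,
    scheme: str = "forward",
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Run the sequential filter over a cohort.

    Returns the per-cell summary DataFrame (columns ``track_id``, condition
    labels, ``q_bar``, ``a_bar``, ``n_updates``, ``n_valid_velocities``,
    ``duration_min``, ``eligible``); with ``keep_steps=True`` additionally a
    per-step estimate table (``track_id, step, q_hat, a_hat``).

    ``scheme`` selects the velocity estimate fed to the likelihood:
    ``"forward"`` (default) uses per-frame displacement velocities, which
    under the discrete-time random walk equal the model velocities exactly
    and give unbiased parameter recovery on simulated cohorts;
    ``"central"`` uses the second-order centered difference, a better
    instantaneous-velocity estimate for finely sampled continuous motion
    but one that averages adjacent model steps (inflating apparent
    persistence) when the motion decorrelates on the frame scale.
    Eligibility always counts centered-difference velocities (a valid
    measurement needs three consecutive positions).
    """
    kernel = kernel or SpreadKernel()
    if scheme not in ("forward", "central"):
        raise ValueError(f"unknown velocity scheme {scheme!r}")
    series = []
    for track in table.tracks:
        vs_c = centered_velocities(track, table.acquisition)
        vs = forward_velocities(track, table.acquisition) if scheme == "forward" else vs_c
        series.append((track, vs_c, vs))
    if grid is None:
        grid = make_grid()
        # widen the activity axis when the cohort is faster than the default
        # ceiling: a clipped grid would bias a_hat downward
        speeds = np.concatenate(
            [np.linalg.norm(vs.u[vs.valid], axis=1) for _, _, vs in series]
            or [np.empty(0)]
        )
        a_max = float(grid.a_values[-1])
        while speeds.size and np.mean(speeds > a_max) > 0.01:
            a_max *= 2.0
        if a_max > grid.a_values[-1]:
            warnings.warn(
                f">1% of step speeds exceed the activity ceiling; expanding "
                f"a_max to {a_max:g} µm/min", stacklevel=2,
            )
            grid = make_grid(a_bounds=(0.0, a_max))
    cond_keys = table.condition_keys()
    rows = []
    step_rows = []
    for track, vs_c, vs in series:
        ps = sequential_filter(vs, grid, kernel, keep_posteriors=False)
        summary = summarize_cell(ps, vs_c, policy, track.track_id, track.condition)
        row = {"track_id": summary.track_id}
        for k in cond_keys:
            row[k] = track.condition.get(k, "")
        row.update(
            q_bar=summary.q_bar,
            a_bar=summary.a_bar,
            n_updates=summary.n_updates,
            n_valid_velocities=summary.n_valid_velocities,
            duration_min=summary.duration_min,
            eligible=summary.eligible,
        )
        rows.append(row)
        if keep_steps:
            for s, qh, ah in zip(ps.steps, ps.q_hat, ps.a_hat):
                step_rows.append(
                    {"track_id": track.track_id, "step": int(s), "q_hat": qh, "a_hat": ah}
                )
    columns = ["track_id", *cond_keys, "q_bar", "a_bar", "n_updates",
               "n_valid_velocities", "duration_min", "eligible"]
    summaries = pd.DataFrame(rows, columns=columns)
    if keep_steps:
        steps = pd.DataFrame(step_rows, columns=["track_id", "step", "q_hat", "a_hat"])
        return summaries, steps
    return summaries
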