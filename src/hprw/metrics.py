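"""Track-level motility metrics and eligibility filters.

Mean track speed, arrest coefficient (fraction of timepoints with
instantaneous speed below 2 µm/min), ensemble mean squared displacement and
turning angles, plus the standard eligibility filters (minimum duration,
minimum net displacement, minimum count of valid centered-difference
velocities).

Two velocity notions coexist deliberately:

* *frame speeds* ``|x_{t+1} - x_t| / dt`` over consecutive observed pairs —
  the tracking-software convention used for speed and arrest metrics;
* *centered velocities* ``(x_{t+1} - x_{t-1}) / (2 dt)`` — the second-order
  estimate used by the random-walk inference, valid only where three
  consecutive slots are observed.  A gap invalidates the neighboring
  centered estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracks import AcquisitionSpec, Track, TrackTable

__all__ = [
    "VelocitySeries",
    "MSDCurve",
    "FilterPolicy",
    "FILTER_PRESETS",
    "centered_velocities",
    "forward_velocities",
    "frame_speeds",
    "mean_track_speed",
    "arrest_coefficient",
    "net_displacement",
    "msd_ensemble",
    "turning_angles",
    "apply_track_filters",
    "track_metrics",
]

#: arrest threshold, µm/min (strict inequality: a speed exactly at the
#: threshold does not count as arrested)
ARREST_THRESHOLD = 2.0


@dataclass
class VelocitySeries:
    """Centered-difference velocities on a track's regular slot grid.

    ``u[t]`` is valid only where slots ``t-1, t, t+1`` are all observed;
    elsewhere it is NaN and ``valid[t]`` is False.
    """

    u: np.ndarray
    valid: np.ndarray
    dt: float
    first_frame: int = 0

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def duration(self) -> float:
        """Track duration in minutes (slot span times dt)."""
        return max(len(self.valid) - 1, 0) * self.dt


def centered_velocities(track: Track, acquisition: AcquisitionSpec) -> VelocitySeries:
    """Second-order centered finite-difference velocities per slot."""
    observed, pos = track.observed_grid()
    n = observed.size
    dt = acquisition.frame_interval
    u = np.full((n, 3), np.nan)
    valid = np.zeros(n, dtype=bool)
    if n >= 3:
        valid[1:-1] = observed[:-2] & observed[1:-1] & observed[2:]
        idx = np.flatnonzero(valid)
        u[idx] = (pos[idx + 1] - pos[idx - 1]) / (2.0 * dt)
    first = int(track.frames[0]) if track.n_observed else 0
    return VelocitySeries(u=u, valid=valid, dt=dt, first_frame=first)


def forward_velocities(track: Track, acquisition: AcquisitionSpec) -> VelocitySeries:
    """Per-frame displacement velocities ``u[t] = (x[t+1] - x[t]) / dt``.

    ``valid[t]`` requires slots ``t`` and ``t+1`` observed; the last slot is
    never valid.  Under a discrete-time velocity model integrated per frame
    this recovers the model velocity exactly, whereas the centered scheme
    averages adjacent model velocities; see :func:`centered_velocities`.
    """
    observed, pos = track.observed_grid()
    n = observed.size
    dt = acquisition.frame_interval
    u = np.full((n, 3), np.nan)
    valid = np.zeros(n, dtype=bool)
    if n >= 2:
        valid[:-1] = observed[:-1] & observed[1:]
        idx = np.flatnonzero(valid)
        u[idx] = (pos[idx + 1] - pos[idx]) / dt
    first = int(track.frames[0]) if track.n_observed else 0
    return VelocitySeries(u=u, valid=valid, dt=dt, first_frame=first)


def frame_speeds(track: Track, acquisition: AcquisitionSpec) -> np.ndarray:
    """Instantaneous speeds over consecutive observed frame pairs, µm/min.

    Pairs spanning a gap are skipped.
    """
    if track.n_observed < 2:
        return np.empty(0)
    consecutive = np.diff(track.frames) == 1
    steps = np.diff(track.positions, axis=0)[consecutive]
    return np.linalg.norm(steps, axis=1) / acquisition.frame_interval


def mean_track_speed(track: Track, acquisition: AcquisitionSpec) -> float:
    """Arithmetic mean of frame speeds; NaN when no speed is computable."""
    speeds = frame_speeds(track, acquisition)
    return float(np.mean(speeds)) if speeds.size else math.nan


def arrest_coefficient(
    track: Track, acquisition: AcquisitionSpec, threshold: float = ARREST_THRESHOLD
) -> float:
    """Percentage of a track's frame speeds strictly below ``threshold``."""
    speeds = frame_speeds(track, acquisition)
    if speeds.size == 0:
        return math.nan
    return 100.0 * float(np.count_nonzero(speeds < threshold)) / speeds.size


def net_displacement(track: Track) -> float:
    """Straight-line distance from first to last observed position, µm."""
    if track.n_observed < 2:
        return 0.0
    return float(np.linalg.norm(track.positions[-1] - track.positions[0]))


def turning_angles(
    track: Track, acquisition: AcquisitionSpec | None = None, min_step: float = 0.2
) -> np.ndarray:
    """Angles between successive displacement vectors, degrees in [0, 180].

    Only triples of consecutive observed slots contribute.  Pairs where
    either displacement is shorter than ``min_step`` µm are skipped so that
    localization noise does not dominate the angle distribution; degenerate
    zero-length steps therefore never produce NaN angles.
    """
    if track.n_observed < 3:
        return np.empty(0)
    consecutive = np.diff(track.frames) == 1
    disp = np.diff(track.positions, axis=0)
    angles = []
    for i in range(len(disp) - 1):
        if not (consecutive[i] and consecutive[i + 1]):
            continue
        d1, d2 = disp[i], disp[i + 1]
        n1, n2 = np.linalg.norm(d1), np.linalg.norm(d2)
        if n1 < min_step or n2 < min_step:
            continue
        c = np.clip(np.dot(d1, d2) / (n1 * n2), -1.0, 1.0)
        angles.append(np.degrees(np.arccos(c)))
    return np.asarray(angles)


@dataclass(frozen=True)
class FilterPolicy:
    """Eligibility thresholds applied before summarizing a cohort.

    All thresholds are inclusive (a track exactly at the threshold passes);
    ``None`` disables a criterion.
    """

    min_duration: float = 0.0  # minutes
    min_displacement: float | None = None  # µm, net start-to-end
    min_valid_velocities: int | None = None
    require_continuous: float | None = None  # minutes without gaps from track start

    def __post_init__(self) -> None:
        for name in ("min_duration", "min_displacement", "min_valid_velocities", "require_continuous"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")


#: named policies matching the standard analysis variants: 2D/3D speed
#: metrics (>= 4 min and >= 15 µm net displacement), myosin-II inhibitor
#: experiments (4-min duration only), random-walk clustering eligibility
#: (>= 240 s and >= 15 valid velocities), and in vivo imaging (>= 5 min).
FILTER_PRESETS: dict[str, FilterPolicy] = {
    "speed_2d3d": FilterPolicy(min_duration=4.0, min_displacement=15.0),
    "blebbistatin": FilterPolicy(min_duration=4.0),
    "clustering": FilterPolicy(min_duration=4.0, min_valid_velocities=15),
    "invivo": FilterPolicy(min_duration=5.0),
}


def _continuous_run_minutes(track: Track, dt: float) -> float:
    """Duration of the gap-free run starting at the first observed frame."""
    observed, _ = track.observed_grid()
    if observed.size == 0:
        return 0.0
    run = 0
    for obs in observed:
        if not obs:
            break
        run += 1
    return (run - 1) * dt


def apply_track_filters(
    table: TrackTable, policy: FilterPolicy | str
) -> tuple[TrackTable, pd.DataFrame]:
    """Split a table into eligible tracks and an exclusion log.

    ``policy`` may be a :class:`FilterPolicy` or a preset name.  The log has
    one row per excluded track with all failed criteria joined by ``;``.
    """
    if isinstance(policy, str):
        policy = FILTER_PRESETS[policy]
    dt = table.acquisition.frame_interval
    kept: list[Track] = []
    log_rows = []
    for track in table.tracks:
        reasons = []
        if track.duration(table.acquisition) < policy.min_duration:
            reasons.append(f"duration<{policy.min_duration:g}min")
        if policy.min_displacement is not None and net_displacement(track) < policy.min_displacement:
            reasons.append(f"net_displacement<{policy.min_displacement:g}um")
        if policy.min_valid_velocities is not None:
            vs = centered_velocities(track, table.acquisition)
            if vs.n_valid < policy.min_valid_velocities:
                reasons.append(f"valid_velocities<{policy.min_valid_velocities}")
        if policy.require_continuous is not None:
            if _continuous_run_minutes(track, dt) < policy.require_continuous:
                reasons.append(f"continuous<{policy.require_continuous:g}min")
        if reasons:
            log_rows.append({"track_id": track.track_id, "reason": ";".join(reasons)})
        else:
            kept.append(track)
    filtered = TrackTable(
        tracks=kept, acquisition=table.acquisition, provenance=dict(table.provenance)
    )
    log = pd.DataFrame(log_rows, columns=["track_id", "reason"])
    return filtered, log


@dataclass
class MSDCurve:
    """Ensemble mean squared displacement versus time lag."""

    lags: np.ndarray  # minutes, starting at 0
    msd: np.ndarray  # µm²
    n_tracks: np.ndarray  # contributing tracks per lag


def msd_ensemble(
    table: TrackTable,
    max_lag: float,
    policy: FilterPolicy | None = None,
    sliding_origin: bool = False,
) -> MSDCurve:
    """Ensemble MSD referenced to each track's first observed frame.

    Eligible tracks are those observed continuously (no gaps) from their
    first frame for at least ``policy.require_continuous`` minutes (default
    10 min, the usual continuous-tracking window).  At each lag the squared
    displacement from the first frame is averaged across the tracks still
    within their continuous run.  ``sliding_origin=True`` switches to the
    time-averaged estimator over all origins inside the continuous run.
    """
    dt = table.acquisition.frame_interval
    n_lag = int(round(max_lag / dt))
    if abs(n_lag * dt - max_lag) > 1e-9:
        raise ValueError("max_lag must be a multiple of the frame interval")
    require = policy.require_continuous if policy and policy.require_continuous is not None else 10.0

    sums = np.zeros(n_lag + 1)
    counts = np.zeros(n_lag + 1, dtype=np.int64)
    for track in table.tracks:
        observed, pos = track.observed_grid()
        run = 0
        for obs in observed:
            if not obs:
                break
            run += 1
        if (run - 1) * dt < require:
            continue
        kmax = min(n_lag, run - 1)
        if sliding_origin:
            for k in range(0, kmax + 1):
                d = pos[k : run] - pos[: run - k]
                sums[k] += float(np.mean(np.sum(d * d, axis=1)))
                counts[k] += 1
        else:
            d = pos[: kmax + 1] - pos[0]
            sums[: kmax + 1] += np.sum(d * d, axis=1)
            counts[: kmax + 1] += 1

    with np.errstate(invalid="ignore"):
        msd = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return MSDCurve(lags=np.arange(n_lag + 1) * dt, msd=msd, n_tracks=counts)


def track_metrics(table: TrackTable) -> pd.DataFrame:
    """Per-track motility summary table.

    Columns: ``track_id``, condition labels, ``mean_speed_um_min``,
    ``arrest_pct``, ``duration_min``, ``net_disp_um``,
    ``n_valid_velocities``.
    """
    acq = table.acquisition
    cond_keys = table.condition_keys()
    rows = []
    for track in table.tracks:
        vs = centered_velocities(track, acq)
        row = {"track_id": track.track_id}
        for k in cond_keys:
            row[k] = track.condition.get(k, "")
        row.update(
            mean_speed_um_min=mean_track_speed(track, acq),
            arrest_pct=arrest_coefficient(track, acq),
            duration_min=track.duration(acq),
            net_disp_um=net_displacement(track),
            n_valid_velocities=vs.n_valid,
        )
        rows.append(row)
    columns = ["track_id", *cond_keys, "mean_speed_um_min", "arrest_pct",
               "duration_min", "net_disp_um", "n_valid_velocities"]
    return pd.DataFrame(rows, columns=columns)
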