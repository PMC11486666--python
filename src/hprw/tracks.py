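"""Track data model and CSV input/output.

Trajectories live on a regular acquisition grid: frame ``k`` corresponds to
time ``k * frame_interval`` minutes.  A track stores only its observed
frames; missing frames inside the span are *gaps* and are reconstructed on
read from the absent rows.  Positions are in micrometres, times in minutes
throughout the package.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AcquisitionSpec",
    "Track",
    "TrackTable",
    "Dialect",
    "FormatError",
    "ValidationError",
    "read_tracks",
    "write_tracks",
    "validate_tracks",
]


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(ValueError):
    """A file parses but violates a track-level contract."""


@dataclass(frozen=True)
class AcquisitionSpec:
    """Imaging cadence of a time-lapse experiment.

    Parameters
    ----------
    frame_interval
        Time between consecutive volumes, in minutes.  Two-photon and
        confocal time-lapse stacks in this domain are typically acquired
        every ~30 s, hence the 0.5 min default.
    position_units
        Label only; the package works in micrometres.
    time_origin
        Frame index of the first acquired volume (0-based).
    """

    frame_interval: float = 0.5
    position_units: str = "µm"
    time_origin: int = 0

    def __post_init__(self) -> None:
        if not self.frame_interval > 0:
            raise ValueError(f"frame_interval must be > 0, got {self.frame_interval}")


@dataclass
class Track:
    """One cell's time-indexed 3D positions.

    ``frames`` are strictly increasing integers on the acquisition grid and
    ``positions`` is the aligned ``(n, 3)`` array of µm coordinates.
    ``condition`` carries experiment labels (genotype, treatment, matrix
    density, ...) used downstream for grouping and comparisons.
    """

    track_id: str
    frames: np.ndarray
    positions: np.ndarray
    condition: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.frames.ndim != 1:
            raise ValidationError(f"track {self.track_id}: frames must be 1-D")
        if self.positions.shape != (self.frames.size, 3):
            raise ValidationError(
                f"track {self.track_id}: positions shape {self.positions.shape} "
                f"does not match {self.frames.size} frames x 3"
            )
        if self.frames.size and np.any(np.diff(self.frames) <= 0):
            raise ValidationError(f"track {self.track_id}: frames not strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError(f"track {self.track_id}: non-finite positions")

    @property
    def n_observed(self) -> int:
        return int(self.frames.size)

    @property
    def span(self) -> int:
        """Number of frame slots spanned, ``last - first`` (0 for a single point)."""
        if self.frames.size == 0:
            return 0
        return int(self.frames[-1] - self.frames[0])

    @property
    def gap_mask(self) -> np.ndarray:
        """Boolean per slot on the regularized grid from first to last frame;
        True marks a missing observation."""
        mask = np.ones(self.span + 1 if self.frames.size else 0, dtype=bool)
        if self.frames.size:
            mask[self.frames - self.frames[0]] = False
        return mask

    @property
    def n_gaps(self) -> int:
        return int(self.gap_mask.sum())

    def duration(self, acquisition: AcquisitionSpec) -> float:
        """Tracked duration in minutes (span of frames times the frame interval)."""
        return self.span * acquisition.frame_interval

    def observed_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Positions expanded onto the regular slot grid.

        Returns ``(observed, pos_grid)`` where ``observed`` is a boolean per
        slot and ``pos_grid`` is ``(span+1, 3)`` with NaN at gaps.
        """
        n = self.span + 1 if self.frames.size else 0
        observed = np.zeros(n, dtype=bool)
        pos = np.full((n, 3), np.nan)
        if self.frames.size:
            idx = self.frames - self.frames[0]
            observed[idx] = True
            pos[idx] = self.positions
        return observed, pos


@dataclass
class TrackTable:
    """A cohort of tracks sharing one acquisition."""

    tracks: list[Track]
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.track_id for t in self.tracks]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate track ids: {dupes}")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def condition_keys(self) -> list[str]:
        keys: list[str] = []
        for t in self.tracks:
            for k in t.condition:
                if k not in keys:
                    keys.append(k)
        return keys


@dataclass(frozen=True)
class Dialect:
    """Column mapping from a foreign tracking export onto track roles.

    Either a ``frame`` column or a ``time`` column must be mapped.  When only
    time is available it is snapped to the nearest frame on the regular grid;
    deviations beyond 25% of the frame interval are rejected rather than
    invented as new frames.
    """

    track_id: str = "track_id"
    frame: str | None = "frame"
    time: str | None = "t_min"
    x: str = "x_um"
    y: str = "y_um"
    z: str = "z_um"
    time_units: str = "min"  # "min" or "s"
    condition_columns: tuple[str, ...] = ()
    condition_constants: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Dialect":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "condition_columns" in raw:
            raw["condition_columns"] = tuple(raw["condition_columns"])
        return cls(**raw)


#: tolerance for snapping a timestamp to the frame grid, as a fraction of
#: the frame interval
SNAP_TOLERANCE = 0.25


def _time_to_minutes(values: np.ndarray, units: str) -> np.ndarray:
    if units == "min":
        return values
    if units == "s":
        return values / 60.0
    raise FormatError(f"unknown time units {units!r} (expected 'min' or 's')")


def read_tracks(
    path: str | Path | io.TextIOBase,
    dialect: Dialect | None = None,
    acquisition: AcquisitionSpec | None = None,
) -> TrackTable:
    """Read a trajectory table in a tracking-software-compatible CSV dialect.

    Rows are grouped by track id and sorted by frame.  Timestamps (when no
    frame column is mapped) are snapped to the nearest grid frame; a
    deviation beyond 25% of the frame interval raises :class:`ValidationError`.
    Condition labels are taken from the configured columns (first row per
    track) plus any configured constants.
    """
    dialect = dialect or Dialect()
    acquisition = acquisition or AcquisitionSpec()
    df = pd.read_csv(path, float_precision="round_trip")

    required = {"track id": dialect.track_id, "x": dialect.x, "y": dialect.y, "z": dialect.z}
    for role, col in required.items():
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} (role: {role})")

    if dialect.frame is not None and dialect.frame in df.columns:
        frames = np.asarray(df[dialect.frame], dtype=np.int64)
    elif dialect.time is not None and dialect.time in df.columns:
        t_min = _time_to_minutes(np.asarray(df[dialect.time], dtype=float), dialect.time_units)
        dt = acquisition.frame_interval
        frames_f = t_min / dt
        frames = np.rint(frames_f).astype(np.int64)
        off = np.abs(t_min - frames * dt)
        bad = off > SNAP_TOLERANCE * dt
        if np.any(bad):
            i = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"timestamp {t_min[i]:g} min deviates more than "
                f"{SNAP_TOLERANCE:.0%} of the frame interval from the grid"
            )
    else:
        raise FormatError(
            f"missing required column: neither frame ({dialect.frame!r}) nor "
            f"time ({dialect.time!r}) present"
        )

    for col in dialect.condition_columns:
        if col not in df.columns:
            raise FormatError(f"missing condition column {col!r}")

    work = pd.DataFrame(
        {
            "_tid": df[dialect.track_id].astype(str),
            "_frame": frames,
            "_x": np.asarray(df[dialect.x], dtype=float),
            "_y": np.asarray(df[dialect.y], dtype=float),
            "_z": np.asarray(df[dialect.z], dtype=float),
        }
    )
    for col in dialect.condition_columns:
        work[col] = df[col].astype(str)

    tracks: list[Track] = []
    for tid, grp in work.groupby("_tid", sort=True):
        grp = grp.sort_values("_frame")
        fr = grp["_frame"].to_numpy()
        if np.any(np.diff(fr) == 0):
            dup = int(fr[np.flatnonzero(np.diff(fr) == 0)[0]])
            raise ValidationError(f"duplicate (track, frame) row: track {tid!r} frame {dup}")
        condition = dict(dialect.condition_constants)
        for col in dialect.condition_columns:
            condition[col] = str(grp[col].iloc[0])
        tracks.append(
            Track(
                track_id=str(tid),
                frames=fr,
                positions=grp[["_x", "_y", "_z"]].to_numpy(),
                condition=condition,
            )
        )
    src = str(path) if isinstance(path, (str, Path)) else "<stream>"
    return TrackTable(tracks=tracks, acquisition=acquisition, provenance={"source": src})


def write_tracks(table: TrackTable, path: str | Path | io.TextIOBase) -> None:
    """Write a track table as CSV (``track_id,frame,t_min,x_um,y_um,z_um,...``).

    Gap slots emit no row; a read of the written file reproduces frames,
    positions, ids and gaps exactly.
    """
    dt = table.acquisition.frame_interval
    cond_keys = table.condition_keys()
    rows = []
    for track in table.tracks:
        for k, frame in enumerate(track.frames):
            row = {
                "track_id": track.track_id,
                "frame": int(frame),
                "t_min": frame * dt,
                "x_um": track.positions[k, 0],
                "y_um": track.positions[k, 1],
                "z_um": track.positions[k, 2],
            }
            for key in cond_keys:
                row[key] = track.condition.get(key, "")
            rows.append(row)
    columns = ["track_id", "frame", "t_min", "x_um", "y_um", "z_um"] + cond_keys
    df = pd.DataFrame(rows, columns=columns)
    # %.17g round-trips float64 exactly
    df.to_csv(path, index=False, float_format="%.17g")


def validate_tracks(table: TrackTable) -> pd.DataFrame:
    """Report per-track duration, observed-slot count and gap count.

    Report-only: never raises.  ``zero_length`` flags tracks spanning a
    single frame (no duration).
    """
    dt = table.acquisition.frame_interval
    rows = []
    for t in table.tracks:
        rows.append(
            {
                "track_id": t.track_id,
                "duration_min": t.span * dt,
                "n_observed": t.n_observed,
                "n_gaps": t.n_gaps,
                "zero_length": t.span == 0,
            }
        )
    return pd.DataFrame(
        rows, columns=["track_id", "duration_min", "n_observed", "n_gaps", "zero_length"]
    )
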