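"""Reading, validating, slicing and writing tracking tables and distance matrices.

The tool consumes per-animal 2-D tracking tables (delimited text with a header),
either time-indexed (``time_s, x, y``) or frame-indexed (``frame, x, y`` plus a
frame rate).  Positions are held internally in millimetres on a uniform frame
grid; irregular input is resampled and short tracking dropouts interpolated,
with counters recording every such repair.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ArgumentError, DataError, FormatError

__all__ = [
    "Arena",
    "Trajectory",
    "TimeInterval",
    "DistanceMatrix",
    "read_tracking_table",
    "slice_interval",
    "write_distance_matrix",
    "read_distance_matrix",
]

#: spatial resolution (pixels per mm) of the original video tracking setup,
#: used as the default pixel-to-mm conversion for ``units="px"``.
DEFAULT_PX_PER_MM = 2.4

_MAX_INTERP_GAP = 5  # frames; longer dropouts are an error unless allow_gaps


@dataclass(frozen=True)
class Arena:
    """Rectangular arena, origin at (0, 0), dimensions in mm."""

    width: float
    height: float

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ArgumentError("arena dimensions must be positive")

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def diagonal(self) -> float:
        return float(np.hypot(self.width, self.height))


@dataclass(frozen=True)
class TimeInterval:
    """Half-open time window [start, end) in seconds."""

    start: float
    end: float

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ArgumentError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass
class Trajectory:
    """A uniformly sampled 2-D trajectory for one subject.

    ``times`` are strictly increasing seconds with consecutive gaps equal to
    ``1/fps``; ``x`` and ``y`` are positions in mm inside ``arena``.
    """

    subject_id: str
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fps: float
    arena: Arena
    #: validation counters: clamped points, dropped duplicate frames,
    #: resampled rows, interpolated dropout frames
    counters: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.times)
        if not (len(self.x) == len(self.y) == n):
            raise DataError("times, x, y must have equal length")
        if n < 2:
            raise DataError("a trajectory needs at least 2 frames")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise DataError("times must be strictly increasing")
        if np.any(np.abs(dt - 1.0 / self.fps) > 1e-9):
            raise DataError("times are not uniform at 1/fps; ingest via read_tracking_table")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def span(self) -> TimeInterval:
        return TimeInterval(float(self.times[0]), float(self.times[-1]) + 1.0 / self.fps)

    def positions(self) -> np.ndarray:
        """(n, 2) array of x, y positions."""
        return np.column_stack([self.x, self.y])


def _clamp_to_arena(x: np.ndarray, y: np.ndarray, arena: Arena) -> tuple[np.ndarray, np.ndarray, int]:
    xc = np.clip(x, 0.0, arena.width)
    yc = np.clip(y, 0.0, arena.height)
    n_clamped = int(np.sum((xc != x) | (yc != y)))
    return xc, yc, n_clamped


def read_tracking_table(
    path,
    fps: float,
    arena: Arena,
    sep: str = ",",
    units: str = "mm",
    px_per_mm: float = DEFAULT_PX_PER_MM,
    subject_id: str | None = None,
    allow_gaps: bool = False,
) -> Trajectory:
    """Read a delimited tracking table into a validated :class:`Trajectory`.

    Two dialects are accepted: time-indexed (columns ``time_s, x, y``) and
    frame-indexed (columns ``frame, x, y``; times become ``frame / fps``).
    ``units`` may be ``"mm"``, ``"cm"`` or ``"px"`` (converted once on ingest).

    Rows with duplicated time stamps are dropped, jittered time stamps are
    linearly resampled onto the uniform ``1/fps`` grid, and tracking dropouts
    of at most 5 frames are linearly interpolated.  Longer dropouts raise
    :class:`DataError` unless ``allow_gaps`` is set.  Out-of-arena positions
    are clamped.  All repairs are tallied in ``Trajectory.counters``.
    """
    if fps <= 0:
        raise ArgumentError("fps must be positive")
    if isinstance(path, (str, os.PathLike)):
        if not os.path.exists(path):
            raise FormatError(f"file not found: {path}")
        label = subject_id or os.path.splitext(os.path.basename(path))[0]
    else:
        label = subject_id or "subject"
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip() for c in df.columns]

    for col in ("x", "y"):
        if col not in df.columns:
            raise FormatError(f"column {col} not found")
    if "time_s" in df.columns:
        times = df["time_s"].to_numpy(dtype=float)
    elif "frame" in df.columns:
        frames = df["frame"].to_numpy(dtype=float)
        if np.any(np.diff(frames) <= 0):
            raise DataError("frame indices must be strictly increasing")
        times = frames / fps
    else:
        raise FormatError("column time_s not found (nor frame)")
    if "subject_id" in df.columns and subject_id is None:
        label = str(df["subject_id"].iloc[0])

    x = df["x"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    if units == "cm":
        x, y = x * 10.0, y * 10.0
    elif units == "px":
        x, y = x / px_per_mm, y / px_per_mm
    elif units != "mm":
        raise ArgumentError(f"unknown units {units!r}")

    if len(x) < 2:
        raise DataError("fewer than 2 rows")
    if np.any(np.diff(times) < 0):
        raise DataError("time stamps must be non-decreasing")

    counters = {"clamped": 0, "duplicates": 0, "resampled": 0, "interpolated": 0}

    # drop duplicate time stamps (repeated frames from the tracker)
    keep = np.concatenate([[True], np.diff(times) > 0])
    counters["duplicates"] = int(np.sum(~keep))
    times, x, y = times[keep], x[keep], y[keep]
    if len(times) < 2:
        raise DataError("fewer than 2 distinct rows")

    # snap onto the uniform grid anchored at the first time stamp
    dt = 1.0 / fps
    t0 = times[0]
    idx_float = (times - t0) * fps
    idx = np.rint(idx_float).astype(np.int64)
    jitter = np.abs(idx_float - idx) * dt
    if np.any(np.diff(idx) < 1):
        # rounding collapsed neighbouring rows: treat input as irregular and
        # resample everything onto the grid
        n_out = int(np.floor((times[-1] - t0) * fps)) + 1
        grid = t0 + np.arange(n_out) * dt
        x = np.interp(grid, times, x)
        y = np.interp(grid, times, y)
        counters["resampled"] = n_out
        times = grid
    else:
        if np.any(jitter > 1e-6):
            rows = jitter > 1e-6
            grid_t = t0 + idx * dt
            x = x.copy()
            y = y.copy()
            x[rows] = np.interp(grid_t[rows], times, x)
            y[rows] = np.interp(grid_t[rows], times, y)
            counters["resampled"] = int(np.sum(rows))
        # fill dropouts
        gaps = np.diff(idx) - 1
        if np.any(gaps > _MAX_INTERP_GAP) and not allow_gaps:
            worst = int(gaps.max())
            raise DataError(
                f"tracking dropout of {worst} frames exceeds {_MAX_INTERP_GAP}; "
                "pass allow_gaps=True to interpolate anyway"
            )
        if np.any(gaps > 0):
            full_idx = np.arange(idx[-1] + 1)
            xf = np.interp(full_idx, idx, x)
            yf = np.interp(full_idx, idx, y)
            counters["interpolated"] = int(len(full_idx) - len(idx))
            x, y = xf, yf
            times = t0 + full_idx * dt
        else:
            times = t0 + idx * dt

    x, y, counters["clamped"] = _clamp_to_arena(x, y, arena)
    return Trajectory(label, times, x, y, fps, arena, counters)


def slice_interval(traj: Trajectory, interval: TimeInterval) -> Trajectory:
    """Return the frames of ``traj`` with ``start <= t < end``.

    Subject id, fps and arena are preserved; an empty result raises
    :class:`DataError`.
    """
    mask = (traj.times >= interval.start) & (traj.times < interval.end)
    if not np.any(mask):
        raise DataError(
            f"interval [{interval.start}, {interval.end}) does not overlap "
            f"trajectory span [{traj.times[0]}, {traj.times[-1]}]"
        )
    if int(mask.sum()) < 2:
        raise DataError("interval selects fewer than 2 frames")
    return replace(
        traj,
        times=traj.times[mask],
        x=traj.x[mask],
        y=traj.y[mask],
        counters=dict(traj.counters),
    )


@dataclass
class DistanceMatrix:
    """Labelled symmetric matrix of pairwise distances for one cohort.

    ``measure`` tags which distance the entries are (``"BDD"`` or ``"CSD"``)
    and ``interval`` records the analysis window they were computed over.
    """

    labels: list[str]
    values: np.ndarray
    measure: str = ""
    interval: TimeInterval | None = None

    def __post_init__(self):
        self.labels = [str(l) for l in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if n == 0:
            raise ArgumentError("empty label list")
        if len(set(self.labels)) != n:
            raise ArgumentError("duplicate subject labels")
        if self.values.shape != (n, n):
            raise ArgumentError(f"matrix shape {self.values.shape} does not match {n} labels")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ArgumentError("distance matrix is not symmetric (1e-9)")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ArgumentError("distance matrix diagonal is not zero")
        if np.any(self.values < -1e-12):
            raise ArgumentError("distance matrix has negative entries")

    def __getitem__(self, pair) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def offdiag(self) -> np.ndarray:
        """Upper-triangle (unordered pair) values as a flat array."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


def write_distance_matrix(dmat: DistanceMatrix, path) -> None:
    """Write ``dmat`` as comma-delimited text, labels as first row and column."""
    df = pd.DataFrame(dmat.values, index=dmat.labels, columns=dmat.labels)
    df.to_csv(path, float_format="%.17g")


def read_distance_matrix(path, measure: str = "", interval: TimeInterval | None = None) -> DistanceMatrix:
    """Read back a matrix written by :func:`write_distance_matrix`."""
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float), measure, interval)
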