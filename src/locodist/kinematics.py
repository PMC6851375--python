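"""From raw trajectories to normalized behavior curves.

A *behavior curve* is a multivariate time series of per-frame behavioral
factors — here the speed s(t) = sqrt(x'(t)^2 + y'(t)^2) (mm/s) and the
unsigned plane curvature kappa(t) = |x'(t) y''(t) - y'(t) x''(t)| / v(t)^3
(1/mm) of the tracked path — each sigmoid-normalized to (0, 1) using the mean
and standard deviation of its own input sequence.  Trajectories are first
denoised with a Savitzky-Golay filter; the filter parameters can be chosen
automatically by jointly minimizing reconstruction error and jerk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .errors import ArgumentError, DataError
from .tracking_io import TimeInterval, Trajectory, slice_interval

__all__ = [
    "SmoothingParams",
    "FactorSeries",
    "BehaviorCurve",
    "savgol_smooth",
    "select_smoothing_params",
    "speed_series",
    "curvature_series",
    "sigmoid_normalize",
    "behavior_curve",
    "DEFAULT_SMOOTHING",
    "DEFAULT_SPEED_FLOOR",
]

#: default speed floor (mm/s) below which curvature is defined as 0; about half
#: the displacement-per-frame scale of the immobility convention (3 mm over
#: 1 s) at 20 fps.
DEFAULT_SPEED_FLOOR = 0.5

_MAX_STABLE_ORDER = 7  # higher polynomial orders are numerically unstable


@dataclass(frozen=True)
class SmoothingParams:
    """Savitzky-Golay parameters: polynomial ``order`` and odd ``window`` length."""

    order: int = 5
    window: int = 53

    def __post_init__(self):
        if self.order < 1:
            raise ArgumentError("smoothing order must be >= 1")
        if self.order > _MAX_STABLE_ORDER:
            raise ArgumentError(f"smoothing order above {_MAX_STABLE_ORDER} is unstable")
        if self.window % 2 == 0:
            raise ArgumentError("smoothing window must be odd")
        if self.window <= self.order:
            raise ArgumentError("smoothing window must exceed the order")


#: documented defaults: order-5 polynomial, 53-frame window.
DEFAULT_SMOOTHING = SmoothingParams(5, 53)


@dataclass
class FactorSeries:
    """Per-frame values of one behavioral factor, with units and a
    normalization record (mu, sigma) once the sigmoid has been applied."""

    name: str
    values: np.ndarray
    units: str
    normalization: tuple[float, float] | None = None
    flags: np.ndarray | None = None  # e.g. curvature frames gated by the speed floor

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self):
        return len(self.values)


@dataclass
class BehaviorCurve:
    """Normalized multivariate behavior curve C_Theta for one subject/interval.

    ``values`` has one row per frame and one column per factor, columns in the
    order of ``factors``; all entries lie in [0, 1] (the sigmoid produces the
    open interval; the closed one is allowed so synthetic curves can sit on
    the bounds).
    """

    factors: tuple[str, ...]
    values: np.ndarray
    subject_id: str = ""
    interval: TimeInterval | None = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if len(self.factors) == 0:
            raise ArgumentError("a behavior curve needs at least one factor")
        if self.values.shape[1] != len(self.factors):
            raise ArgumentError("column count does not match factor count")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise DataError("behavior curve entries must lie in [0, 1]")

    def __len__(self):
        return self.values.shape[0]


def savgol_smooth(traj: Trajectory, params: SmoothingParams = DEFAULT_SMOOTHING) -> Trajectory:
    """Savitzky-Golay filter x(t) and y(t) independently; times unchanged."""
    if params.window > len(traj):
        raise ArgumentError(
            f"smoothing window {params.window} exceeds trajectory length {len(traj)}"
        )
    from dataclasses import replace

    xs = savgol_filter(traj.x, params.window, params.order)
    ys = savgol_filter(traj.y, params.window, params.order)
    return replace(traj, x=xs, y=ys, counters=dict(traj.counters))


def _derivative(values: np.ndarray, fps: float, n: int = 1) -> np.ndarray:
    """n-th derivative by repeated central differences on the uniform grid."""
    out = values
    for _ in range(n):
        out = np.gradient(out, 1.0 / fps)
    return out


def _smoothing_objective(traj: Trajectory, params: SmoothingParams) -> float:
    """Product of mean squared positional deviation and mean jerk magnitude."""
    sm = savgol_smooth(traj, params)
    mse = float(np.mean((sm.x - traj.x) ** 2 + (sm.y - traj.y) ** 2))
    jx = _derivative(sm.x, traj.fps, 3)
    jy = _derivative(sm.y, traj.fps, 3)
    jerk = float(np.mean(np.hypot(jx, jy)))
    return mse * jerk


def select_smoothing_params(
    traj: Trajectory,
    max_order: int = _MAX_STABLE_ORDER,
    max_window_frames: int = 600,
    return_table: bool = False,
):
    """Grid-search Savitzky-Golay parameters minimizing MSE x mean jerk.

    Candidates are odd orders ``1..max_order`` crossed with odd windows
    ``order+2..max_window_frames`` (only odd orders are searched: adjacent
    even/odd orders give near-identical filters).  Ties are broken by smaller
    order, then smaller window.  With ``return_table=True`` the full
    per-candidate objective table (order, window, objective) is also returned
    for plotting.
    """
    max_window = min(max_window_frames, len(traj) if len(traj) % 2 == 1 else len(traj) - 1)
    if max_window < 3:
        raise DataError("trajectory too short for any smoothing window")
    rows = []
    for order in range(1, max_order + 1, 2):
        w0 = order + 2 if (order + 2) % 2 == 1 else order + 3
        for window in range(w0, max_window + 1, 2):
            obj = _smoothing_objective(traj, SmoothingParams(order, window))
            rows.append((order, window, obj))
    # objectives that are zero up to float noise (exactly-reproduced signals)
    # are genuine ties; resolve them by smaller order, then smaller window
    floor = 1e-12 * max(obj for _, _, obj in rows)
    best = min(rows, key=lambda r: (r[2] if r[2] > floor else 0.0, r[0], r[1]))
    params = SmoothingParams(best[0], best[1])
    if return_table:
        return params, rows
    return params


def speed_series(traj: Trajectory) -> FactorSeries:
    """Speed s(t) = sqrt(x'^2 + y'^2) in mm/s via central finite differences."""
    if len(traj) < 2:
        raise DataError("speed needs at least 2 frames")
    dx = _derivative(traj.x, traj.fps)
    dy = _derivative(traj.y, traj.fps)
    return FactorSeries("speed", np.hypot(dx, dy), "mm/s")


def curvature_series(traj: Trajectory, speed_floor: float = DEFAULT_SPEED_FLOOR) -> FactorSeries:
    """Unsigned plane curvature kappa(t) = |x'y'' - y'x''| / v^3 in 1/mm.

    Frames with speed below ``speed_floor`` get curvature 0 and are flagged —
    kappa's v^3 denominator is meaningless for a near-stationary animal.
    """
    if len(traj) < 3:
        raise DataError("curvature needs at least 3 frames")
    dx = _derivative(traj.x, traj.fps)
    dy = _derivative(traj.y, traj.fps)
    ddx = np.gradient(dx, 1.0 / traj.fps)
    ddy = np.gradient(dy, 1.0 / traj.fps)
    v = np.hypot(dx, dy)
    slow = v < speed_floor
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.abs(dx * ddy - dy * ddx) / v**3
    kappa[slow] = 0.0
    return FactorSeries("curvature", kappa, "1/mm", flags=slow)


def sigmoid_normalize(series: FactorSeries) -> FactorSeries:
    """Map values through sig(x) = 1 / (1 + exp(-(x - mu)/sigma)).

    mu and sigma are the mean and (population) standard deviation of the input
    sequence itself and are recorded on the result.  A constant series
    (sigma = 0) maps to 0.5 everywhere, the limit of the centered argument.
    """
    if len(series) == 0:
        raise DataError("cannot normalize an empty series")
    mu = float(np.mean(series.values))
    sigma = float(np.std(series.values))
    # a constant factor (sigma = 0, up to float rounding of an exactly
    # constant signal) maps to 0.5 everywhere: rescaling pure representation
    # noise to the full (0, 1) range would fabricate structure
    if sigma <= 1e-9 * max(abs(mu), 1e-300):
        sigma = 0.0
        vals = np.full_like(series.values, 0.5)
    else:
        vals = 1.0 / (1.0 + np.exp(-(series.values - mu) / sigma))
        # keep the open range (0, 1) even when the exponential underflows
        vals = np.clip(vals, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
    return FactorSeries(series.name, vals, "1", normalization=(mu, sigma), flags=series.flags)


_EXTRACTORS = {
    "speed": lambda traj, floor: speed_series(traj),
    "curvature": lambda traj, floor: curvature_series(traj, floor),
}


def behavior_curve(
    traj: Trajectory,
    interval: TimeInterval | None = None,
    factors: tuple[str, ...] = ("speed", "curvature"),
    smoothing: SmoothingParams = DEFAULT_SMOOTHING,
    speed_floor: float = DEFAULT_SPEED_FLOOR,
    extra_series: dict[str, FactorSeries] | None = None,
) -> BehaviorCurve:
    """slice -> smooth -> per-factor series -> per-factor sigmoid normalization.

    Normalization statistics are computed from the analyzed interval itself,
    so curves are comparable between equal-length protocol windows.  Custom
    factors may be supplied pre-computed via ``extra_series``.
    """
    if len(factors) == 0:
        raise ArgumentError("empty factor set")
    sub = slice_interval(traj, interval) if interval is not None else traj
    sm = savgol_smooth(sub, smoothing)
    cols = []
    for name in factors:
        if extra_series and name in extra_series:
            series = extra_series[name]
            if len(series) != len(sm):
                raise ArgumentError(f"custom factor {name!r} length mismatch")
        elif name in _EXTRACTORS:
            series = _EXTRACTORS[name](sm, speed_floor)
        else:
            raise ArgumentError(f"unknown factor {name!r}")
        cols.append(sigmoid_normalize(series).values)
    return BehaviorCurve(tuple(factors), np.column_stack(cols), sub.subject_id, interval)
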