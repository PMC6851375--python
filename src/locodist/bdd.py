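"""Behavioral Distortion Distance: multivariate dynamic time warping.

The alignment energy of a monotone warping path through two behavior curves is
the *mean* per-step m-dimensional Euclidean cost along the path — the discrete
analogue of the continuous alignment energy, whose 1/(u_f - u_0) prefactor
normalizes by parameter length.  BDD is the minimum of that energy over all
admissible paths.  Because a path's step count varies, minimizing the mean is
a fractional program: we solve it exactly with Dinkelbach iteration, where
each subproblem is a standard O(nm) dynamic program on lambda-shifted costs
(accelerated with numba).

With sigmoid-normalized factors every per-step cost is below sqrt(m), so
BDD <= sqrt(|Theta|).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import ArgumentError, DataError
from .kinematics import (
    DEFAULT_SMOOTHING,
    DEFAULT_SPEED_FLOOR,
    BehaviorCurve,
    SmoothingParams,
    behavior_curve,
)
from .tracking_io import DistanceMatrix, TimeInterval, Trajectory

__all__ = ["WarpAlignment", "dtw_align", "bdd_distance", "pairwise_bdd", "iibdd"]


@dataclass
class WarpAlignment:
    """Optimal monotone correspondence between two behavior curves.

    ``path`` is a (K, 2) integer array of index pairs from (0, 0) to
    (n-1, m-1) with steps in {(1,0), (0,1), (1,1)}; ``energy`` is the mean
    per-step Euclidean cost along it.
    """

    path: np.ndarray
    energy: float

    def validate(self, n: int, m: int) -> None:
        p = self.path
        if tuple(p[0]) != (0, 0) or tuple(p[-1]) != (n - 1, m - 1):
            raise DataError("warp path endpoints are wrong")
        steps = np.diff(p, axis=0)
        ok = np.all(steps >= 0) and np.all(steps <= 1) and np.all(steps.sum(axis=1) >= 1)
        if not ok:
            raise DataError("warp path steps must be (1,0), (0,1) or (1,1)")
        if self.energy < 0:
            raise DataError("alignment energy must be nonnegative")


@njit(cache=True)
def _dp_shifted(cost, lam):  # pragma: no cover - exercised through dtw_align
    """Min total (cost - lam) path DP; returns raw total cost, step count K
    and the path.  Tie-break prefers diagonal, then (0,1), then (1,0)."""
    n, m = cost.shape
    D = np.empty((n, m))
    step = np.empty((n, m), dtype=np.int8)
    D[0, 0] = cost[0, 0] - lam
    step[0, 0] = -1
    for j in range(1, m):
        D[0, j] = D[0, j - 1] + cost[0, j] - lam
        step[0, j] = 1
    for i in range(1, n):
        D[i, 0] = D[i - 1, 0] + cost[i, 0] - lam
        step[i, 0] = 2
        for j in range(1, m):
            best = D[i - 1, j - 1]
            s = 0
            if D[i, j - 1] < best:
                best = D[i, j - 1]
                s = 1
            if D[i - 1, j] < best:
                best = D[i - 1, j]
                s = 2
            D[i, j] = best + cost[i, j] - lam
            step[i, j] = s
    # backtrack
    path = np.empty((n + m, 2), dtype=np.int64)
    i, j = n - 1, m - 1
    k = 0
    total = 0.0
    while True:
        path[k, 0] = i
        path[k, 1] = j
        total += cost[i, j]
        k += 1
        s = step[i, j]
        if s == -1:
            break
        if s == 0:
            i -= 1
            j -= 1
        elif s == 1:
            j -= 1
        else:
            i -= 1
    out = np.empty((k, 2), dtype=np.int64)
    for a in range(k):
        out[a, 0] = path[k - 1 - a, 0]
        out[a, 1] = path[k - 1 - a, 1]
    return total, k, out


def _cost_matrix(c1: BehaviorCurve, c2: BehaviorCurve) -> np.ndarray:
    a = c1.values[:, None, :]
    b = c2.values[None, :, :]
    return np.sqrt(np.sum((a - b) ** 2, axis=2))


def dtw_align(c1: BehaviorCurve, c2: BehaviorCurve) -> WarpAlignment:
    """Optimal warping between two behavior curves sharing a factor set.

    Minimizes the mean per-step Euclidean cost exactly (Dinkelbach iteration
    over shifted-cost dynamic programs).  Deterministic tie-break among
    equal-cost predecessors: diagonal, then (0,1), then (1,0); equal-energy
    optima are equivalent, only the energy is contract-bearing.
    """
    if c1.factors != c2.factors:
        raise ArgumentError(f"factor sets differ: {c1.factors} vs {c2.factors}")
    if len(c1) == 0 or len(c2) == 0:
        raise DataError("cannot align an empty behavior curve")
    cost = np.ascontiguousarray(_cost_matrix(c1, c2))
    total, k, path = _dp_shifted(cost, 0.0)
    lam = total / k
    for _ in range(100):
        total, k, path = _dp_shifted(cost, lam)
        new_lam = total / k
        if new_lam >= lam - 1e-15:
            lam = min(lam, new_lam)
            break
        lam = new_lam
    return WarpAlignment(path, float(lam))


def bdd_distance(
    t1: Trajectory,
    t2: Trajectory,
    interval: TimeInterval | None = None,
    factors: tuple[str, ...] = ("speed", "curvature"),
    smoothing: SmoothingParams = DEFAULT_SMOOTHING,
    speed_floor: float = DEFAULT_SPEED_FLOOR,
) -> float:
    """BDD_Theta between two trajectories over an analysis window.

    Symmetric, zero for identical trajectories, and bounded above by
    sqrt(|Theta|) thanks to the sigmoid normalization.
    """
    c1 = behavior_curve(t1, interval, factors, smoothing, speed_floor)
    c2 = behavior_curve(t2, interval, factors, smoothing, speed_floor)
    return dtw_align(c1, c2).energy


def pairwise_bdd(
    cohort: list[Trajectory],
    interval: TimeInterval | None = None,
    factors: tuple[str, ...] = ("speed", "curvature"),
    smoothing: SmoothingParams = DEFAULT_SMOOTHING,
    speed_floor: float = DEFAULT_SPEED_FLOOR,
) -> DistanceMatrix:
    """Symmetric matrix of BDD over all unordered pairs of a cohort.

    Behavior curves are extracted once per subject, then aligned pairwise.
    """
    if len(cohort) < 2:
        raise ArgumentError("need at least 2 subjects")
    labels = [t.subject_id for t in cohort]
    if len(set(labels)) != len(labels):
        raise ArgumentError("duplicate subject labels in cohort")
    curves = [behavior_curve(t, interval, factors, smoothing, speed_floor) for t in cohort]
    n = len(cohort)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = dtw_align(curves[i], curves[j]).energy
    return DistanceMatrix(labels, vals, "BDD", interval)


def iibdd(
    traj: Trajectory,
    interval: TimeInterval,
    segment_length_s: float,
    n_pairs: int = 1000,
    seed: int | None = None,
    factors: tuple[str, ...] = ("speed", "curvature"),
    smoothing: SmoothingParams = DEFAULT_SMOOTHING,
    speed_floor: float = DEFAULT_SPEED_FLOOR,
) -> float:
    """Intra-Individual BDD: mean BDD from a subject to itself.

    Draws ``n_pairs`` pairs of equal-length, non-overlapping sub-intervals of
    ``interval`` uniformly at random (rejection sampling on overlap within
    each pair), computes the BDD between the two segments of each pair — each
    segment sigmoid-normalized independently — and returns the mean.

    ``segment_length_s`` is a required protocol parameter: the sub-interval
    length is not standardized, and IIBDD values are only comparable at equal
    segment lengths.
    """
    if interval.length < 2 * segment_length_s:
        raise ArgumentError("interval must be at least twice the segment length")
    win = smoothing.window
    n_seg = int(round(segment_length_s * traj.fps))
    if n_seg < max(3, win):
        raise ArgumentError("segment too short for smoothing window")
    rng = np.random.default_rng(seed)
    t_lo = max(interval.start, float(traj.times[0]))
    t_hi = min(interval.end, float(traj.times[-1]) + 1.0 / traj.fps)
    n_starts = int(np.floor((t_hi - t_lo) * traj.fps)) - n_seg + 1
    if n_starts < 2:
        raise ArgumentError("interval too short for the requested segments")
    total = 0.0
    for _ in range(n_pairs):
        while True:
            k1 = int(rng.integers(n_starts))
            k2 = int(rng.integers(n_starts))
            if abs(k1 - k2) >= n_seg:  # non-overlapping within the pair
                break
        energies = []
        for k in (k1, k2):
            s = t_lo + k / traj.fps
            iv = TimeInterval(s, s + segment_length_s)
            energies.append(behavior_curve(traj, iv, factors, smoothing, speed_floor))
        total += dtw_align(energies[0], energies[1]).energy
    return total / n_pairs
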