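"""Seeded synthetic trajectories with the statistical structure the measures assume.

Trajectories are correlated random walks in a rectangular arena: per frame the
heading turns by a draw from a wrapped turning-angle distribution, the step
length is a speed draw divided by the frame rate, and walls reflect the step
(conserving its length).  Two preset regimes bracket the behaviors of
interest: a "cruise" regime (narrow speed band, concentrated turning, no
immobility) and an "erratic" regime (broad speeds, heavy-tailed turning,
immobility bouts, one spatial attractor), mimicking an ethogram of erratic
swimming interspersed with freezing.  The presets are test fixtures with
realistic magnitudes, not claims about any particular species.

Closed-form paths (line, circle, sine) are provided as noise-free oracles for
the kinematics formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ArgumentError
from .tracking_io import Arena, Trajectory

__all__ = [
    "RegimeParams",
    "CRUISE",
    "ERRATIC",
    "DEFAULT_ARENA",
    "simulate_trajectory",
    "analytic_trajectory",
    "make_cohort",
]

#: default arena: 20 cm x 12 cm tank cross-section, in mm.
DEFAULT_ARENA = Arena(200.0, 120.0)

#: isotropic tracking jitter radius (mm), below the 1/2.4 mm video resolution.
TRACKING_JITTER_MM = 0.3


@dataclass(frozen=True)
class RegimeParams:
    """Kinematic regime of a correlated random walk.

    speed_mean/speed_sd: per-frame speed draw (mm/s), truncated at 0;
    turn_concentration: von Mises concentration of the per-frame heading
    change (low = erratic turning); turn_heavy_tail: probability of replacing
    a draw with a uniform angle (heavy-tailed darting); immobility_rate:
    bouts/min of freezing; immobility_mean_s: mean bout duration (s,
    exponential); attractor/attractor_strength: optional spatial hot spot and
    the per-frame pull toward it; wall_margin: preferred standoff from walls
    (mm).
    """

    speed_mean: float = 30.0
    speed_sd: float = 6.0
    turn_concentration: float = 8.0
    turn_heavy_tail: float = 0.0
    immobility_rate: float = 0.0
    immobility_mean_s: float = 2.0
    attractor: tuple[float, float] | None = None
    attractor_strength: float = 0.0
    wall_margin: float = 5.0

    def __post_init__(self):
        if min(self.speed_mean, self.speed_sd, self.turn_concentration) < 0:
            raise ArgumentError("rates and scales must be nonnegative")
        if not (0 <= self.turn_heavy_tail <= 1):
            raise ArgumentError("turn_heavy_tail must be a probability")
        if self.immobility_rate < 0 or self.immobility_mean_s < 0:
            raise ArgumentError("immobility parameters must be nonnegative")


#: steady swimming: tight speed band, persistent heading, no freezing.
CRUISE = RegimeParams(
    speed_mean=30.0,
    speed_sd=3.0,
    turn_concentration=20.0,
    turn_heavy_tail=0.0,
    immobility_rate=0.0,
)

#: alarmed-like swimming: broad speeds, heavy-tailed turning (darts), long
#: freezing bouts, one spatial attractor (a corner refuge).
ERRATIC = RegimeParams(
    speed_mean=45.0,
    speed_sd=35.0,
    turn_concentration=1.0,
    turn_heavy_tail=0.25,
    immobility_rate=6.0,
    immobility_mean_s=6.0,
    attractor=(40.0, 30.0),
    attractor_strength=0.15,
)


def _reflect(p: np.ndarray, arena: Arena) -> np.ndarray:
    """Reflect a point into the arena across the walls (conserves step length)."""
    x, y = p
    w, h = arena.width, arena.height
    # mirror until inside; at most a couple of bounces for realistic steps
    for _ in range(16):
        moved = False
        if x < 0:
            x = -x
            moved = True
        elif x > w:
            x = 2 * w - x
            moved = True
        if y < 0:
            y = -y
            moved = True
        elif y > h:
            y = 2 * h - y
            moved = True
        if not moved:
            break
    return np.array([min(max(x, 0.0), w), min(max(y, 0.0), h)])


def simulate_trajectory(
    regime: RegimeParams,
    duration_s: float,
    fps: float = 20.0,
    arena: Arena = DEFAULT_ARENA,
    seed: int | None = None,
    subject_id: str = "sim",
    jitter_mm: float = TRACKING_JITTER_MM,
) -> Trajectory:
    """Simulate one correlated-random-walk trajectory.

    Produces exactly ``round(duration_s * fps)`` frames, positions inside the
    arena, reproducible for a fixed seed.  Immobility bouts freeze the
    underlying position; bounded isotropic jitter emulates tracking noise.
    """
    if duration_s <= 0 or fps <= 0:
        raise ArgumentError("duration and fps must be positive")
    if arena.width < 2 * regime.wall_margin or arena.height < 2 * regime.wall_margin:
        raise ArgumentError("arena smaller than twice the wall margin")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fps))
    dt = 1.0 / fps

    pos = np.array([
        rng.uniform(regime.wall_margin, arena.width - regime.wall_margin),
        rng.uniform(regime.wall_margin, arena.height - regime.wall_margin),
    ])
    heading = rng.uniform(-np.pi, np.pi)
    frozen_until = -1.0
    p_bout = regime.immobility_rate / 60.0 * dt

    xy = np.empty((n, 2))
    for k in range(n):
        t = k * dt
        if t < frozen_until:
            pass  # frozen: hold position
        else:
            if p_bout > 0 and rng.random() < p_bout:
                frozen_until = t + rng.exponential(regime.immobility_mean_s)
            else:
                if regime.turn_heavy_tail > 0 and rng.random() < regime.turn_heavy_tail:
                    turn = rng.uniform(-np.pi, np.pi)
                else:
                    turn = rng.vonmises(0.0, regime.turn_concentration)
                heading += turn
                if regime.attractor is not None and regime.attractor_strength > 0:
                    to_att = np.arctan2(
                        regime.attractor[1] - pos[1], regime.attractor[0] - pos[0]
                    )
                    delta = np.angle(np.exp(1j * (to_att - heading)))
                    heading += regime.attractor_strength * delta
                # wall avoidance: inside the margin, turn the approaching
                # heading component back toward the interior
                m = regime.wall_margin
                hx, hy = np.cos(heading), np.sin(heading)
                if (pos[0] < m and hx < 0) or (pos[0] > arena.width - m and hx > 0):
                    hx = -hx
                if (pos[1] < m and hy < 0) or (pos[1] > arena.height - m and hy > 0):
                    hy = -hy
                heading = np.arctan2(hy, hx)
                speed = max(rng.normal(regime.speed_mean, regime.speed_sd), 0.0)
                step = speed * dt
                pos = _reflect(
                    pos + step * np.array([np.cos(heading), np.sin(heading)]), arena
                )
        xy[k] = pos
    if jitter_mm > 0:
        ang = rng.uniform(0, 2 * np.pi, n)
        rad = jitter_mm * np.sqrt(rng.uniform(0, 1, n))
        xy = xy + np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
        xy[:, 0] = np.clip(xy[:, 0], 0.0, arena.width)
        xy[:, 1] = np.clip(xy[:, 1], 0.0, arena.height)
    times = np.arange(n) * dt
    return Trajectory(subject_id, times, xy[:, 0], xy[:, 1], fps, arena)


def analytic_trajectory(
    kind: str,
    duration_s: float,
    fps: float = 100.0,
    arena: Arena = DEFAULT_ARENA,
    speed: float = 100.0,
    radius: float = 50.0,
    omega: float = 1.0,
    amplitude: float = 30.0,
    wavelength: float = 100.0,
    subject_id: str | None = None,
) -> Trajectory:
    """Exact sampled closed-form path (no noise) for kinematics oracles.

    kind="line": constant-velocity segment at ``speed`` mm/s;
    kind="circle": radius ``radius`` mm at angular rate ``omega`` rad/s
    (speed R*omega, curvature 1/R);
    kind="sine": y = amplitude * sin(2 pi x / wavelength) traversed at
    constant horizontal speed.
    """
    n = int(round(duration_s * fps))
    t = np.arange(n) / fps
    cx, cy = arena.width / 2.0, arena.height / 2.0
    if kind == "line":
        x = 5.0 + speed * t
        y = np.full_like(t, cy)
    elif kind == "circle":
        x = cx + radius * np.cos(omega * t)
        y = cy + radius * np.sin(omega * t)
    elif kind == "sine":
        x = 5.0 + speed * t
        y = cy + amplitude * np.sin(2.0 * np.pi * (x - 5.0) / wavelength)
    else:
        raise ArgumentError(f"unknown analytic path {kind!r}")
    if x.min() < 0 or x.max() > arena.width or y.min() < 0 or y.max() > arena.height:
        raise ArgumentError(f"{kind} path exits the arena; shrink its parameters")
    return Trajectory(subject_id or f"analytic-{kind}", t, x, y, fps, arena)


def make_cohort(
    n_per_class: int,
    regimes: list[tuple[str, RegimeParams]],
    duration_s: float = 120.0,
    fps: float = 20.0,
    arena: Arena = DEFAULT_ARENA,
    seed: int | None = None,
) -> tuple[list[Trajectory], dict[str, str]]:
    """Simulate a labeled cohort: ``n_per_class`` subjects per regime.

    Per-subject seeds are spawned deterministically from the master seed, so
    an identical master seed reproduces the cohort bitwise.  Returns the
    trajectories and a subject -> regime-label map.
    """
    if n_per_class < 2:
        raise ArgumentError("need at least 2 subjects per class")
    names = [name for name, _ in regimes]
    if len(set(names)) != len(names):
        raise ArgumentError("duplicate regime labels")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(regimes) * n_per_class)
    trajectories: list[Trajectory] = []
    labels: dict[str, str] = {}
    k = 0
    for name, regime in regimes:
        for i in range(n_per_class):
            subject = f"{name}-{i + 1:02d}"
            sub_seed = int(child_seeds[k].generate_state(1)[0] % (2**31))
            trajectories.append(
                simulate_trajectory(
                    regime, duration_s, fps, arena, seed=sub_seed, subject_id=subject
                )
            )
            labels[subject] = name
            k += 1
    return trajectories, labels
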