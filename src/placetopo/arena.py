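"""Arena geometry and exploratory trajectories.

The modeled environment is a small planar arena (default 1 m x 1 m) with a
rectangular obstacle (default a 25 cm square in the center), so the space has
one connected component and one non-contractible loop: Betti numbers
(b0, b1) = (1, 1).  Exploration is non-preferential: a correlated random walk
at constant speed with heading diffusion and specular reflection at the walls
and the obstacle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

Rect = tuple[float, float, float, float]  # (x0, y0, x1, y1), metres


@dataclass(frozen=True)
class Arena:
    width: float = 1.0
    height: float = 1.0
    obstacles: tuple[Rect, ...] = ()

    def __post_init__(self):
        for (x0, y0, x1, y1) in self.obstacles:
            if not (0 <= x0 < x1 <= self.width and 0 <= y0 < y1 <= self.height):
                raise ValueError(f"obstacle {(x0, y0, x1, y1)} not inside arena bounds")
        if self.free_area <= 0:
            raise ValueError("arena has no free area")

    @property
    def free_area(self) -> float:
        blocked = sum((x1 - x0) * (y1 - y0) for x0, y0, x1, y1 in self.obstacles)
        return self.width * self.height - blocked

    def in_obstacle(self, x, y):
        """Vectorized: True where (x, y) lies strictly inside an obstacle."""
        x = np.asarray(x)
        y = np.asarray(y)
        hit = np.zeros(np.broadcast(x, y).shape, dtype=bool)
        for (x0, y0, x1, y1) in self.obstacles:
            hit |= (x > x0) & (x < x1) & (y > y0) & (y < y1)
        return hit

    def contains(self, x, y):
        """Vectorized: True where (x, y) is inside the arena and outside obstacles."""
        x = np.asarray(x)
        y = np.asarray(y)
        inside = (x >= 0) & (x <= self.width) & (y >= 0) & (y <= self.height)
        return inside & ~self.in_obstacle(x, y)


def default_arena(obstacle_side: float = 0.25) -> Arena:
    """1 m x 1 m arena with a centered square obstacle (default side 25 cm)."""
    half = obstacle_side / 2.0
    return Arena(1.0, 1.0, ((0.5 - half, 0.5 - half, 0.5 + half, 0.5 + half),))


@dataclass(frozen=True)
class Trajectory:
    """Timed positions r(t) = (x(t), y(t)) on a uniform grid."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    v_mean: float

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.n > 1 else 0.0

    @property
    def duration(self) -> float:
        return float(self.t[-1]) if self.n else 0.0


def simulate_trajectory(
    arena: Arena,
    duration: float,
    dt: float = 0.001,
    mean_speed: float = 0.20,
    heading_persistence: float = 1.0,
    seed: int | None = None,
    dt_dynamics: float = 0.01,
) -> Trajectory:
    """Simulate a non-preferential exploratory path.

    The heading performs a diffusion with decorrelation time
    ``heading_persistence`` (seconds) while the speed stays at ``mean_speed``;
    steps that would leave the free space are specularly reflected.  The walk
    is integrated on a coarse ``dt_dynamics`` grid and linearly resampled to
    ``dt`` (positions between dynamics knots stay in free space because the
    free region is a union of convex-boundary pieces at this step scale).

    Deterministic given ``seed``.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    if mean_speed <= 0:
        raise ValueError("mean_speed must be positive")
    if mean_speed * dt_dynamics > min(arena.width, arena.height) / 4:
        raise ValueError("step mean_speed*dt too coarse for the arena")
    dt_dynamics = min(dt_dynamics, duration)

    rng = np.random.default_rng(seed)
    n_steps = max(1, int(round(duration / dt_dynamics)))
    sigma = math.sqrt(2.0 * dt_dynamics / max(heading_persistence, 1e-6))

    # random free start position
    while True:
        x0 = rng.uniform(0, arena.width)
        y0 = rng.uniform(0, arena.height)
        if arena.contains(x0, y0):
            break

    xs = np.empty(n_steps + 1)
    ys = np.empty(n_steps + 1)
    xs[0], ys[0] = x0, y0
    heading = rng.uniform(0, 2 * math.pi)
    turns = rng.normal(0.0, sigma, n_steps)
    step = mean_speed * dt_dynamics

    for k in range(n_steps):
        heading += turns[k]
        dx = step * math.cos(heading)
        dy = step * math.sin(heading)
        x, y = xs[k], ys[k]
        for _ in range(4):  # resolve reflections (corner hits need two passes)
            nx, ny = x + dx, y + dy
            if nx < 0 or nx > arena.width:
                dx = -dx
                heading = math.pi - heading
                continue
            if ny < 0 or ny > arena.height:
                dy = -dy
                heading = -heading
                continue
            if arena.in_obstacle(nx, ny):
                # reflect off the obstacle face the step crosses
                ox0, oy0, ox1, oy1 = _hit_obstacle(arena, nx, ny)
                if x <= ox0 or x >= ox1:
                    dx = -dx
                    heading = math.pi - heading
                else:
                    dy = -dy
                    heading = -heading
                continue
            break
        else:
            nx, ny = x, y  # trapped; stay put this step
        xs[k + 1], ys[k + 1] = nx, ny

    t_coarse = np.arange(n_steps + 1) * dt_dynamics
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    x_fine = np.interp(t, t_coarse, xs)
    y_fine = np.interp(t, t_coarse, ys)
    path_len = float(np.sum(np.hypot(np.diff(xs), np.diff(ys))))
    return Trajectory(t=t, x=x_fine, y=y_fine, v_mean=path_len / duration)


def _hit_obstacle(arena: Arena, x: float, y: float) -> Rect:
    for rect in arena.obstacles:
        x0, y0, x1, y1 = rect
        if x0 < x < x1 and y0 < y < y1:
            return rect
    raise AssertionError("no obstacle contains the point")


def occupancy(trajectory: Trajectory, arena: Arena, grid_n: int) -> np.ndarray:
    """Dwell time (s) per cell of a ``grid_n x grid_n`` partition of the arena.

    Each sample contributes one time step of dwell to its cell; the total
    equals the session duration to within one step.  Cells fully inside an
    obstacle receive zero dwell because the path never enters it.
    """
    if grid_n < 2:
        raise ValueError("grid_n must be >= 2")
    dt = trajectory.dt if trajectory.n > 1 else 0.0
    H, _, _ = np.histogram2d(
        trajectory.x,
        trajectory.y,
        bins=grid_n,
        range=[[0, arena.width], [0, arena.height]],
    )
    return H * dt


def free_cells(arena: Arena, grid_n: int) -> np.ndarray:
    """Boolean mask of grid cells whose center lies in free space."""
    cx = (np.arange(grid_n) + 0.5) * arena.width / grid_n
    cy = (np.arange(grid_n) + 0.5) * arena.height / grid_n
    X, Y = np.meshgrid(cx, cy, indexing="ij")
    return arena.contains(X, Y)


# ---------------------------------------------------------------- CSV I/O

def trajectory_to_csv(traj: Trajectory, path) -> None:
    pd.DataFrame({"t_s": traj.t, "x_m": traj.x, "y_m": traj.y}).to_csv(path, index=False)


def trajectory_from_csv(path) -> Trajectory:
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy(float)
    x = df["x_m"].to_numpy(float)
    y = df["y_m"].to_numpy(float)
    if t.size > 1:
        v = float(np.sum(np.hypot(np.diff(x), np.diff(y))) / (t[-1] - t[0]))
    else:
        v = 0.0
    return Trajectory(t, x, y, v)
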