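"""Conceptual task space: lattice geometry, direction conventions, behavioral scoring.

The task space is a 45x45 lattice of object variants defined by two
morphable feature ratios (0.12..1.88 in steps of 0.04), with the prototype
(the navigation goal) at the central cell.  Coordinates are 0-based integers,
x increasing East, y increasing North; angles are measured counterclockwise
from East in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpaceSpec",
    "LatticePath",
    "PerformanceScore",
    "path_direction",
    "optimal_path_length",
    "performance_score",
    "triplet_direction_count",
    "sample_ring_starts",
    "simulate_strategy_path",
]


@dataclass(frozen=True)
class SpaceSpec:
    """Geometry of the conceptual object space."""

    width: int = 45
    height: int = 45
    ratio_min: float = 0.12
    ratio_max: float = 1.88
    ratio_step: float = 0.04

    def __post_init__(self) -> None:
        if self.width % 2 == 0 or self.height % 2 == 0:
            raise ValueError("space must be odd-sized so the prototype is a unique center")
        span = self.ratio_min + self.ratio_step * (self.width - 1)
        if not math.isclose(span, self.ratio_max, rel_tol=0, abs_tol=1e-9):
            raise ValueError(
                f"ratio grid inconsistent: {self.ratio_min} + {self.ratio_step}*(width-1)"
                f" = {span} != {self.ratio_max}"
            )

    @property
    def prototype(self) -> tuple[int, int]:
        """The central lattice cell (the goal location)."""
        return (self.width // 2, self.height // 2)

    @property
    def radius(self) -> float:
        """Half-extent of the space in cells (center to edge)."""
        return (self.width - 1) / 2

    def contains(self, point) -> bool:
        x, y = point
        return 0 <= x < self.width and 0 <= y < self.height


@dataclass
class LatticePath:
    """An ordered sequence of lattice locations visited by a navigator."""

    locations: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.locations) < 1:
            raise ValueError("path needs at least one location")

    @property
    def start(self) -> tuple[int, int]:
        return self.locations[0]

    @property
    def end(self) -> tuple[int, int]:
        return self.locations[-1]

    @property
    def n_steps(self) -> int:
        return len(self.locations) - 1

    def steps(self) -> list[tuple[int, int]]:
        """Unit step vectors between consecutive locations."""
        return [
            (x1 - x0, y1 - y0)
            for (x0, y0), (x1, y1) in zip(self.locations[:-1], self.locations[1:])
        ]

    def validate_cardinal(self) -> None:
        """Raise if any step is not a single unit move along a cardinal axis."""
        for dx, dy in self.steps():
            if abs(dx) + abs(dy) != 1:
                raise ValueError(f"non-cardinal step ({dx},{dy}) in behavioral path")


@dataclass(frozen=True)
class PerformanceScore:
    """Composite per-trial behavioral score: path excess plus scaled endpoint error.

    Lower is better; the error term E (feature-ratio distance between the
    ending location and the goal) is converted to step units by the feature
    step size 0.04.
    """

    T: float
    T_opt: float
    E: float
    ratio_step: float = 0.04
    score: float = field(init=False)

    def __post_init__(self) -> None:
        if self.T < 0 or self.T_opt < 0 or self.E < 0:
            raise ValueError("T, T_opt and E must be non-negative")
        if self.T < self.T_opt:
            raise ValueError("actual path length cannot be shorter than the optimal one")
        object.__setattr__(self, "score", self.T - self.T_opt + self.E / self.ratio_step)


def path_direction(start, end, convention: str = "start_rel_end") -> float:
    """Direction of a path in degrees in [0, 360).

    convention="start_rel_end" returns the angle of the vector (start - end),
    i.e. where the start lies relative to the ending location ("movement from
    the East" is 0 deg); convention="toward_goal" returns the angle of
    (end - start).  The two always differ by exactly 180 deg.
    """
    sx, sy = start
    ex, ey = end
    if sx == ex and sy == ey:
        raise ValueError("direction undefined: start == end")
    if convention == "start_rel_end":
        dx, dy = sx - ex, sy - ey
    elif convention == "toward_goal":
        dx, dy = ex - sx, ey - sy
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return math.degrees(math.atan2(dy, dx)) % 360.0


def optimal_path_length(start, end) -> int:
    """Shortest cardinal-step path length (Manhattan distance)."""
    return abs(start[0] - end[0]) + abs(start[1] - end[1])


def performance_score(T: float, T_opt: float, E: float) -> PerformanceScore:
    """Composite score T - T_opt + E/0.04 (lower = better)."""
    return PerformanceScore(T=T, T_opt=T_opt, E=E)


def triplet_direction_count(path: LatticePath) -> int:
    """Number of unique net-displacement directions over consecutive step triplets.

    The step sequence is partitioned into non-overlapping windows of three
    steps from the path start (a trailing remainder of fewer than three steps
    is dropped); each window contributes the direction of its net displacement.
    A strictly axis-by-axis ("horizontal-vertical") path yields 2.
    """
    steps = path.steps()
    if len(steps) < 3:
        raise ValueError("triplet direction count needs a path with at least 3 steps")
    dirs = set()
    for i in range(0, len(steps) - len(steps) % 3, 3):
        dx = sum(s[0] for s in steps[i : i + 3])
        dy = sum(s[1] for s in steps[i : i + 3])
        if dx == 0 and dy == 0:
            continue  # closed triplet carries no direction
        dirs.add(round(math.degrees(math.atan2(dy, dx)) % 360.0, 9))
    return len(dirs)


def sample_ring_starts(
    spec: SpaceSpec | None = None,
    per_bin: int = 24,
    bin_width: float = 30.0,
    precision: float = 1.25,
    radius: float = 21.0,
    radius_jitter: int = 1,
    seed: int | None = None,
):
    """Sample start locations on a near-boundary ring, balanced over direction bins.

    Directions are quantized to the `precision` grid (1.25 deg by default) and
    drawn without replacement within each `bin_width` bin, `per_bin` per bin
    (24 per 30 deg bin -> 288 starts).  Each start lies on a ring of
    ``radius +/- radius_jitter`` cells around the prototype, at the angle of
    its assigned direction under the start-relative-to-goal convention.

    Returns a list of ((x, y), direction_deg) pairs sorted by direction.
    """
    if spec is None:
        spec = SpaceSpec()
    if 360.0 % bin_width != 0:
        raise ValueError("bin_width must divide 360")
    slots_per_bin = bin_width / precision
    if slots_per_bin != int(slots_per_bin):
        raise ValueError("precision must divide bin_width")
    slots_per_bin = int(slots_per_bin)
    if per_bin > slots_per_bin:
        raise ValueError(
            f"per_bin={per_bin} exceeds the {slots_per_bin} distinct "
            f"{precision} deg slots available per {bin_width} deg bin"
        )
    rng = np.random.default_rng(seed)
    n_bins = int(360.0 // bin_width)
    cx, cy = spec.prototype
    out = []
    for b in range(n_bins):
        slots = rng.choice(slots_per_bin, size=per_bin, replace=False)
        for s in sorted(slots):
            theta = b * bin_width + s * precision
            r = radius + rng.integers(-radius_jitter, radius_jitter + 1)
            # start lies at angle theta from the goal: (start - goal) points at theta
            x = int(round(cx + r * math.cos(math.radians(theta))))
            y = int(round(cy + r * math.sin(math.radians(theta))))
            x = min(max(x, 0), spec.width - 1)
            y = min(max(y, 0), spec.height - 1)
            out.append(((x, y), theta))
    return out


def simulate_strategy_path(start, goal, strategy: str, seed: int | None = None) -> LatticePath:
    """Construct a monotone cardinal-step path under a movement strategy.

    "radial_adjustment" alternates unit steps between the two axes (emulating
    a participant adjusting both features in turn) until one axis is matched,
    then finishes along the other; "horizontal_vertical" completes one axis
    entirely before the other.  Both reach the goal in exactly the Manhattan
    distance.  The seed decides which axis moves first.
    """
    if tuple(start) == tuple(goal):
        raise ValueError("start must differ from goal")
    rng = np.random.default_rng(seed)
    dx = goal[0] - start[0]
    dy = goal[1] - start[1]
    step_x = (int(np.sign(dx)), 0)
    step_y = (0, int(np.sign(dy)))
    nx, ny = abs(dx), abs(dy)
    x_first = bool(rng.integers(2)) if nx and ny else nx > 0

    steps: list[tuple[int, int]] = []
    if strategy == "horizontal_vertical":
        first, nfirst, second, nsecond = (
            (step_x, nx, step_y, ny) if x_first else (step_y, ny, step_x, nx)
        )
        steps = [first] * nfirst + [second] * nsecond
    elif strategy == "radial_adjustment":
        a, na, b, nb = (step_x, nx, step_y, ny) if x_first else (step_y, ny, step_x, nx)
        while na or nb:
            if na:
                steps.append(a)
                na -= 1
            if nb:
                steps.append(b)
                nb -= 1
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    locs = [tuple(start)]
    for sx, sy in steps:
        x, y = locs[-1]
        locs.append((x + sx, y + sy))
    assert locs[-1] == tuple(goal)
    return LatticePath(locations=locs)
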