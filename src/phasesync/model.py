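"""The EC-HPC PhaseSync model.

Entorhinal grid cells are modeled as sums of three cosine gratings whose
plane waves are 60 deg apart, one cell per phase offset on the 45x45 task
lattice.  Mentally traversing a straight path sums the population pattern
over path locations into a "path code" V; V is identical for a direction
phi and phi+180, so paths live on orientations psi in [0, 180).  Pooling V
to a scalar delta(psi) yields a threefold alignment profile over
orientations, peaking on the three grid axes.  A hippocampal goal field
C(R) = cos(delta_c*Phi_R + delta_eps) + exp(-|R-q|^2 / (2*sigma^2))
combines that threefold directional structure with Gaussian goal proximity
and drives winner-take-all navigation; path lengths across start directions
inherit the threefold periodicity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .space import SpaceSpec
from .spectrum import FoldSpectrum, PermutationNull, circular_resample, _prepare

__all__ = [
    "GridParams",
    "GoalField",
    "NavRun",
    "grid_code",
    "population_pattern",
    "rasterize_path",
    "path_code",
    "delta_profile",
    "delta_epsilon_for",
    "goal_field",
    "navigate",
    "run_simulation",
    "SimulationResult",
]


@dataclass(frozen=True)
class GridParams:
    """Cosine-grating grid-cell population parameters.

    `orientation` is the allocentric angle (deg) of the first grid axis;
    axes sit at orientation + {0, 60, 120} and plane-wave vectors
    perpendicular to them.  `period` is the plane-wave wavelength in lattice
    cells (grid scale); `amplitude` scales each grating.
    """

    amplitude: float = 1.0
    period: float = 9.0
    orientation: float = 15.0
    size: int = 45

    @property
    def omega(self) -> float:
        """Angular spatial frequency (radians per cell) of each grating."""
        return 2 * math.pi / self.period

    @property
    def wave_angles(self) -> np.ndarray:
        """Plane-wave vector angles (deg): perpendicular to the grid axes."""
        return self.orientation + 90.0 + np.array([0.0, 60.0, 120.0])

    @property
    def wave_vectors(self) -> np.ndarray:
        ang = np.radians(self.wave_angles)
        return np.column_stack([np.cos(ang), np.sin(ang)])

    @property
    def axis_orientations(self) -> np.ndarray:
        """The three grid-axis orientations in [0, 180)."""
        return (self.orientation + np.array([0.0, 60.0, 120.0])) % 180.0


@dataclass
class GoalField:
    """Hippocampal goal field over the lattice.

    ``C`` holds the field sampled at integer cells (indexed [y, x]); ``at``
    evaluates the same closed-form field at arbitrary real positions, which
    sub-cell navigation uses.
    """

    C: np.ndarray  # indexed [y, x]
    goal: tuple[float, float]
    delta_c: int
    delta_eps: float
    sigma: float
    directional_weight: float = 1.0

    def value(self, x: int, y: int) -> float:
        return float(self.C[y, x])

    def at(self, x, y):
        qx, qy = self.goal
        Phi = np.arctan2(qy - np.asarray(y, float), qx - np.asarray(x, float))
        d2 = (np.asarray(x, float) - qx) ** 2 + (np.asarray(y, float) - qy) ** 2
        out = self.directional_weight * np.cos(self.delta_c * Phi + self.delta_eps) + np.exp(
            -d2 / (2 * self.sigma**2)
        )
        return np.where(d2 == 0, 1.0, out)


@dataclass
class NavRun:
    """One winner-take-all navigation run."""

    start: tuple[float, float]
    goal: tuple[float, float]
    visited: list[tuple[float, float]]
    flagged: bool = False

    @property
    def path_length(self) -> float:
        pts = np.asarray(self.visited, float)
        if len(pts) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))

    @property
    def terminal(self) -> tuple[int, int]:
        return self.visited[-1]


def grid_code(c, r, params: GridParams) -> float:
    """Activity of the grid cell with phase offset c at location r (Eq. of the grating sum)."""
    rx, ry = r
    cx, cy = c
    k = params.wave_vectors
    args = params.omega * (k[:, 0] * (rx - cx) + k[:, 1] * (ry - cy))
    return float(params.amplitude * np.cos(args).sum())


def population_pattern(r, params: GridParams) -> np.ndarray:
    """Grid-cell population activity at location r, one cell per lattice offset c.

    Returns an array indexed [cy, cx] of shape (size, size); the maximum 3*A
    is attained where the offset coincides with r (mod the pattern period).
    """
    n = params.size
    cx = np.arange(n)[None, :, None]  # broadcast: [cy, cx, wave]
    cy = np.arange(n)[:, None, None]
    rx, ry = r
    k = params.wave_vectors
    args = params.omega * (k[None, None, :, 0] * (rx - cx) + k[None, None, :, 1] * (ry - cy))
    return params.amplitude * np.cos(args).sum(axis=-1)


def rasterize_path(start, end, samples_per_cell: int = 8) -> list[tuple[int, int]]:
    """Lattice cells crossed by the straight segment start->end, ordered, deterministic.

    Endpoints may be real-valued; the segment is sampled densely, rounded to
    the nearest cell, and de-duplicated preserving order (a supercover-style
    rasterization).  Both endpoint cells are included.
    """
    sx, sy = float(start[0]), float(start[1])
    ex, ey = float(end[0]), float(end[1])
    length = max(abs(ex - sx), abs(ey - sy))
    n = max(int(math.ceil(length * samples_per_cell)), 1) + 1
    t = np.linspace(0.0, 1.0, n)
    xs = np.round(sx + (ex - sx) * t).astype(int)
    ys = np.round(sy + (ey - sy) * t).astype(int)
    cells: list[tuple[int, int]] = []
    for x, y in zip(xs, ys):
        if not cells or cells[-1] != (x, y):
            cells.append((int(x), int(y)))
    return cells


def _path_samples(start, end, step: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Equally spaced sample locations (continuous) along the segment, endpoints included."""
    sx, sy = float(start[0]), float(start[1])
    ex, ey = float(end[0]), float(end[1])
    length = math.hypot(ex - sx, ey - sy)
    m = max(int(math.floor(length / step)), 1) + 1
    t = np.linspace(0.0, 1.0, m)
    return sx + (ex - sx) * t, sy + (ey - sy) * t


def path_code(
    start, goal, params: GridParams, sampling: str = "lattice", step: float = 1.0
) -> np.ndarray:
    """Path code V: population patterns summed over locations along start->goal.

    sampling="lattice" sums over the rasterized lattice cells the segment
    crosses (the discrete mental trajectory); sampling="continuous" sums
    over equally spaced real-valued locations (spacing `step` cells), which
    removes rasterization jitter when V is reduced to the orientation
    profile delta(psi).
    """
    V = np.zeros((params.size, params.size))
    if sampling == "lattice":
        for r in rasterize_path(start, goal):
            V += population_pattern(r, params)
    elif sampling == "continuous":
        xs, ys = _path_samples(start, goal, step)
        for r in zip(xs, ys):
            V += population_pattern(r, params)
    else:
        raise ValueError(f"unknown sampling {sampling!r}")
    return V


def _pool(V: np.ndarray, rule: str) -> float:
    if rule == "energy":
        return float(np.mean(V**2))
    if rule == "max":
        return float(V.max())
    raise ValueError(f"unknown pooling rule {rule!r}")


def delta_profile(
    params: GridParams,
    orientations_deg=None,
    radius: float = 21.0,
    pooling: str = "energy",
    sampling: str = "continuous",
):
    """Alignment profile delta(psi) over orientations [0, 180).

    For each orientation psi a straight path is simulated from the ring
    location at angle psi (radius cells from the center) to the center, its
    path code V computed, and V pooled to a scalar.  Pooling "energy" (the
    default) is the mean of V^2 across the population — the coherence energy
    of the summed pattern; "max" reads out the single best-aligned
    downstream unit.  Both are threefold over [0, 180): coherent planar
    waves (large delta) appear when psi lies on a grid axis.

    Returns (orientations, delta values).
    """
    if orientations_deg is None:
        orientations_deg = np.arange(0.0, 180.0, 1.0)
    psi = np.asarray(orientations_deg, float)
    center = ((params.size - 1) / 2, (params.size - 1) / 2)
    if radius > (params.size - 1) / 2 + 1:
        raise ValueError("ring radius exceeds the lattice")
    delta = np.empty(psi.size)
    for i, p in enumerate(psi):
        start = (
            center[0] + radius * math.cos(math.radians(p)),
            center[1] + radius * math.sin(math.radians(p)),
        )
        delta[i] = _pool(path_code(start, center, params, sampling=sampling), pooling)
    return psi, delta


def count_profile_peaks(
    psi: np.ndarray, delta: np.ndarray, prominence_frac: float = 0.1
):
    """Prominence-filtered local maxima of a periodic orientation profile.

    Returns (peak orientations, count).  The profile is circularly extended
    so maxima at the domain wrap are found once.
    """
    from scipy.signal import find_peaks

    n = delta.size
    tiled = np.concatenate([delta, delta, delta])
    prom = prominence_frac * (delta.max() - delta.min())
    peaks, _ = find_peaks(tiled, prominence=prom)
    peaks = peaks[(peaks >= n) & (peaks < 2 * n)] - n
    return psi[peaks], peaks.size


def delta_epsilon_for(params: GridParams, delta_c: int = 3) -> float:
    """Phase offset (radians) placing the goal-field cosine peaks on the grid axes.

    Each axis has two opposite directions; by convention the preferred
    directions are orientation + {0, 120, 240}, giving
    delta_eps = -delta_c * orientation.
    """
    return float(-delta_c * math.radians(params.orientation))


def goal_field(
    q,
    delta_c: int = 3,
    delta_eps: float | None = None,
    sigma: float | None = None,
    params: GridParams | None = None,
    size: int = 45,
    directional_weight: float = 1.0,
) -> GoalField:
    """Goal field C(R) = w*cos(delta_c*Phi_R + delta_eps) + exp(-|R-q|^2/(2 sigma^2)).

    Phi_R = atan2(q_y - R_y, q_x - R_x) is the allocentric direction from R
    toward the goal; sigma defaults to the radius of the space.  At R = q
    the direction is undefined: the Gaussian term is 1 and the directional
    term is set to its circular mean (zero), a documented convention.
    `directional_weight` scales (or suppresses, at 0) the cosine term.
    """
    if params is not None:
        size = params.size
        if delta_eps is None:
            delta_eps = delta_epsilon_for(params, delta_c)
    if delta_eps is None:
        delta_eps = 0.0
    if sigma is None:
        sigma = (size - 1) / 2
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    qx, qy = float(q[0]), float(q[1])
    if not (0 <= qx < size and 0 <= qy < size):
        raise ValueError("goal outside the lattice")
    X, Y = np.meshgrid(np.arange(size), np.arange(size))  # [y, x]
    Phi = np.arctan2(qy - Y, qx - X)
    d2 = (X - qx) ** 2 + (Y - qy) ** 2
    C = directional_weight * np.cos(delta_c * Phi + delta_eps) + np.exp(-d2 / (2 * sigma**2))
    at_goal = d2 == 0
    if at_goal.any():
        C[at_goal] = 1.0  # Gaussian 1, directional term at its mean (0)
    return GoalField(
        C=C, goal=(qx, qy), delta_c=delta_c, delta_eps=float(delta_eps),
        sigma=float(sigma), directional_weight=float(directional_weight),
    )


def _ring_offsets(s: int) -> list[tuple[int, int]]:
    """Chebyshev ring at radius s, ordered clockwise from East; deterministic tie-break."""
    offs = [
        (dx, dy)
        for dx in range(-s, s + 1)
        for dy in range(-s, s + 1)
        if max(abs(dx), abs(dy)) == s
    ]
    # clockwise from East: descending angle starting at 0
    offs.sort(key=lambda o: (-math.atan2(o[1], o[0])) % (2 * math.pi))
    return offs


_RING_CACHE: dict[int, np.ndarray] = {}


def _ring(s: int) -> np.ndarray:
    if s not in _RING_CACHE:
        _RING_CACHE[s] = np.asarray(_ring_offsets(s), float)
    return _RING_CACHE[s]


def navigate(
    start,
    fld: GoalField,
    max_step: int = 5,
    max_iters: int = 500,
    resolution: float = 1.0,
) -> NavRun:
    """Winner-take-all ascent of the goal field with adaptive step size.

    From the current location the Chebyshev ring at radius s (starting at
    one grid step) is scanned in a fixed clockwise-from-East order; the
    agent moves to the strongest ring location if it beats the current
    location's field value, otherwise s grows until the ring radius reaches
    `max_step` cells.  The run ends when the agent is within one cell of the
    goal, when no ring improves, or at `max_iters` (flagged).

    `resolution` sets the movement grid in cells: 1.0 walks the integer
    lattice (field values from the precomputed table); finer values (e.g.
    0.25) walk a sub-cell grid with the field evaluated in closed form,
    which removes the eightfold step-direction anisotropy of the coarse
    lattice.
    """
    size = fld.C.shape[0]
    x, y = float(start[0]), float(start[1])
    if not (0 <= x < size and 0 <= y < size):
        raise ValueError("start outside the lattice")
    qx, qy = fld.goal
    coarse = resolution == 1.0
    if coarse:
        x, y = int(round(x)), int(round(y))
    n_rings = int(round(max_step / resolution))
    visited = [(x, y)]
    flagged = False
    for _ in range(max_iters):
        if max(abs(x - qx), abs(y - qy)) <= 1.0:
            break
        here = fld.C[int(y), int(x)] if coarse else float(fld.at(x, y))
        moved = False
        for s in range(1, n_rings + 1):
            offs = _ring(s) * resolution
            nx = x + offs[:, 0]
            ny = y + offs[:, 1]
            ok = (nx >= 0) & (nx <= size - 1) & (ny >= 0) & (ny <= size - 1)
            if not ok.any():
                continue
            nx, ny = nx[ok], ny[ok]
            vals = (
                fld.C[ny.astype(int), nx.astype(int)] if coarse else fld.at(nx, ny)
            )
            j = int(np.argmax(vals))  # first maximum in clockwise-from-East order
            if vals[j] > here:
                x, y = (int(nx[j]), int(ny[j])) if coarse else (float(nx[j]), float(ny[j]))
                visited.append((x, y))
                moved = True
                break
        if not moved:
            break
    else:
        flagged = True
    return NavRun(start=tuple(start), goal=fld.goal, visited=visited, flagged=flagged)


@dataclass
class SimulationResult:
    """Random-goal navigation protocol output."""

    runs: pd.DataFrame
    mean_spectrum: FoldSpectrum
    null: PermutationNull
    significant_folds: set[int]
    per_goal_values: np.ndarray  # (n_goals, n_grid) resampled path lengths

    @property
    def argmax_fold(self) -> int:
        return self.mean_spectrum.argmax_fold()


def _mean_spectrum_null(values: np.ndarray, n_perm: int, rng) -> PermutationNull:
    """Max-statistic null for a mean-across-goals spectrum.

    Each goal's per-direction vector is label-shuffled independently per
    permutation; the spectrum pipeline is re-run and averaged across goals.
    """
    n_goals, n_grid = values.shape
    mags_obs_shape = n_grid // 2 + 1
    maxima = np.empty(n_perm)
    per_fold = np.empty((n_perm, mags_obs_shape))
    for p in range(n_perm):
        shuf = rng.permuted(values, axis=1)
        mags = np.abs(np.fft.rfft(_prepare(shuf), axis=1)).mean(axis=0)
        per_fold[p] = mags
        maxima[p] = mags[1:].max()
    return PermutationNull(
        per_fold=np.percentile(per_fold, 95, axis=0),
        fwe=float(np.percentile(maxima, 95)),
        n_perm=n_perm,
    )


def run_simulation(
    params: GridParams | None = None,
    n_goals: int = 100,
    n_starts: int = 120,
    delta_c: int = 3,
    sigma: float | None = None,
    directional_weight: float = 1.0,
    n_grid: int = 36,
    n_perm: int = 5000,
    max_step: int = 5,
    resolution: float = 0.25,
    annulus_inner_frac: float = 0.15,
    seed: int | None = None,
    spec: SpaceSpec | None = None,
) -> SimulationResult:
    """Random-goal navigation protocol.

    `n_goals` goal locations are drawn uniformly from the lattice interior
    (margin about sigma/4 from the boundary).  Each goal is paired with
    `n_starts` starting locations spread over all directions (pseudo-random
    angles on a uniform grid with within-slot jitter) at pseudo-random radii
    spanning an annulus from ``annulus_inner_frac`` times to the full
    goal-to-boundary distance, mirroring the task's ring-shaped sampling
    region around the prototype.  Per goal, path lengths from
    winner-take-all navigation (sub-cell `resolution`) are sorted by
    start->goal direction, resampled onto a uniform `n_grid` direction grid
    and Fourier analyzed; the mean spectrum across goals is tested against a
    label-shuffle max-statistic permutation threshold.
    """
    if params is None:
        params = GridParams()
    if spec is None:
        spec = SpaceSpec(width=params.size, height=params.size)
    rng = np.random.default_rng(seed)
    size = params.size
    if sigma is None:
        sigma = (size - 1) / 2
    margin = max(int(round(sigma / 4)), 1)

    rows = []
    per_goal = np.empty((n_goals, n_grid))
    delta_eps = delta_epsilon_for(params, delta_c)
    slot = 360.0 / n_starts
    for g in range(n_goals):
        q = (
            rng.uniform(margin, size - 1 - margin),
            rng.uniform(margin, size - 1 - margin),
        )
        fld = goal_field(
            q, delta_c=delta_c, delta_eps=delta_eps, sigma=sigma,
            size=size, directional_weight=directional_weight,
        )
        base_r = min(q[0], q[1], size - 1 - q[0], size - 1 - q[1]) - 1.0
        angles = (np.arange(n_starts) * slot + rng.uniform(0, slot, n_starts)) % 360.0
        dirs = np.empty(n_starts)
        lens = np.empty(n_starts)
        for i, ang in enumerate(angles):
            r = max(rng.uniform(annulus_inner_frac * base_r, base_r), 1.5)
            sx = q[0] + r * math.cos(math.radians(ang))
            sy = q[1] + r * math.sin(math.radians(ang))
            sx = min(max(sx, 0.0), size - 1.0)
            sy = min(max(sy, 0.0), size - 1.0)
            run = navigate((sx, sy), fld, max_step=max_step, resolution=resolution)
            dirs[i] = math.degrees(math.atan2(q[1] - sy, q[0] - sx)) % 360.0
            lens[i] = run.path_length
            rows.append((q[0], q[1], sx, sy, dirs[i], lens[i], run.flagged))
        per_goal[g] = circular_resample(dirs, lens, n_grid)

    mean_mags = np.abs(np.fft.rfft(_prepare(per_goal), axis=1)).mean(axis=0)
    spectrum = FoldSpectrum(magnitudes=mean_mags, n_bins=n_grid)
    null = _mean_spectrum_null(per_goal, n_perm, rng)
    null.seed = seed
    sig = {int(f) for f in range(1, mean_mags.size) if mean_mags[f] > null.fwe}
    runs = pd.DataFrame(
        rows,
        columns=["goal_x", "goal_y", "start_x", "start_y", "direction_deg", "path_length", "flagged"],
    )
    return SimulationResult(
        runs=runs,
        mean_spectrum=spectrum,
        null=null,
        significant_folds=sig,
        per_goal_values=per_goal,
    )
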