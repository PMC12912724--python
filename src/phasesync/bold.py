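"""Synthetic event designs and direction-modulated BOLD-like time series.

Emulates the study design this package analyzes: 8 event-related sessions of
36 direction trials plus 4 lure trials each, TR = 2 s, per-trial neural
amplitude ``baseline + a*cos(k*(theta - phi*))`` convolved with a canonical
double-gamma hemodynamic response, plus i.i.d. Gaussian noise.  Ground-truth
parameters are carried alongside so estimator recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import gamma as _gamma

__all__ = [
    "EventDesign",
    "GroundTruth",
    "RegionTruth",
    "make_event_design",
    "hrf_double_gamma",
    "convolve_events",
    "simulate_voxel",
    "simulate_region",
    "simulate_behavior",
]

EVENT_COLUMNS = ["onset", "duration", "direction_deg", "session", "trial_type"]

# task timing: 2 s fixation then a 10 s trial window, on the TR grid
TRIAL_SPACING_S = 12.0
FIXATION_S = 2.0
TRIAL_DURATION_S = 10.0


@dataclass
class EventDesign:
    """Trial table consumed by both GLM stages.

    ``table`` columns: onset (s), duration (s), direction_deg (NaN for
    lures), session (1-based), trial_type ("direction" | "lure").
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"event table missing column(s): {', '.join(missing)}")
        for sess, grp in self.table.groupby("session"):
            onsets = grp["onset"].to_numpy()
            if np.any(np.diff(onsets) <= 0):
                raise ValueError(f"onsets not strictly increasing in session {sess}")

    @property
    def sessions(self) -> list[int]:
        return sorted(self.table["session"].unique())

    def session(self, sess: int) -> "EventDesign":
        return EventDesign(self.table[self.table["session"] == sess].reset_index(drop=True))

    def direction_trials(self) -> pd.DataFrame:
        return self.table[self.table["trial_type"] == "direction"]

    @property
    def directions(self) -> np.ndarray:
        return self.direction_trials()["direction_deg"].to_numpy(float)


@dataclass(frozen=True)
class GroundTruth:
    """Planted directional tuning of a simulated voxel."""

    fold: int = 6
    phi: float = 15.0  # deg, in [0, 360/fold)
    amplitude: float = 1.0
    baseline: float = 1.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValueError("fold must be >= 1")
        if not 0 <= self.phi < 360.0 / self.fold:
            raise ValueError(f"phi must lie in [0, {360.0 / self.fold}) for fold {self.fold}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RegionTruth:
    """A multi-voxel region sharing a fold, with von Mises-spread voxel orientations.

    kappa is the von Mises concentration of voxel orientations in k*phi
    space; kappa -> inf collapses every voxel onto the shared orientation,
    kappa = 0 scatters them uniformly.
    """

    n_voxels: int
    kappa: float
    truth: GroundTruth = field(default_factory=GroundTruth)

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


def make_event_design(
    directions,
    n_sessions: int = 8,
    trials_per_session: int = 36,
    lures_per_session: int = 4,
    trial_spacing: float = TRIAL_SPACING_S,
    seed: int | None = None,
) -> EventDesign:
    """Partition direction labels into sessions and lay trials on a fixed grid.

    The `directions` pool (length n_sessions * trials_per_session, e.g. the
    288 ring-start directions) is shuffled and split across sessions without
    replacement; `lures_per_session` lure trials (blank screens, no
    direction) are interleaved at random trial positions.  Trial i of a
    session starts at ``FIXATION_S + i*trial_spacing`` seconds.
    """
    directions = np.asarray(directions, float)
    if directions.size != n_sessions * trials_per_session:
        raise ValueError(
            f"need {n_sessions * trials_per_session} directions, got {directions.size}"
        )
    rng = np.random.default_rng(seed)
    pool = rng.permutation(directions)
    rows = []
    per = trials_per_session + lures_per_session
    for sess in range(1, n_sessions + 1):
        sess_dirs = pool[(sess - 1) * trials_per_session : sess * trials_per_session]
        lure_pos = set(rng.choice(per, size=lures_per_session, replace=False).tolist())
        d_iter = iter(sess_dirs)
        for i in range(per):
            onset = FIXATION_S + i * trial_spacing
            if i in lure_pos:
                rows.append((onset, TRIAL_DURATION_S, np.nan, sess, "lure"))
            else:
                rows.append((onset, TRIAL_DURATION_S, float(next(d_iter)), sess, "direction"))
    return EventDesign(pd.DataFrame(rows, columns=EVENT_COLUMNS))


def hrf_double_gamma(time_grid) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, unit peak.

    Response gamma with shape 6, undershoot gamma with shape 16 (unit
    dispersions), undershoot ratio 1/6; peak near 5 s, zero at t = 0.
    """
    t = np.asarray(time_grid, float)
    if np.any(t < 0):
        raise ValueError("time grid must be non-negative")
    h = _gamma.pdf(t, a=6.0) - _gamma.pdf(t, a=16.0) / 6.0
    peak = h.max()
    if peak > 0:
        h = h / peak
    return h


def convolve_events(
    onsets, amplitudes, n_scans: int, TR: float = 2.0, dt: float = 0.1
) -> np.ndarray:
    """Convolve amplitude-weighted event impulses with the HRF, sampled at TR.

    Impulses are placed on a microtime grid of resolution `dt`; the forward
    simulator and the GLM design builders share this routine so that a
    noiseless simulation is reproduced exactly by the matching design.
    """
    onsets = np.asarray(onsets, float)
    amplitudes = np.asarray(amplitudes, float)
    n_fine = int(round(n_scans * TR / dt))
    x = np.zeros(n_fine)
    idx = np.round(onsets / dt).astype(int)
    if np.any(idx >= n_fine):
        raise ValueError("event onsets extend past the scan window")
    np.add.at(x, idx, amplitudes)
    kernel = hrf_double_gamma(np.arange(0, 32.0 + dt / 2, dt))
    conv = np.convolve(x, kernel)[:n_fine]
    scan_idx = np.round(np.arange(n_scans) * TR / dt).astype(int)
    return conv[scan_idx]


def n_scans_for(design: EventDesign, TR: float = 2.0, tail_s: float = 24.0) -> int:
    """Scans needed to cover every session's events plus an HRF tail."""
    last = design.table.groupby("session")["onset"].max().max()
    return int(np.ceil((last + TRIAL_DURATION_S + tail_s) / TR))


def trial_amplitudes(directions_deg, truth: GroundTruth) -> np.ndarray:
    """Per-trial neural amplitude baseline + a*cos(k*(theta - phi*))."""
    th = np.radians(np.asarray(directions_deg, float))
    phi = np.radians(truth.phi)
    return truth.baseline + truth.amplitude * np.cos(truth.fold * (th - phi))


def simulate_voxel(
    design: EventDesign,
    truth: GroundTruth,
    TR: float = 2.0,
    n_scans: int | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Simulate one voxel's session-wise time series; returns (n_sessions, n_scans).

    Each direction trial contributes an impulse of amplitude
    ``baseline + a*cos(k*(theta - phi*))`` at its onset; lures contribute a
    baseline-only impulse.  Impulses are convolved with the double-gamma HRF
    and i.i.d. Gaussian noise of sd `noise_sd` is added per scan.
    """
    if n_scans is None:
        n_scans = n_scans_for(design, TR)
    rng = np.random.default_rng(seed)
    out = np.zeros((len(design.sessions), n_scans))
    for row, sess in enumerate(design.sessions):
        tab = design.session(sess).table
        is_dir = (tab["trial_type"] == "direction").to_numpy()
        amps = np.full(len(tab), truth.baseline)
        amps[is_dir] = trial_amplitudes(tab.loc[is_dir, "direction_deg"], truth)
        clean = convolve_events(tab["onset"].to_numpy(), amps, n_scans, TR)
        out[row] = clean + rng.normal(0.0, truth.noise_sd, n_scans)
    return out


def simulate_region(
    design: EventDesign,
    region: RegionTruth,
    TR: float = 2.0,
    n_scans: int | None = None,
    seed: int | None = None,
):
    """Simulate a region: (n_voxels, n_sessions, n_scans) plus per-voxel phi*.

    Voxel orientations are drawn von Mises around k*phi* in fold space and
    divided back by k, so each voxel keeps the shared fold but its own
    orientation; kappa = 0 is exactly uniform.
    """
    rng = np.random.default_rng(seed)
    t = region.truth
    mu = np.radians(t.fold * t.phi)
    if region.kappa == 0:
        folded = rng.uniform(0, 2 * np.pi, region.n_voxels)
    else:
        folded = rng.vonmises(mu, region.kappa, region.n_voxels) % (2 * np.pi)
    phis = np.degrees(folded) / t.fold
    if n_scans is None:
        n_scans = n_scans_for(design, TR)
    series = np.empty((region.n_voxels, len(design.sessions), n_scans))
    for v in range(region.n_voxels):
        vt = GroundTruth(
            fold=t.fold, phi=float(phis[v]), amplitude=t.amplitude,
            baseline=t.baseline, noise_sd=t.noise_sd,
        )
        series[v] = simulate_voxel(
            design, vt, TR, n_scans, seed=int(rng.integers(2**31)),
        )
    return series, phis


def simulate_behavior(
    directions,
    fold: int = 3,
    phase: float = 0.0,
    amplitude: float = 1.0,
    baseline: float = 10.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Per-direction performance scores with a planted fold.

    score(theta) = baseline + amplitude*cos(fold*(theta - phase)) + noise.
    (With performance scored lower-is-better a positive amplitude plants the
    score peaks at the phase; the spectral analysis is sign-agnostic.)
    """
    th = np.radians(np.asarray(directions, float))
    rng = np.random.default_rng(seed)
    clean = baseline + amplitude * np.cos(fold * (th - np.radians(phase)))
    return clean + rng.normal(0.0, noise_sd, th.size)
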