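"""Sinusoidal-modulation GLMs: quadrature fits, orientation estimates, cross-validated
alignment, direction-bin GLMs, and tuning-curve reconstruction.

The quadrature GLM models direction-evoked activity with two parametric
modulators sin(k*theta) and cos(k*theta) convolved with the hemodynamic
response; the estimated weights give the grid orientation
phi = atan2(beta_sine, beta_cosine)/k on [0, 360/k).  Fold k = 6 is the
entorhinal (hexadirectional) signature; k in {3,4,5,7} serve as controls and
k = 3 is the hippocampal signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .bold import EventDesign, convolve_events, n_scans_for

__all__ = [
    "QuadratureFit",
    "OrientationEstimate",
    "DirectionBinBetas",
    "QuadratureDesign",
    "build_quadrature_design",
    "fit_quadrature",
    "orientation_from_betas",
    "mean_grid_orientation",
    "crossval_alignment",
    "fit_direction_bins",
    "reconstruct_tuning",
]

DEFAULT_FOLDS = (3, 4, 5, 6, 7)


@dataclass(frozen=True)
class QuadratureFit:
    beta_sine: float
    beta_cosine: float
    fold: int
    session: int | None = None
    residual_var: float = np.nan

    @property
    def amplitude(self) -> float:
        """Amplitude of the fitted k-fold tuning curve."""
        return float(np.hypot(self.beta_sine, self.beta_cosine))


@dataclass(frozen=True)
class OrientationEstimate:
    """Grid orientation phi in degrees on [0, 360/fold)."""

    phi: float
    fold: int
    resultant: float = 1.0  # mean resultant length in fold space (1 = single estimate)

    def __post_init__(self) -> None:
        if not 0 <= self.phi < 360.0 / self.fold:
            raise ValueError(f"phi={self.phi} outside [0, {360.0 / self.fold})")

    @property
    def low_confidence(self) -> bool:
        return self.resultant < 0.1


@dataclass
class DirectionBinBetas:
    """Per-direction-bin activity estimates, ascending from bin 0 deg."""

    betas: np.ndarray
    bin_width: float = 10.0

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, float)
        if self.betas.size != int(round(360.0 / self.bin_width)):
            raise ValueError("need exactly 360/bin_width bins")

    @property
    def bin_centers(self) -> np.ndarray:
        return np.arange(self.betas.size) * self.bin_width + self.bin_width / 2

    @property
    def bin_lefts(self) -> np.ndarray:
        return np.arange(self.betas.size) * self.bin_width


class QuadratureDesign:
    """Design matrix for one session: intercept, drift, onsets, sin/cos modulators."""

    COLUMNS = ("intercept", "drift", "onset", "sine", "cosine")

    def __init__(self, matrix: np.ndarray, fold: int, session: int | None = None):
        self.matrix = matrix
        self.fold = fold
        self.session = session

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.COLUMNS.index(name)]


def _session_nuisance(n_scans: int) -> tuple[np.ndarray, np.ndarray]:
    intercept = np.ones(n_scans)
    drift = np.linspace(-1.0, 1.0, n_scans)
    return intercept, drift


def build_quadrature_design(
    events: EventDesign,
    k: int,
    TR: float = 2.0,
    n_scans: int | None = None,
) -> QuadratureDesign:
    """Quadrature design for a single session's events.

    Columns: intercept, linear drift (high-pass surrogate), unmodulated onset
    regressor over all trials (absorbs the baseline response, lures
    included), and sin(k*theta), cos(k*theta) parametric modulators built on
    direction trials only; event columns are convolved with the double-gamma
    HRF on a shared microtime grid.
    """
    if k < 1:
        raise ValueError("fold k must be >= 1")
    tab = events.table
    if len(events.sessions) != 1:
        raise ValueError("build_quadrature_design expects a single session")
    if n_scans is None:
        n_scans = n_scans_for(events, TR)
    is_dir = (tab["trial_type"] == "direction").to_numpy()
    if not is_dir.any():
        raise ValueError("no direction trials in session")
    onsets = tab["onset"].to_numpy()  # session-relative clock by construction
    th = np.radians(tab["direction_deg"].to_numpy(float))
    onset_col = convolve_events(onsets, np.ones(len(tab)), n_scans, TR)
    sin_col = convolve_events(onsets[is_dir], np.sin(k * th[is_dir]), n_scans, TR)
    cos_col = convolve_events(onsets[is_dir], np.cos(k * th[is_dir]), n_scans, TR)
    intercept, drift = _session_nuisance(n_scans)
    X = np.column_stack([intercept, drift, onset_col, sin_col, cos_col])
    _check_rank(X, QuadratureDesign.COLUMNS)
    sess = events.sessions[0]
    return QuadratureDesign(X, fold=k, session=sess)


def _check_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns involved in the dependency via pairwise correlation
        Xc = X - X.mean(0)
        norm = np.linalg.norm(Xc, axis=0)
        norm[norm == 0] = 1.0
        corr = (Xc / norm).T @ (Xc / norm)
        bad = {
            f"{names[i]}~{names[j]}"
            for i in range(len(names))
            for j in range(i + 1, len(names))
            if abs(corr[i, j]) > 0.999
        }
        raise ValueError(f"rank-deficient design (rank {rank} < {X.shape[1]}): {sorted(bad)}")


def fit_quadrature(series, design: QuadratureDesign) -> QuadratureFit:
    """Ordinary least squares of one voxel's series on the quadrature design."""
    y = np.asarray(series, float)
    X = design.matrix
    if y.shape[0] != X.shape[0]:
        raise ValueError(f"series length {y.shape[0]} != design rows {X.shape[0]}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(X.shape[0] - X.shape[1], 1)
    i_sin = QuadratureDesign.COLUMNS.index("sine")
    i_cos = QuadratureDesign.COLUMNS.index("cosine")
    return QuadratureFit(
        beta_sine=float(beta[i_sin]),
        beta_cosine=float(beta[i_cos]),
        fold=design.fold,
        session=design.session,
        residual_var=float(resid @ resid / dof),
    )


def orientation_from_betas(fit: QuadratureFit) -> OrientationEstimate:
    """phi = atan2(beta_sine, beta_cosine)/k mapped into [0, 360/k) degrees."""
    if fit.beta_sine == 0 and fit.beta_cosine == 0:
        raise ValueError("orientation undefined for zero beta vector")
    phi = np.degrees(np.arctan2(fit.beta_sine, fit.beta_cosine)) / fit.fold
    return OrientationEstimate(phi=float(phi % (360.0 / fit.fold)), fold=fit.fold)


def mean_grid_orientation(estimates, k: int | None = None) -> OrientationEstimate:
    """Circular mean of orientations, computed in fold space (k*phi) then divided by k."""
    estimates = list(estimates)
    if not estimates:
        raise ValueError("no orientation estimates to average")
    folds = {e.fold for e in estimates}
    if len(folds) > 1:
        raise ValueError(f"mixed folds {folds}")
    k = k or folds.pop()
    z = np.mean([np.exp(1j * np.radians(k * e.phi)) for e in estimates])
    R = float(np.abs(z))
    if R < 1e-12:
        warnings.warn("degenerate circular mean (resultant ~ 0)", stacklevel=2)
        phi = 0.0
    else:
        phi = np.degrees(np.angle(z)) / k
    return OrientationEstimate(phi=float(phi % (360.0 / k)), fold=k, resultant=R)


def _per_session_series(series: np.ndarray, n_sessions: int) -> np.ndarray:
    """Normalize series to shape (n_voxels, n_sessions, n_scans)."""
    arr = np.asarray(series, float)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3 or arr.shape[1] != n_sessions:
        raise ValueError(f"series must be (voxels, {n_sessions}, scans); got {arr.shape}")
    return arr


def crossval_alignment(
    series,
    design: EventDesign,
    k: int,
    TR: float = 2.0,
) -> float:
    """Cross-validated alignment effect at fold k.

    The grid orientation is estimated on odd-numbered sessions (quadrature
    fit per voxel and session, circular-averaged in fold space), then the
    even-numbered sessions are refit with the single aligned regressor
    cos(k*(theta - Phi)); the held-out beta, averaged over voxels and even
    sessions, is returned.  Positive values mean activity is elevated on the
    estimated grid axes.
    """
    sessions = design.sessions
    if len(sessions) < 2:
        raise ValueError("cross-validation needs at least two sessions")
    arr = _per_session_series(series, len(sessions))
    odd = [s for s in sessions if s % 2 == 1]
    even = [s for s in sessions if s % 2 == 0]
    if not odd or not even:
        raise ValueError("need both odd- and even-numbered sessions")

    estimates = []
    for s in odd:
        ev = design.session(s)
        X = build_quadrature_design(ev, k, TR, n_scans=arr.shape[2])
        for v in range(arr.shape[0]):
            fit = fit_quadrature(arr[v, sessions.index(s)], X)
            estimates.append(orientation_from_betas(fit))
    Phi = mean_grid_orientation(estimates, k).phi

    betas = []
    for s in even:
        ev = design.session(s)
        tab = ev.table
        n_scans = arr.shape[2]
        is_dir = (tab["trial_type"] == "direction").to_numpy()
        onsets = tab["onset"].to_numpy()
        th = np.radians(tab["direction_deg"].to_numpy(float))
        onset_col = convolve_events(onsets, np.ones(len(tab)), n_scans, TR)
        aligned = convolve_events(
            onsets[is_dir], np.cos(k * (th[is_dir] - np.radians(Phi))), n_scans, TR
        )
        intercept, drift = _session_nuisance(n_scans)
        X = np.column_stack([intercept, drift, onset_col, aligned])
        for v in range(arr.shape[0]):
            beta, _, _, _ = np.linalg.lstsq(X, arr[v, sessions.index(s)], rcond=None)
            betas.append(beta[-1])
    return float(np.mean(betas))


def fit_direction_bins(
    series,
    design: EventDesign,
    bin_width: float = 10.0,
    TR: float = 2.0,
) -> DirectionBinBetas:
    """Direction-bin GLM over all sessions: one binary regressor per 10-deg bin.

    Directions are down-sampled into half-open bins [b, b+width); every
    session contributes to the shared bin regressors while intercept, drift
    and a lure regressor are fit per session.  Returns per-bin betas sorted
    ascending by bin (0 deg first).
    """
    n_bins = int(round(360.0 / bin_width))
    if n_bins * bin_width != 360.0:
        raise ValueError("bin_width must divide 360")
    sessions = design.sessions
    arr = _per_session_series(series, len(sessions))
    if arr.shape[0] != 1:
        raise ValueError("fit_direction_bins expects a single voxel/ROI series")
    n_scans = arr.shape[2]

    all_dirs = design.directions
    bins_present = np.unique((all_dirs % 360.0 // bin_width).astype(int))
    if bins_present.size == 0:
        raise ValueError("no direction trials")
    if bins_present.size < n_bins:
        warnings.warn(
            f"{n_bins - bins_present.size} direction bins are empty", stacklevel=2
        )

    n_sess = len(sessions)
    total = n_sess * n_scans
    X = np.zeros((total, n_bins + 3 * n_sess))
    y = np.zeros(total)
    for si, s in enumerate(sessions):
        tab = design.session(s).table
        onsets = tab["onset"].to_numpy()
        is_dir = (tab["trial_type"] == "direction").to_numpy()
        th = tab["direction_deg"].to_numpy(float)
        rows = slice(si * n_scans, (si + 1) * n_scans)
        for b in range(n_bins):
            in_bin = is_dir & (th % 360.0 >= b * bin_width) & (th % 360.0 < (b + 1) * bin_width)
            if in_bin.any():
                X[rows, b] = convolve_events(
                    onsets[in_bin], np.ones(in_bin.sum()), n_scans, TR
                )
        intercept, drift = _session_nuisance(n_scans)
        X[rows, n_bins + 3 * si] = intercept
        X[rows, n_bins + 3 * si + 1] = drift
        if (~is_dir).any():
            X[rows, n_bins + 3 * si + 2] = convolve_events(
                onsets[~is_dir], np.ones((~is_dir).sum()), n_scans, TR
            )
        y[rows] = arr[0, si]

    keep = [b for b in range(n_bins) if X[:, b].any()] + list(range(n_bins, X.shape[1]))
    keep = [c for c in keep if X[:, c].any()]
    beta, _, _, _ = np.linalg.lstsq(X[:, keep], y, rcond=None)
    out = np.full(n_bins, np.nan)
    for i, c in enumerate(keep):
        if c < n_bins:
            out[c] = beta[i]
    return DirectionBinBetas(out, bin_width=bin_width)


def reconstruct_tuning(fit: QuadratureFit, theta_grid_deg) -> np.ndarray:
    """Reconstructed directional tuning beta_cos*cos(k*theta) + beta_sin*sin(k*theta)."""
    th = np.radians(np.asarray(theta_grid_deg, float))
    return fit.beta_cosine * np.cos(fit.fold * th) + fit.beta_sine * np.sin(fit.fold * th)
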