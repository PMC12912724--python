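"""Cross-frequency coupling in the direction domain.

Reconstructed k-fold activity profiles are treated as periodic signals over
direction (0..360 deg).  The Hilbert transform gives the instantaneous
phase of the low-fold (hippocampal, threefold) signal and the amplitude
envelope of the high-fold (entorhinal, sixfold) signal; the modulation
index M_b = |mean(A * exp(i*phase))| within each of nine 40-deg phase bins
measures amplitude-phase coupling, referenced against circular-lag
surrogates.  A zero-phase least-squares FIR band-pass and PLV/PLI
phase-locking statistics round out the toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import filtfilt, firls, hilbert

__all__ = [
    "AnalyticSignal",
    "CouplingResult",
    "PhaseLockResult",
    "analytic_signal",
    "phase_bin_index",
    "modulation_by_phase",
    "shift_surrogates",
    "coupling_analysis",
    "fir_bandpass",
    "phase_locking",
    "PHASE_BIN_COUNT",
]

PHASE_BIN_COUNT = 9
_BIN_WIDTH = 360.0 / PHASE_BIN_COUNT  # 40 deg, one bin centered at phase 0


@dataclass
class AnalyticSignal:
    """Instantaneous phase (radians, (-pi, pi]) and amplitude envelope per sample."""

    phase: np.ndarray
    amplitude: np.ndarray
    grid_deg: np.ndarray


@dataclass
class CouplingResult:
    """Phase-binned modulation indices and lag-surrogate baselines."""

    M: np.ndarray
    M_surrogate: np.ndarray | None
    bin_centers: np.ndarray

    @property
    def strength(self) -> np.ndarray:
        if self.M_surrogate is None:
            raise ValueError("no surrogate baseline computed")
        return self.M - self.M_surrogate

    def argmax_bin_center(self, use_strength: bool = False) -> float:
        vals = self.strength if use_strength else self.M
        return float(self.bin_centers[int(np.nanargmax(vals))])


@dataclass
class PhaseLockResult:
    plv: float
    pli: float
    plv_surrogates: np.ndarray
    pli_surrogates: np.ndarray


def _uniform_grid(n: int) -> np.ndarray:
    return np.arange(n) * 360.0 / n


def analytic_signal(values, grid_deg=None) -> AnalyticSignal:
    """Discrete analytic signal of a periodic direction-domain profile.

    The signal is treated as one full period of a circular domain, so the
    FFT-based Hilbert transform needs no edge padding.  The grid must be
    uniform (use circular_resample first otherwise).
    """
    x = np.asarray(values, float)
    if x.size < 16:
        raise ValueError("need at least 16 samples on the direction grid")
    if grid_deg is None:
        grid_deg = _uniform_grid(x.size)
    else:
        grid_deg = np.asarray(grid_deg, float)
        step = np.diff(grid_deg)
        if not np.allclose(step, step[0], atol=1e-9):
            raise ValueError("direction grid is not uniform; resample first")
    z = hilbert(x)
    return AnalyticSignal(phase=np.angle(z), amplitude=np.abs(z), grid_deg=grid_deg)


def phase_bin_index(phase_rad) -> np.ndarray:
    """Assign phases to the 9 bins of 40 deg anchored so one bin is centered at 0."""
    deg = np.degrees(np.asarray(phase_rad, float))
    return (np.floor((deg + _BIN_WIDTH / 2) / _BIN_WIDTH).astype(int)) % PHASE_BIN_COUNT


def _bin_centers() -> np.ndarray:
    # centers 0, 40, ..., 320 reported on [-180, 180) for readability
    c = np.arange(PHASE_BIN_COUNT) * _BIN_WIDTH
    return np.where(c >= 180.0, c - 360.0, c)


def modulation_by_phase(amplitude, phase, n_bins: int = PHASE_BIN_COUNT) -> CouplingResult:
    """Modulation index per phase bin: M_b = |mean over bin of A * exp(i*phase)|."""
    A = np.asarray(amplitude, float)
    ph = np.asarray(phase, float)
    if A.size != ph.size:
        raise ValueError("amplitude and phase must have equal length")
    if n_bins != PHASE_BIN_COUNT:
        raise ValueError("phase binning is fixed at 9 bins of 40 deg")
    idx = phase_bin_index(ph)
    z = A * np.exp(1j * ph)
    M = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            M[b] = np.abs(np.mean(z[sel]))
    order = np.argsort(_bin_centers())
    return CouplingResult(
        M=M[order], M_surrogate=None, bin_centers=_bin_centers()[order]
    )


def shift_surrogates(amplitude, phase, n_bins: int = PHASE_BIN_COUNT) -> np.ndarray:
    """Per-bin mean modulation index across all circular lags of A relative to phase.

    Spatially offsetting the amplitude by every possible lag destroys any
    consistent amplitude-phase alignment while preserving both marginals;
    the mean across lags is the surrogate baseline M'.
    """
    A = np.asarray(amplitude, float)
    ph = np.asarray(phase, float)
    Ms = np.full((A.size, n_bins), np.nan)
    for lag in range(A.size):
        Ms[lag] = modulation_by_phase(np.roll(A, lag), ph, n_bins).M
    return np.nanmean(Ms, axis=0)


def coupling_analysis(amplitude_signal, phase_signal) -> CouplingResult:
    """Full amplitude-phase coupling: envelope of one profile vs phase of the other."""
    amp = analytic_signal(amplitude_signal).amplitude
    ph = analytic_signal(phase_signal).phase
    res = modulation_by_phase(amp, ph)
    res.M_surrogate = shift_surrogates(amp, ph)
    return res


def fir_bandpass(
    values,
    center_fold: int,
    halfwidth_folds: float = 1.0,
    order: int | None = None,
) -> np.ndarray:
    """Zero-phase least-squares FIR band-pass around a fold, circular boundaries.

    The filter is designed with least squares (firls) for the band
    ``center_fold +/- halfwidth_folds`` in cycles per 360 deg and applied
    forward and backward (filtfilt) on a 3x periodic tiling of the signal to
    respect the circular domain; the central period is returned.
    """
    x = np.asarray(values, float)
    n = x.size
    if order is None:
        order = 2 * (n // 3)
    if order >= n:  # tiled signal gives filtfilt 3n samples of room
        raise ValueError(f"filter order {order} too long for {n} samples")
    if order % 2 == 1:
        order += 1  # firls needs an odd tap count (even order)
    nyq = n / 2.0  # folds per circle
    lo, hi = center_fold - halfwidth_folds, center_fold + halfwidth_folds
    trans = max(0.5, halfwidth_folds / 2)
    if lo - trans <= 0 or hi + trans >= nyq:
        raise ValueError("pass band (with transition) must sit inside (0, Nyquist)")
    bands = np.array([0, lo - trans, lo, hi, hi + trans, nyq]) / nyq
    desired = [0, 0, 1, 1, 0, 0]
    taps = firls(order + 1, bands, desired)
    # normalize to unit gain at the center fold so the two-pass (zero-phase)
    # application preserves pass-band amplitude
    w = 2 * np.pi * center_fold / n
    gain = np.abs(np.sum(taps * np.exp(-1j * w * np.arange(taps.size))))
    taps = taps / gain
    tiled = np.tile(x, 3)
    filtered = filtfilt(taps, [1.0], tiled, padtype=None)
    return filtered[n : 2 * n]


def phase_locking(sig_a, sig_b, n_bins_unused: int | None = None) -> PhaseLockResult:
    """PLV and PLI between two direction-domain profiles on the same grid.

    Phase differences come from the analytic signals;
    PLV = |mean(exp(i*dphi))| and PLI = |mean(sign(sin(dphi)))|.  Surrogates
    circularly shift one signal across all lags.
    """
    a = np.asarray(sig_a, float)
    b = np.asarray(sig_b, float)
    if a.size != b.size:
        raise ValueError("signals must share the direction grid")
    pa = analytic_signal(a).phase

    def _stats(bb):
        dphi = pa - analytic_signal(bb).phase
        plv = float(np.abs(np.mean(np.exp(1j * dphi))))
        pli = float(np.abs(np.mean(np.sign(np.sin(dphi)))))
        return plv, pli

    plv, pli = _stats(b)
    plvs = np.empty(a.size - 1)
    plis = np.empty(a.size - 1)
    for lag in range(1, a.size):
        plvs[lag - 1], plis[lag - 1] = _stats(np.roll(b, lag))
    return PhaseLockResult(plv=plv, pli=pli, plv_surrogates=plvs, pli_surrogates=plis)
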