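"""Circular statistics: Rayleigh test, pairwise phase consistency, circular
means and circular-circular correlation, plus fold-space phase mapping.

Angles are radians unless a function name says otherwise.  Orientation
estimates that live on a fold-specific range (entorhinal phi in [0, 60),
hippocampal phi in [0, 120) degrees) are mapped to a common full circle by
multiplying by their fold before any cross-region statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pingouin as pg

__all__ = [
    "CircStatResult",
    "rayleigh_test",
    "ppc",
    "circ_circ_corr",
    "fold_phase_to_circle",
    "bonferroni",
]


@dataclass(frozen=True)
class CircStatResult:
    statistic: float
    p_value: float
    n: int
    name: str


def rayleigh_test(angles) -> CircStatResult:
    """Rayleigh test of circular uniformity.

    Returns the mean resultant length R-bar as the statistic; z = n*R-bar^2
    and the standard small-sample series approximation for p (as implemented
    in pingouin) are used for inference.
    """
    a = np.asarray(angles, float)
    if a.size < 4:
        raise ValueError("Rayleigh test needs n >= 4")
    rbar = float(np.abs(np.mean(np.exp(1j * a))))
    _, p = pg.circ_rayleigh(a)
    return CircStatResult(statistic=rbar, p_value=float(p), n=a.size, name="rayleigh_rbar")


def rayleigh_z(angles) -> float:
    a = np.asarray(angles, float)
    rbar = np.abs(np.mean(np.exp(1j * a)))
    return float(a.size * rbar**2)


def ppc(angles, n_perm: int = 0, seed: int | None = None) -> CircStatResult:
    """Pairwise phase consistency: mean of cos(theta_i - theta_j) over unordered pairs.

    Identical angles give 1; n evenly spaced angles give -1/(n-1).  If
    n_perm > 0, a permutation p-value is computed against surrogates of
    uniformly distributed random phases on (0, 2*pi).
    """
    a = np.asarray(angles, float)
    n = a.size
    if n < 2:
        raise ValueError("PPC needs n >= 2")
    diffs = a[:, None] - a[None, :]
    iu = np.triu_indices(n, k=1)
    stat = float(np.mean(np.cos(diffs[iu])))
    p = np.nan
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for i in range(n_perm):
            b = rng.uniform(0, 2 * np.pi, n)
            z = np.abs(np.sum(np.exp(1j * b))) ** 2
            null[i] = (z - n) / (n * (n - 1))  # resultant identity, O(n)
        p = float((np.sum(null >= stat) + 1) / (n_perm + 1))
    return CircStatResult(statistic=stat, p_value=p, n=n, name="ppc")


def circ_circ_corr(alpha, beta) -> CircStatResult:
    """Jammalamadaka-SenGupta circular-circular correlation with asymptotic p."""
    a = np.asarray(alpha, float)
    b = np.asarray(beta, float)
    if a.size != b.size:
        raise ValueError("alpha and beta must have equal length")
    if a.size < 5:
        raise ValueError("circular correlation needs n >= 5")
    for name, x in (("alpha", a), ("beta", b)):
        if np.abs(np.mean(np.exp(1j * x))) > 1 - 1e-12:
            raise ValueError(f"{name} has zero circular variance; correlation undefined")
    r, p = pg.circ_corrcc(a, b)
    return CircStatResult(statistic=float(r), p_value=float(p), n=a.size, name="circ_corr")


def fold_phase_to_circle(phase_deg: float, fold: int) -> float:
    """Map a fold-range orientation (degrees in [0, 360/fold)) to radians on the circle."""
    if not 0 <= phase_deg < 360.0 / fold:
        raise ValueError(f"phase {phase_deg} outside [0, {360.0 / fold}) for fold {fold}")
    return float(np.radians(fold * phase_deg))


def bonferroni(p: float, n_tests: int) -> float:
    """Multiplicative multiple-comparison correction, capped at 1."""
    return float(min(1.0, p * n_tests))
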