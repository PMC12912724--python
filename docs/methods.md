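# Methods

This note documents the models, estimators, defaults and numerical choices
in `phasesync`, and what its synthetic-data validation does and does not
establish about real data.

## Task space and behavioral scoring

The conceptual space is a 45×45 integer lattice of object variants defined
by two feature ratios (0.12–1.88 in steps of 0.04), prototype (goal) at the
central cell (22, 22). Coordinates: x East, y North; angles counterclockwise
from East, degrees. Two direction conventions coexist and are explicit at
every call site: `start_rel_end` (angle of start − end, "movement from the
East" = 0°) is used by the empirical-analysis stages, `toward_goal` (angle
of end − start) by the navigation model. They differ by exactly 180°, which
is invisible to even folds and flips the sign of cos(3θ); the magnitude
spectra used throughout are unaffected.

Per-trial behavioral score: `T − T′ + E/0.04`, with `T` the executed path
length in unit steps, `T′` the Manhattan-optimal length, and `E` the
feature-ratio distance from the ending location to the goal (0.04 is one
step of feature ratio). Lower is better. Triplet direction counts partition
a path's steps into non-overlapping windows of three from the start
(trailing remainder dropped) and count distinct net-displacement directions;
a pure axis-by-axis path scores 2 when each leg is a multiple of three
steps, which is the configuration used for the strategy diagnostic.

Peripheral start sampling draws, per 30° bin, 24 directions without
replacement from the 24 slots of the 1.25° precision grid (288 total), and
places each start on a ring of radius 21 ± 1 cells around the prototype.
Directions binned at 30° are exactly uniform by construction.

## Synthetic BOLD generator

Eight sessions of 36 direction trials and 4 lures; trial i of a session
starts at 2 + 12·i s (2 s fixation + 10 s trial window) on a TR = 2 s grid;
lures are blank trials without a direction. Each direction trial contributes
a neural impulse of amplitude `baseline + a·cos(k*(θ − φ*))`; lures
contribute baseline only. Impulses on a 0.1 s microtime grid are convolved
with a canonical double-gamma hemodynamic response (response gamma shape 6,
undershoot shape 16, unit dispersions, undershoot ratio 1/6, unit peak —
the field-standard parameterization, chosen here as a default) and sampled
at TR; i.i.d. Gaussian noise is added per scan. The forward model and the
GLM design builders share one convolution routine, so noiseless simulations
are reproduced exactly by the matching design (the round-trip recovers φ*
to < 1e-6° for every fold 3–7). Regions draw voxel orientations von Mises
around k·φ* in fold space (kappa = 0 exactly uniform). Noise is white by
design; real BOLD autocorrelation, drift spectra, motion and spatial
smoothness are not emulated, so estimator validation here speaks to
correctness of the math, not to robustness against fMRI artifacts.

## Quadrature GLM and cross-validation

Per-session design columns: intercept, linear drift (a minimal stand-in for
the high-pass filtering of real pipelines), an unmodulated onset regressor
over all trials (absorbs the baseline response), and sin(kθ)/cos(kθ)
parametric modulators on direction trials only, all HRF-convolved.
Orientation: φ = atan2(β_sin, β_cos)/k on [0°, 360°/k); the two-argument
arctangent resolves the quadrant ambiguity of a printed one-argument
arctan. ROI aggregation is a circular mean in fold space (k·φ averaged,
divided by k), with the mean resultant length reported and flagged when
below 0.1. Cross-validation estimates Φ from odd-numbered sessions (voxels
and sessions pooled by the fold-space circular mean), then refits
even-numbered sessions with the single aligned regressor cos(k(θ − Φ));
the held-out β equals the planted amplitude exactly in the noiseless case
and is ~0 for control folds. The 36-bin direction GLM shares bin regressors
across sessions (8 trials per 10° bin by design) with per-session
intercept, drift and lure regressors; bins are half-open [b, b+10°).

## Fold spectrum and permutation inference

Per-direction vectors sorted ascending by direction are linearly detrended,
multiplied by a *periodic* Hann window, and Fourier transformed; magnitude
at coefficient f is the power at f cycles per 360°. The periodic (DFT-even)
window keeps integer folds exact: a pure fold-f tone leaks only into f±1,
each sidelobe carrying exactly half the main magnitude — a fact that
matters for interpreting strong periodic signals (below). Detrend before
window; the reverse order was considered and makes no practical difference.
Because detrending and windowing act in a fixed direction frame, magnitude
spectra are exactly rotation-invariant only for the bare transform; the
tapered pipeline preserves the detected (argmax) fold under rotation, and
that is the property asserted.

Significance: direction labels are shuffled (5000 iterations by default),
the spectrum recomputed per shuffle; per-fold 95th percentiles give
uncorrected thresholds and the 95th percentile of the per-shuffle maximum
over non-DC folds gives the family-wise threshold. The DC coefficient is
excluded from maxima and from argmax reporting, as it is not a
periodicity. Family-wise type-I error on white noise is calibrated (2.5% –
7.5% band asserted over 500 replicates).

## Direction-domain coupling

Reconstructed k-fold activity profiles (β_cos·cos(kθ) + β_sin·sin(kθ)) are
periodic signals over direction, so the FFT-based Hilbert transform needs
no padding. The modulation index in each of 9 phase bins of 40° (one bin
centered at phase 0, fixed by the anchoring of the reported effect) is
M_b = |mean(A·e^{iφ})| over samples in the bin; surrogates circularly lag
the amplitude against the phase across all offsets and average. A pure
sixfold tone has a constant envelope and therefore cannot couple to
anything — the aligned-coupling fixture is an amplitude-modulated carrier
(1 + cos 3θ)·cos 6θ whose analytic envelope is exactly 1 + cos 3θ, peaked
where the threefold phase is zero; ninefold/twelvefold controls stay pure
tones and show zero coupling strength. The FIR band-pass is least-squares
(firls), applied forward and backward on a 3× periodic tiling (zero phase,
circular boundaries), tap count 2·⌊n/3⌋ + 1 and unit-normalized at the
center fold so the two-pass gain is 1. PLV = |mean e^{iΔφ}| and
PLI = |mean sign(sin Δφ)| are both computed; PLV with circular-shift
surrogates is the headline synchrony statistic, PLI is reported alongside
because zero-lag coupling (PLI = 0 by construction) and constant-lag
coupling (PLV = PLI = 1) need both to be distinguished.

## Circular statistics

R̄ and z = nR̄² are computed directly; the Rayleigh p-value and the
Jammalamadaka–SenGupta circular–circular correlation are delegated to
pingouin. PPC is the mean cosine of all unordered pairwise differences,
computed explicitly and tested against its resultant identity
(nR̄² − 1)/(n − 1); its permutation p uses uniform random phases.
Orientations on fold-specific ranges are mapped to the common circle by
multiplying by their fold before any cross-region statistic.

## The PhaseSync model

Grid parameters: amplitude 1, plane-wave wavelength 9 cells (≈5 pattern
repeats across the space; unspecified upstream, chosen once as a scale
small enough for several fields yet well resolved on the lattice), single
module, grid-axis orientation 15° (axes at 15°/75°/135°, placing one axis
at 135° as in the aligned illustration). Wave vectors are perpendicular to
the axes: a path is "aligned" when it runs along a grating's wavefronts, so
axes — where δ peaks — sit 90° from the wave vectors; this convention is
verified numerically.

δ(ψ): for each orientation, a straight path from the ring location at
radius 21 to the center; the path code is pooled to a scalar. Default
pooling is the population energy (mean V²); max-over-cells pooling is
available. Energy pooling yields exactly three prominence-filtered maxima
(10% prominence) located on the grid axes to within the sampling step; max
pooling shares the threefold dominant Fourier component but shows small
secondary bumps midway between axes, which is why it is not the default.
For δ the path is sampled at unit-spaced continuous locations; lattice
rasterization (kept for the path-code operations) adds rounding jitter that
displaces peaks by a few degrees.

Goal field: C(R) = cos(3Φ_R + δ_ε) + exp(−‖R−q‖²/(2σ²)), Φ_R the
toward-goal direction, σ = 22 (the space radius), δ_ε = −3·orientation so
the cosine peaks on one chosen direction of each axis (which of the two
opposite directions is preferred is a convention). At R = q the directional
term is undefined and set to its mean (0), the Gaussian to 1.

Navigation: winner-take-all over Chebyshev rings of growing radius (step
sizes 1–5 cells), ties broken by a fixed clockwise-from-East scan order;
termination within one cell of the goal, on failure to improve, or at the
iteration cap (flagged). `navigate` defaults to the integer lattice and is
fully deterministic. The simulation protocol instead moves on a 0.25-cell
grid with the field evaluated in closed form: on the integer lattice the
unit-step ring offers only eight directions, and that eightfold movement
anisotropy intermodulates with the threefold detour signal, injecting
structured power at folds 1/2/4 that no shuffle threshold can separate.

Simulation protocol (100 goals × 120 starts, 5000 shuffles): goals uniform
in the interior (margin ≈ σ/4 = 6 cells); starts for each goal span all
directions (3° slots with within-slot jitter) at radii drawn from an
annulus reaching from 0.15× to 1× of the goal-to-boundary distance,
mirroring the task's ring-shaped peripheral sampling region while
controlling distance within each goal's analysis. Starts ringed at the
space boundary with goals elsewhere were rejected: start-to-goal distance
then varies as cos(direction) and fold 1 dominates the spectrum. Per goal,
path lengths are resampled onto 36 uniform directions (periodic linear
interpolation) and the mean magnitude spectrum across goals is tested
against per-goal label shuffles with the max-statistic correction.

One spectral consequence is worth making explicit: a noiseless,
strong-threefold profile cannot come out "significant at fold 3 only",
because the periodic-Hann sidelobes at folds 2 and 4 carry half the fold-3
magnitude while the shuffle threshold of a signal-dominated vector sits
near 0.45× of it. The distance spread of the annulus supplies the
across-start variability that places the simulation in the weak-signal
regime (fold 3 ≈ 1.5× threshold) where only fold 3 clears the corrected
threshold — the regime noisy empirical data occupy naturally. With the
directional term switched off, no fold is significant.

## Problem sizes and determinism

Defaults throughout are the study-scale numbers (8 sessions × 36 + 4
trials, 288 directions, 36 bins, 5000 permutations, 100 × 120 navigation
runs); the full simulation runs in well under a minute. Monte-Carlo checks
in the test suite use reduced replicate counts (e.g., 20–25 voxels or
seeds, 200–1000 permutations) chosen as the package's own trade-off between
statistical resolution and suite runtime. Every stochastic routine takes a
single seed; CLI runs record their seeds in a JSON manifest sufficient for
bit-identical replay.

## Known limitations

- The synthetic BOLD generator omits autocorrelated noise, motion, spatial
  structure and susceptibility artifacts; passing recovery tests validates
  the estimators, not their behavior on real scanner data.
- The model is single-module and on-lattice; multiple grid scales, learning
  and off-lattice dynamics are out of scope.
- The δ pooling rule is one of several defensible readings of a pooling
  step that is underdetermined upstream; both provided poolings are
  threefold, but absolute δ values are convention-dependent.
- Group-level inference across participants (t-maps, cluster correction on
  volumes) is not reproduced; all inference here is within-simulation
  permutation testing.
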