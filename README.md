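# phasesync

Directional-periodicity analysis and a grid-code navigation model for the
entorhinal–hippocampal circuit, exercised entirely on synthetic data.

## The scientific problem

Entorhinal grid cells fire on a hexagonal lattice, which in fMRI shows up as
a *sixfold* (60°-periodic) modulation of entorhinal activity by movement
direction. When people navigate a two-dimensional conceptual object space —
morphing an object's two features to match a central prototype, which traces
a path from a peripheral start toward a central goal — the hippocampus
instead carries a *threefold* (120°-periodic) directional code, phase-locked
to the entorhinal sixfold code, and behavioral performance fluctuates with
the same threefold rhythm. This package provides, for that phenomenon:

- **The EC-HPC PhaseSync model.** Grid cells are sums of three cosine
  gratings 60° apart, one cell per phase offset on the 45×45 task lattice:
  `G_r = Σᵢ A·cos(ωᵢ kᵢ·(r − c))`. Summing population patterns along a
  straight path gives a path code `V` that is identical for directions φ and
  φ+180°, so paths live on orientations ψ ∈ [0°, 180°). Pooling `V` yields an
  alignment profile δ(ψ) with three peaks per half-turn, on the grid axes. A
  hippocampal goal field
  `C(R) = cos(δ_c·Φ_R + δ_ε) + exp(−‖R−q‖²/(2σ²))`
  combines that threefold directional structure with Gaussian goal
  proximity; winner-take-all navigation on `C` (adaptive step size, 1–5
  cells) yields path lengths whose spectrum over start→goal direction peaks
  at fold 3.
- **The analysis stack.** Quadrature GLMs with sin(kθ)/cos(kθ) parametric
  modulators and grid-orientation estimation φ = atan2(β_sin, β_cos)/k;
  cross-validated alignment (orientation from odd sessions, cos(k(θ−Φ))
  tested on even sessions); 36-bin direction GLMs; fold-spectrum FFT
  (detrend, periodic Hann window, magnitudes at 0–18 cycles per 360°) with
  5000-iteration label-shuffle permutation and max-statistic family-wise
  correction; direction-domain amplitude–phase coupling (Hilbert envelope ×
  phase, 9 bins of 40°, modulation index M with circular-lag surrogates);
  zero-phase least-squares FIR band-pass; PLV/PLI phase locking; circular
  statistics (Rayleigh, pairwise phase consistency, circular–circular
  correlation).
- **Synthetic data generators.** The 8-session × (36 direction + 4 lure)
  event-related design with 288 directions at 1.25° precision, double-gamma
  HRF BOLD forward model with planted fold/orientation/amplitude ground
  truth, multi-voxel regions with von Mises-spread voxel orientations, and
  per-direction behavioral performance vectors.

No external data are required or used.

## Worked example

```python
import numpy as np
from phasesync import model, space, bold
from phasesync.spectrum import circular_resample, detect_periodicity

# behavioral periodicity: plant a threefold performance modulation and detect it
starts = space.sample_ring_starts(seed=0)           # 288 peripheral starts
dirs = np.array([d for _, d in starts])
scores = bold.simulate_behavior(dirs, fold=3, amplitude=1.0, noise_sd=0.5, seed=1)
vec = circular_resample(dirs, scores, 36)
spec, null, sig = detect_periodicity(vec, n_perm=5000, seed=2)
print(f"behavior: argmax fold = {spec.argmax_fold()}, "
      f"fold-3 magnitude = {spec.magnitudes[3]:.2f}, "
      f"FWE threshold = {null.fwe:.2f}, significant = {sorted(sig)}")

# model: 100 random goals x 120 starts, winner-take-all navigation
res = model.run_simulation(n_goals=100, n_starts=120, n_perm=5000, seed=0)
m = res.mean_spectrum.magnitudes
print(f"model: argmax fold = {res.argmax_fold}, magnitudes[1..6] = "
      f"{np.round(m[1:7], 2).tolist()}, FWE = {res.null.fwe:.2f}, "
      f"significant = {sorted(res.significant_folds)}")
```

prints

```
behavior: argmax fold = 3, fold-3 magnitude = 10.88, FWE threshold = 8.23, significant = [3]
model: argmax fold = 3, magnitudes[1..6] = [10.45, 12.66, 19.39, 12.21, 10.6, 9.89], FWE = 13.80, significant = [3]
```

The behavioral spectrum recovers the planted threefold modulation as the
only fold clearing the family-wise permutation threshold. The navigation
model, given nothing but the threefold goal field inherited from the grid
code, produces path lengths whose mean spectrum across 100 random goals
likewise peaks at fold 3 — and at fold 3 only.

A command-line interface mirrors the library:

```bash
phasesync synth --seed 0 --fold 6 --phi 23 --out synth_out
phasesync fit-periodicity --events synth_out/events.tsv --series synth_out/series.tsv
phasesync simulate-model --seed 0 --out model_out
```

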