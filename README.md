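# pfmodes

Probabilistic functional modes (PFMs) from multi-subject resting-state fMRI,
by hierarchical Bayesian matrix factorisation with variational inference —
plus a ground-truth simulator and a decomposition-scoring suite.

## Who this is for

Resting-state fMRI is commonly summarised as a small set of *modes*: spatial
maps that share a common time course, possibly overlapping each other and
containing anti-correlated regions. ICA-family methods force modes to be
spatially or temporally independent, which rules out exactly the correlated,
overlapping structure one expects between large-scale brain systems. This
package is for researchers who want mode decompositions that (a) permit
spatial and temporal correlations between modes, (b) model how each
subject's maps deviate from the group, and (c) exploit the haemodynamics of
the BOLD signal — with full posterior uncertainty rather than point
estimates.

## The model

Each run of each subject is factorised as

```
D^(sr) = P^(s) A^(sr) + ε^(sr)
```

with `D^(sr) ∈ R^{V×T}` the data, `P^(s) ∈ R^{V×M}` the subject's mode maps
(shared across their runs), `A^(sr) ∈ R^{M×T}` the run's time courses, and
ε white Gaussian noise with per-voxel means ν and per-run precision ψ.

* **Spatial hierarchy.** Every map weight `P_vm^(s)` follows a delta-Gaussian
  mixture: exactly zero with probability `1 − π_vm`, else drawn from
  `N(μ_vm, σ_vm²)`. The mixture answers three questions per voxel: is the
  voxel in the mode, how strong is the effect, and how much does it vary
  across subjects. π carries a beta hyperprior, σ² an inverse-gamma, and the
  group means μ a spike-slab hyperprior `ρ_vm λ` / `N(0, γ_m^{-1})` that
  sparsifies whole voxel-mode effects at the group level.
* **Temporal prior.** If the neural process is white, convolution with the
  haemodynamic response function h induces the autocorrelation
  `E[y(t₁)y(t₂)] = Σ_τ h(τ)h(τ − (t₁−t₂))`. Sampling this at multiples of
  the TR gives a Toeplitz covariance `K_A`, so each time course has the
  prior `A_m^(sr) ~ N(0, α^{-1} K_A)` with a gamma-distributed global
  precision α.
* **Inference.** The posterior is approximated as a product over factors
  (mean field), with a structured Bernoulli-gated-Gaussian factor for each
  `(P, q)` and `(μ, ρ)` pair. All distributions are conjugate-exponential,
  so every coordinate update is closed-form and the evidence lower bound
  (ELBO) is monotone non-decreasing across sweeps.

Modes that the data do not support are shrunk to zero automatically — no
explicit pruning step.

## Worked example

Simulate a small multi-subject dataset with known modes, fit PFMs, and score
the recovery (Hungarian matching, uncentered correlations):

```python
import numpy as np
from pfmodes import (SimConfig, simulate_dataset, fit, FitConfig,
                     match_modes, score_decomposition)

cfg = SimConfig(V=1000, N=40, M=6, S=4, runs_per_subject=2, T=120, seed=0)
data, truth = simulate_dataset(cfg)          # -10 dB SNR by default

state = fit(data, M=6, config=FitConfig(max_iter=50, log_every=0), seed=1)
print(f"final ELBO: {state.elbo_trace[-1]:.1f} after {len(state.elbo_trace)} sweeps")

est_tc = {k: tc.mean for k, tc in state.timecourses.items()}
order = sorted(truth.bold_tc)
match = match_modes(
    state.group_maps(),
    np.mean(list(truth.subject_maps.values()), axis=0),
    np.concatenate([est_tc[k] for k in order], axis=1),
    np.concatenate([truth.bold_tc[k] for k in order], axis=1),
)
report = score_decomposition(
    state.subject_maps(), est_tc, truth.subject_maps, truth.bold_tc, match
)
print("per-mode spatial accuracy:",
      {m: round(r, 2) for m, r in sorted(report.spatial_accuracy.items())})
print(f"mean spatial accuracy: {report.mean_spatial():.3f}")
print(f"mean temporal accuracy: {report.mean_temporal():.3f}")
```

Output:

```
final ELBO: -1416340.6 after 50 sweeps
per-mode spatial accuracy: {0: 0.2, 1: 0.37, 2: 0.26, 3: 0.4, 4: 0.12, 5: 0.5}
mean spatial accuracy: 0.309
mean temporal accuracy: 0.370
```

The per-mode numbers are means over subjects of the uncentered correlation
between the estimated and true subject-specific maps (and time courses),
after matching estimated to true modes and resolving joint map/time-course
sign flips. At −10 dB SNR (noise power ten times signal power) and this
small problem size, recovery is partial; accuracies rise with more voxels,
runs and sweeps.

The same workflow is available from the shell:

```bash
pfm simulate --config sim.json --out simdir/
pfm fit --data simdir/dataset.h5 --modes 6 --seed 1 --out fit.h5
pfm evaluate --est fit.h5 --truth simdir/ground_truth.h5 --report report.json
pfm match --est fitA.h5 --ref fitB.h5
pfm hrf --tr 0.72 --out hrf.csv
```

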