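# Methods

This note documents the generative model, the variational scheme, the
simulator, the scoring conventions, and the numerical and design choices
made where more than one defensible option existed.

## Generative model

For subjects `s ∈ S`, runs `r ∈ R_s`, voxels `v`, modes `m`, time points `t`:

```
D^(sr) = P^(s) A^(sr) + ε^(sr)                      data, V×T per run

P_vm^(s) | q_vm^(s)=1 ~ N(μ_vm, σ_vm²)              slab (effect present)
P_vm^(s) | q_vm^(s)=0 = 0                           delta (effect absent)
q_vm^(s) ~ Bernoulli(π_vm)
π_vm ~ Beta(a₀, b₀);   σ_vm² ~ InvGamma(c₀, d₀)
μ_vm | ρ_vm=1 ~ N(0, γ_m⁻¹);  μ_vm | ρ_vm=0 = 0;  ρ_vm ~ Bernoulli(λ)

A_m^(sr) ~ N(0, α⁻¹ K_A);  α ~ Gamma(e₀, f₀)
ε_t^(sr) ~ N(ν^(sr), ψ^(sr)⁻¹ I);  ψ^(sr) ~ Gamma(g₀, h₀);  ν_v ~ N(0, v₀)
```

`K_A` is the Toeplitz matrix of the canonical double-gamma HRF's
autocovariance sampled at the TR: if the neural process is white, the
observed autocorrelation is exactly the autocorrelation of the HRF. The
prior is deliberately weak on purpose — it biases the decomposition toward
haemodynamically plausible time courses without forbidding structure the
data support. It is also rotation-invariant across modes, so unmixing is
driven entirely by the non-Gaussian spatial prior.

One interpretation choice: the precision α is given a *gamma* prior
(equivalently, an inverse-gamma on the variance), which is the conjugate
form for a precision scalar.

### Default hyperparameters

All are exposed through `Hyperparameters`; defaults are broad:

| parameter | default | role |
|---|---|---|
| a₀, b₀ | 1, 1 | uniform prior on π |
| c₀, d₀ | 1e-3, 1e-3 | vague inverse-gamma on σ² |
| γ_m | 1 | group-mean slab precision (fixed, per mode) |
| λ | min(5/M, 0.95) | group sparsity; must exceed 1/M for M > 1 |
| e₀, f₀ | 1e-3, 1e-3 | vague gamma on α |
| g₀, h₀ | 1e-3, 1e-3 | vague gamma on each ψ |
| v₀ | 1e4 | vague variance for voxel means ν |

λ = 5/M encodes the expectation that modes overlap (each voxel can sit in
several modes); the 0.95 cap keeps the spike active when 5/M would reach 1.
γ is fixed rather than inferred; its value only sets the scale split between
maps and time courses, which the unit-diagonal `K_A` and the α prior already
constrain softly. No hard renormalisation is applied during inference; a
post-hoc `variance_normalize_modes` utility exists for reporting.

## Variational scheme

The posterior factorises over {subject (P,q) pairs, group (μ,ρ) pairs, π,
σ², per-run time courses per mode, α, per-run (ν, ψ)}. Two structure
choices matter:

* `(P, q)` and `(μ, ρ)` are kept as *structured pairs* (Bernoulli-gated
  Gaussians). Full mean field between the weight and its indicator would
  collapse the spike: the Gaussian factor would have to cover both branches.
  The gated form has an exact coordinate update: the slab moments solve the
  usual Gaussian conjugate update, and the gate takes the log-odds of slab
  vs delta evidence, using digamma forms E[log π] − E[log(1−π)] (exact
  conjugate-exponential VB, not the log-of-mean approximation).
* q(A) factorises across modes and runs but keeps the full T×T Gaussian per
  mode per run. This keeps each solve at O(T³) per mode instead of
  O((MT)³), and preserves the within-mode temporal correlations that the
  precision update needs.

Sweep order: subject maps → group means → group variances → mixture weights
→ time courses → temporal precision → noise (ν before ψ within a run).
Spatial factors go first so time-course updates see subject-pooled maps;
precision updates consume fresh second moments. Within the subject-map and
time-course updates, modes are swept sequentially against a maintained
residual, so each inner step is an exact coordinate maximisation — this is
what makes the ELBO provably non-decreasing, which the test suite checks
numerically (monotonicity across sweeps, and vanishing finite-difference
ELBO gradients immediately after each update).

Subject-map evidence is pooled over a subject's runs weighted by each run's
E[ψ], so noisier runs count for less.

### Numerical choices

* `K_A` is normalised to unit diagonal (so α is the marginal time-course
  precision) and ridge-regularised — shifts of 1e-6·λ_max are added until
  positive definite, then the diagonal is rescaled back to exactly 1.
* Posteriors are *initialised* at moderate values (e.g. q(σ²) = IG(2, 1))
  rather than at the vague priors: Beta/Gamma/InvGamma distributions with
  shape ~1e-3 have E[log x] dominated by the digamma pole, which would
  saturate every slab gate on the first sweep. Initialisation is not an
  update, so conjugacy and monotonicity are unaffected.
* Two initialisation schemes: `random` (subject slab means ~ N(0,1),
  q = λ) and `svd` (default), which seeds maps from the top-M left singular
  vectors of the concatenated demeaned data, *scrambled by a seed-dependent
  random orthogonal rotation across modes*. Different seeds therefore start
  from disparate points in mode space while sharing the data-driven
  subspace — the analogue of randomising an ICA unmixing matrix after
  whitening — and the spatial prior performs the unmixing. Pure random
  initialisation also works but needs many more sweeps at low SNR.
* Both schemes seed time courses by least-squares regression of each run on
  the initial maps.
* Convergence: relative ELBO change < 1e-8 for 5 consecutive sweeps, or
  `max_iter` (default 1000).
* Data are variance-normalised per voxel per run before fitting (config
  flag, default on); voxel means are handled by ν.
* Degenerate voxels (zero data variance) can be masked to q = 0 via the
  `active_mask` argument instead of producing NaNs.
* Mode elimination is emergent shrinkage; `mode_strengths` /
  `eliminated_modes` flag modes whose group-map standard deviation,
  normalised by the strongest mode, falls below 0.05 (reporting only).

## Simulator

The simulator generates a one-dimensional "brain" whose ground truth is
known exactly, with defaults emulating a scaled-down multi-band
resting-state acquisition protocol:
V = 12,500 voxels, N = 200 parcels, M = 25 modes, S = 30 subjects × 4 runs ×
1200 time points at TR 0.72 s (4800 time points per subject; 144,000 total),
neural resolution 0.1 s, −10 dB SNR.

Pipeline, each stage independently seeded:

1. **Atlas** — N contiguous disjoint parcels tiling [0, V), Dirichlet widths
   (minimum 2 voxels).
2. **Subject warps** — a smooth monotone displacement field (Gaussian noise
   convolved with a wide Gaussian window), rescaled so no boundary moves
   more than 1.5 mean parcel widths; order, count and minimum width are
   preserved by construction.
3. **Mode weights** — per-mode sparsity ~ Beta moment-matched to mean 0.08,
   variance 7.5e-4; ⌈s_m·N⌉ parcels selected with Markov clumping
   (probability 0.5 of picking a neighbour of the current selection);
   signed Gaussian weights with AR(1) magnitude correlation (0.7) within
   contiguous blocks. This yields ≈16.5 active parcels per mode and ≈2
   modes per parcel.
4. **Subject weights** — group weights plus a Bernoulli(0.1) mask of
   N(0, 0.5²) deviations. Subject maps are exactly (atlas indicator) ×
   (subject weights).
5. **Neural time courses** — jointly Gaussian at 0.1 s resolution with a
   low-rank random inter-mode correlation matrix, perturbed per subject and
   per run (eigenvalue-clipped back to a correlation matrix if needed);
   spectrally shaped by a common filter that boosts power below 0.1 Hz
   (common linear filtering preserves the zero-lag correlations); then the
   smallest 80% of each mode's |amplitude| set exactly to zero.
6. **Haemodynamics** — convolution with an HRF drawn per (subject, parcel)
   from a 3-member basis (canonical double-gamma and ±1 s peak-delay,
   ±10% dispersion variants); decimation to the TR grid by strided sampling
   when TR/dt is an integer, otherwise exact-time linear interpolation
   (the default 0.72/0.1 ratio is non-integer). Per-parcel HRF assignment
   makes voxel-level convolution exact but cheap; a per-voxel flag exists.
7. **Saturation** — y = x − c·x·|x| (c = 0.25), clamped constant beyond
   |x| = 1/(2c): odd, monotone, compressive; c = 0 is the identity.
8. **Noise** — white Gaussian, rescaled post hoc so the realised SNR is
   exactly −10 dB over the whole dataset (per-run option available).

The stored reference time courses (`bold_tc`) are the neural series
convolved with the *canonical* HRF, since with HRFs varying by parcel no
single mode-level BOLD series exists.

### What the simulations do and do not show

The simulator deliberately violates model assumptions the way real data do:
the neural process is not white (low-frequency power), time courses are
non-Gaussian (80% zeros), HRFs vary over subjects and space, the
saturation is nonlinear, and subject maps differ by spatial warps, not by
the model's additive slab deviations. Passing the recovery tests therefore
shows robustness to these mismatches at realistic SNR. It does *not* show
anything about 3-D spatial structure, physiological/motion artefacts,
registration error beyond smooth 1-D warps, or real-data effect sizes.

## Scoring conventions

* **Similarity** is the uncentered Pearson correlation (means not removed):
  the factorisation is scale-ambiguous but not shift-ambiguous. A
  correlation against an all-zero vector is *undefined* and reported as
  missing, never as 0.
* **Matching** solves the assignment problem (Hungarian algorithm) on the
  sum of spatial and temporal scores, scoring each candidate pair at its
  better joint sign — one flip applied to a mode's map and time course
  together. When mode counts differ, unmatched modes are excluded from
  means and listed separately.
* **Netmat RMSE** compares mode×mode Pearson correlation matrices (spatial
  from subject maps, temporal from concatenated run time courses), averages
  the elementwise error over subjects, then takes the RMS over off-diagonal
  elements.
* **Test–retest** matches two decompositions of the same data from
  different initialisations and reports per-pair map correlations plus a
  normalised strength (map s.d. over the strongest mode's, max over the
  pair); pairs below 0.05 are flagged as eliminated.
* **Group statistics**: per-subject correlations are Fisher-transformed,
  t-tested across subjects per element, and the t values (S−1 d.f.)
  converted to z by two-sided tail matching, preserving sign. Partial
  correlations always condition on the *full* mode set and return the
  requested block.
* **Dual regression** (two-stage least squares) doubles as the scoring-time
  baseline: group-PCA maps → per-subject time courses → subject maps.

## Problem sizes used by the test suite

The automated tests run at desk scale: simulator statistics on the default
configuration's samplers (hundreds to thousands of replicates); ELBO
monotonicity on twenty V=200/T=60/S=3/M=3 datasets; update stationarity on
V=8/T=12 instances; and a recovery study at V=2000, N=50, M=10, S=8,
2 runs × 150 time points, −10 dB SNR, fitted for 60 sweeps from two seeds.
At that problem size the fit recovers subject maps more accurately than the
group-PCA + dual-regression baseline, and per-mode accuracy correlates
positively with test–retest reliability — the property that makes
reliability a usable proxy for accuracy on real data, where ground truth is
unavailable. Accuracies at these sizes are far from the asymptote; they
grow with V, runs and sweeps.

## Known limitations

* One canonical HRF in the prior; no subject- or voxel-specific HRF
  inference (the simulator varies HRFs precisely to test robustness to
  this).
* White noise per run; no temporally or spatially coloured noise, no
  voxelwise precision.
* No spatial smoothness or contiguity prior, by design — this keeps the
  cost linear in V and is what makes very large studies feasible.
* Mean-field VB underestimates posterior correlations between factors;
  ELBO values are comparable only within a fixed factorisation.
* The map/time-course scale split is only softly identified (unit-diagonal
  K_A plus the α prior); compare decompositions after
  `variance_normalize_modes`.
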