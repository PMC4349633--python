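"""Ground-truth simulator for multi-subject resting-state fMRI.

Generates a scaled model of a multi-run rfMRI study on a one-dimensional
"brain": a group atlas of contiguous random parcels, smoothly warped per
subject; sparse signed mode weights over parcels with spatial clumping;
neural time courses at high temporal resolution with low-frequency power,
inter-mode correlations and amplitude thresholding; haemodynamic convolution
with an HRF drawn from a small basis varying over subjects and parcels; a
compressive saturation nonlinearity; and white noise at a controlled SNR.

Defaults emulate a scaled-down multi-band resting-state acquisition
protocol: 12,500 voxels, 200
parcels, 25 modes, 30 subjects x 4 runs x 1200 time points at TR 0.72 s,
neural resolution 0.1 s, -10 dB SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .engine import MultiRunDataset
from .hrf import canonical_hrf

__all__ = [
    "SimConfig",
    "ParcelAtlas",
    "GroundTruth",
    "generate_atlas",
    "warp_atlas",
    "sample_mode_weights",
    "sample_subject_weights",
    "sample_neural_timecourses",
    "apply_haemodynamics",
    "apply_saturation",
    "add_noise",
    "simulate_dataset",
]


@dataclass
class SimConfig:
    """All knobs of the simulation, with the default study conditions baked in."""

    V: int = 12500
    N: int = 200
    M: int = 25
    S: int = 30
    runs_per_subject: int = 4
    T: int = 1200
    tr: float = 0.72
    dt_neural: float = 0.1
    sparsity_mean: float = 0.08
    sparsity_var: float = 7.5e-4
    zero_fraction: float = 0.8
    snr_db: float = -10.0
    max_shift_ratio: float = 1.5
    adjacency_strength: float = 0.5
    weight_neighbour_corr: float = 0.7
    subject_deviation_sparsity: float = 0.1
    deviation_scale: float = 0.5
    corr_rank: int = 3
    corr_strength: float = 0.6
    corr_subject_jitter: float = 0.2
    corr_run_jitter: float = 0.1
    lowfreq_knee_hz: float = 0.1
    lowfreq_boost: float = 4.0
    saturation_c: float = 0.25
    snr_per_run: bool = False
    hrf_per_voxel: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("V", "N", "M", "S", "runs_per_subject", "T"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.zero_fraction < 1.0:
            raise ValueError("zero_fraction must lie in (0, 1)")
        if not 0.0 < self.sparsity_mean < 1.0:
            raise ValueError("sparsity_mean must lie in (0, 1)")
        if self.max_shift_ratio < 0:
            raise ValueError("max_shift_ratio must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ParcelAtlas:
    """Hard 1-D parcellation: ``labels[v]`` in 1..N, contiguous and disjoint."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")

    @property
    def V(self) -> int:
        return self.labels.size

    @property
    def N(self) -> int:
        return int(self.labels.max())

    def indicator(self) -> np.ndarray:
        """V x N binary membership matrix."""
        ind = np.zeros((self.V, self.N))
        ind[np.arange(self.V), self.labels - 1] = 1.0
        return ind

    def boundaries(self) -> np.ndarray:
        """Start index of each parcel (length N), assuming contiguity."""
        change = np.flatnonzero(np.diff(self.labels)) + 1
        return np.concatenate([[0], change])


@dataclass
class GroundTruth:
    """Full latent state of a simulated dataset, for scoring."""

    config: SimConfig
    group_atlas: ParcelAtlas
    subject_atlases: dict[str, ParcelAtlas]
    group_weights: np.ndarray  # N x M
    subject_weights: dict[str, np.ndarray]
    subject_maps: dict[str, np.ndarray]  # V x M
    neural_tc: dict[tuple[str, str], np.ndarray]  # M x T_highres
    bold_tc: dict[tuple[str, str], np.ndarray]  # M x T (canonical HRF)
    clean_signal: dict[tuple[str, str], np.ndarray]  # V x T
    noise: dict[tuple[str, str], np.ndarray]  # V x T

    def group_maps(self) -> np.ndarray:
        return self.group_atlas.indicator() @ self.group_weights


# ----------------------------------------------------------------------------
# Atlas
# ----------------------------------------------------------------------------

_MIN_PARCEL_WIDTH = 2


def generate_atlas(V: int, N: int, seed) -> ParcelAtlas:
    """N contiguous, disjoint parcels tiling [0, V) with Dirichlet widths."""
    if N > V // _MIN_PARCEL_WIDTH:
        raise ValueError(f"cannot fit {N} parcels of width >= {_MIN_PARCEL_WIDTH} in {V} voxels")
    rng = np.random.default_rng(seed)
    spare = V - _MIN_PARCEL_WIDTH * N
    widths = np.full(N, _MIN_PARCEL_WIDTH, dtype=int)
    if spare > 0:
        frac = rng.dirichlet(np.full(N, 5.0))
        extra = np.floor(frac * spare).astype(int)
        shortfall = spare - extra.sum()
        if shortfall > 0:
            order = np.argsort(frac * spare - extra)[::-1]
            extra[order[:shortfall]] += 1
        widths += extra
    labels = np.repeat(np.arange(1, N + 1), widths)
    return ParcelAtlas(labels=labels)


def warp_atlas(atlas: ParcelAtlas, max_shift_ratio: float, seed) -> ParcelAtlas:
    """Smooth monotone 1-D warp of the parcel boundaries.

    A low-pass-filtered Gaussian displacement field, rescaled so its largest
    magnitude is at most ``max_shift_ratio`` mean parcel widths, is applied to
    every internal boundary; parcel order, count and the minimum width are
    preserved.
    """
    if max_shift_ratio < 0:
        raise ValueError("max_shift_ratio must be >= 0")
    V, N = atlas.V, atlas.N
    if max_shift_ratio == 0:
        return ParcelAtlas(labels=atlas.labels.copy())
    rng = np.random.default_rng(seed)
    mean_width = V / N
    # Smooth field: Gaussian noise convolved with a wide Gaussian window.
    noise = rng.standard_normal(V)
    width = max(int(V / 20), 3)
    x = np.arange(-3 * width, 3 * width + 1)
    window = np.exp(-0.5 * (x / width) ** 2)
    window /= window.sum()
    disp = np.convolve(noise, window, mode="same")
    cap = int(np.floor(max_shift_ratio * mean_width))  # shift cap in voxels
    peak = np.abs(disp).max()
    if peak > 0:
        disp *= cap / peak

    bounds = atlas.boundaries()[1:]  # internal boundaries only
    new_bounds = np.round(bounds + disp[bounds]).astype(int)
    # Restore monotonicity and minimum widths; each boundary stays within
    # `cap` voxels of its original position (feasible because the original
    # boundaries are at least the minimum width apart).
    lo = _MIN_PARCEL_WIDTH
    for i in range(new_bounds.size):
        hi = min(bounds[i] + cap, V - (N - 1 - i) * _MIN_PARCEL_WIDTH)
        new_bounds[i] = min(max(new_bounds[i], lo, bounds[i] - cap), hi)
        lo = new_bounds[i] + _MIN_PARCEL_WIDTH
    widths = np.diff(np.concatenate([[0], new_bounds, [V]]))
    labels = np.repeat(np.arange(1, N + 1), widths)
    return ParcelAtlas(labels=labels)


# ----------------------------------------------------------------------------
# Mode weights
# ----------------------------------------------------------------------------

def beta_moments_to_params(mean: float, var: float) -> tuple[float, float]:
    """Moment-match (mean, variance) to beta (a, b); errors if infeasible."""
    if var <= 0 or var >= mean * (1.0 - mean):
        raise ValueError("beta variance must lie in (0, mean*(1-mean))")
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def sample_sparsities(M: int, mean: float, var: float, rng) -> np.ndarray:
    """Per-mode sparsity levels drawn from the moment-matched beta."""
    a, b = beta_moments_to_params(mean, var)
    return rng.beta(a, b, size=M)


def _select_parcels(N: int, k: int, adjacency_strength: float, rng) -> np.ndarray:
    """Select k of N parcels, favouring neighbours of already-selected parcels.

    With probability ``adjacency_strength`` the next parcel is drawn from the
    unselected neighbours of the current selection (if any exist); otherwise
    it is drawn uniformly from the unselected parcels.  Strength 0 reduces to
    uniform sampling without replacement.
    """
    if not 0 <= k <= N:
        raise ValueError("k must lie in [0, N]")
    selected = np.zeros(N, dtype=bool)
    chosen = []
    for i in range(k):
        neighbours = []
        if i > 0 and adjacency_strength > 0:
            idx = np.flatnonzero(selected)
            cand = np.unique(np.concatenate([idx - 1, idx + 1]))
            cand = cand[(cand >= 0) & (cand < N)]
            neighbours = cand[~selected[cand]]
        if len(neighbours) > 0 and rng.random() < adjacency_strength:
            pick = rng.choice(neighbours)
        else:
            pick = rng.choice(np.flatnonzero(~selected))
        selected[pick] = True
        chosen.append(pick)
    return np.sort(np.array(chosen, dtype=int))


def sample_mode_weights(
    N: int,
    M: int,
    sparsity_beta: tuple[float, float] = (0.08, 7.5e-4),
    adjacency_strength: float = 0.5,
    seed=0,
    neighbour_corr: float = 0.7,
) -> np.ndarray:
    """Sparse signed group mode weights over parcels (N x M).

    Per mode: a beta-distributed sparsity sets the number of active parcels
    (ceil(s_m * N)); parcels are selected with spatial clumping; weights are
    signed Gaussians, with adjacent selected parcels sharing correlated
    magnitudes (an AR(1) walk within each contiguous block).
    """
    rng = np.random.default_rng(seed)
    mean, var = sparsity_beta
    sparsities = sample_sparsities(M, mean, var, rng)
    W = np.zeros((N, M))
    for m in range(M):
        k = min(int(np.ceil(sparsities[m] * N)), N)
        idx = _select_parcels(N, k, adjacency_strength, rng)
        w = np.empty(k)
        for j in range(k):
            if j > 0 and idx[j] == idx[j - 1] + 1:
                w[j] = neighbour_corr * w[j - 1] + np.sqrt(
                    1.0 - neighbour_corr**2
                ) * rng.standard_normal()
            else:
                w[j] = rng.standard_normal()
        W[idx, m] = w
    return W


def sample_subject_weights(
    group_weights: np.ndarray,
    subject_deviation_sparsity: float,
    deviation_scale: float,
    seed,
    S: int = 1,
) -> list[np.ndarray]:
    """Per-subject weights: group plus a sparse set of Gaussian deviations."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(S):
        mask = rng.random(group_weights.shape) < subject_deviation_sparsity
        dev = deviation_scale * rng.standard_normal(group_weights.shape)
        out.append(group_weights + mask * dev)
    return out


# ----------------------------------------------------------------------------
# Time courses
# ----------------------------------------------------------------------------

def random_correlation(M: int, rank: int, strength: float, rng) -> np.ndarray:
    """Random correlation matrix from a low-rank factor construction."""
    F = rng.standard_normal((M, rank))
    C = strength * (F @ F.T) / rank + (1.0 - strength) * np.eye(M)
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d)


def _nearest_correlation(C: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and renormalise the diagonal."""
    evals, evecs = np.linalg.eigh(C)
    if evals.min() > 1e-10:
        return C
    evals = np.clip(evals, 1e-8, None)
    C = (evecs * evals) @ evecs.T
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d)


def perturb_correlation(C: np.ndarray, jitter: float, rng) -> np.ndarray:
    """Blend a correlation matrix with an independent random one."""
    if jitter <= 0:
        return C
    M = C.shape[0]
    noise = random_correlation(M, max(M // 2, 1), 1.0, rng)
    return _nearest_correlation((1.0 - jitter) * C + jitter * noise)


def _lowfreq_filter_gains(T: int, dt: float, knee_hz: float, boost: float) -> np.ndarray:
    """Amplitude gains for an rFFT that lift power below the knee frequency."""
    freqs = np.fft.rfftfreq(T, d=dt)
    power = 1.0 + boost / (1.0 + (freqs / knee_hz) ** 4)
    return np.sqrt(power)


def sample_neural_timecourses(
    M: int,
    duration: float,
    dt_neural: float,
    correlation: np.ndarray,
    zero_fraction: float,
    seed,
    knee_hz: float = 0.1,
    boost: float = 4.0,
) -> np.ndarray:
    """High-resolution neural mode time courses (M x T_highres).

    Correlated Gaussian series with the target inter-mode correlation, shaped
    by a common low-pass-boosting filter (so the zero-lag correlation matrix
    is preserved), then amplitude-thresholded per mode so that the smallest
    ``zero_fraction`` of time points are set exactly to zero.
    """
    if not 0.0 < zero_fraction < 1.0:
        raise ValueError("zero_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    T = int(round(duration / dt_neural))
    C = _nearest_correlation(np.asarray(correlation, dtype=float))
    L = np.linalg.cholesky(C)
    white = rng.standard_normal((M, T))
    x = L @ white
    gains = _lowfreq_filter_gains(T, dt_neural, knee_hz, boost)
    x = np.fft.irfft(np.fft.rfft(x, axis=1) * gains[None, :], n=T, axis=1)
    x /= x.std(axis=1, keepdims=True)
    # Per-mode amplitude threshold: zero the smallest |x| quantile exactly.
    n_zero = int(round(zero_fraction * T))
    order = np.argsort(np.abs(x), axis=1, kind="stable")
    for m in range(M):
        x[m, order[m, :n_zero]] = 0.0
    return x


def hrf_basis(dt: float, duration: float = 32.0) -> list[np.ndarray]:
    """Three-member HRF basis: canonical double-gamma and two dispersed variants."""
    kernels = []
    for peak_delay, disp in ((6.0, 1.0), (5.0, 0.9), (7.0, 1.1)):
        k = canonical_hrf(
            dt,
            duration,
            peak_delay=peak_delay,
            peak_dispersion=disp,
            undershoot_dispersion=disp,
        )
        kernels.append(k.samples)
    return kernels


def _decimate(signal: np.ndarray, dt: float, tr: float, T_out: int) -> np.ndarray:
    """Resample from neural resolution to the TR grid.

    Strided sampling when tr/dt is an integer; otherwise exact-time linear
    interpolation at t = k * tr.
    """
    ratio = tr / dt
    T_high = signal.shape[-1]
    if abs(ratio - round(ratio)) < 1e-9:
        step = int(round(ratio))
        out = signal[..., ::step][..., :T_out]
    else:
        t_high = np.arange(T_high) * dt
        t_out = np.arange(T_out) * tr
        t_out = np.clip(t_out, None, t_high[-1])
        out = np.stack(
            [np.interp(t_out, t_high, row) for row in np.atleast_2d(signal)]
        )
        if signal.ndim == 1:
            out = out[0]
    if out.shape[-1] != T_out:
        raise ValueError("neural series too short for the requested output length")
    return out


def apply_haemodynamics(
    neural_tc: np.ndarray,
    hrf_kernels: list[np.ndarray],
    kernel_index: np.ndarray | int,
    dt_neural: float,
    tr: float,
    T_out: int,
) -> np.ndarray:
    """Convolve neural time courses with HRFs from a basis and decimate to TR.

    ``kernel_index`` is either a single basis index (all modes share one HRF)
    or a per-mode index vector.  Returns an M x T_out matrix.
    """
    if dt_neural <= 0 or tr <= 0 or dt_neural > tr + 1e-12:
        raise ValueError("require 0 < dt_neural <= tr")
    x = np.atleast_2d(np.asarray(neural_tc, dtype=float))
    M, T_high = x.shape
    idx = np.full(M, kernel_index, dtype=int) if np.isscalar(kernel_index) else np.asarray(kernel_index, dtype=int)
    conv = np.empty_like(x)
    for m in range(M):
        h = hrf_kernels[idx[m]]
        conv[m] = np.convolve(x[m], h, mode="full")[:T_high]
    out = _decimate(conv, dt_neural, tr, T_out)
    return out if neural_tc.ndim > 1 else out[0]


def apply_saturation(signal: np.ndarray, saturation_c: float) -> np.ndarray:
    """Compressive odd nonlinearity y = x - c x |x|, continued constant.

    A second-order Volterra-style saturation: monotone non-decreasing on
    |x| <= 1/(2c) and clamped at +-1/(4c) beyond; c = 0 is the identity.
    """
    if saturation_c < 0:
        raise ValueError("saturation_c must be >= 0")
    x = np.asarray(signal, dtype=float)
    if saturation_c == 0:
        return x.copy()
    limit = 1.0 / (2.0 * saturation_c)
    xc = np.clip(x, -limit, limit)
    return xc - saturation_c * xc * np.abs(xc)


def add_noise(
    clean: np.ndarray, snr_db: float, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Add white Gaussian noise at an exactly realised SNR (in dB).

    The drawn noise is rescaled post hoc so that
    10 log10(P_signal / P_noise) equals ``snr_db`` for this realisation.
    """
    clean = np.asarray(clean, dtype=float)
    p_signal = float(np.mean(clean**2))
    if p_signal <= 0:
        raise ValueError("clean signal has zero power")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(clean.shape)
    p_noise = float(np.mean(noise**2))
    target = p_signal / 10.0 ** (snr_db / 10.0)
    noise *= np.sqrt(target / p_noise)
    return clean + noise, noise


# ----------------------------------------------------------------------------
# Full pipeline
# ----------------------------------------------------------------------------

def _spawn(seed: int, *salt: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=seed, spawn_key=tuple(salt))


def simulate_dataset(config: SimConfig) -> tuple[MultiRunDataset, GroundTruth]:
    """Compose all simulation stages into a dataset plus its ground truth."""
    cfg = config
    subjects = [f"sub{i + 1:03d}" for i in range(cfg.S)]
    run_ids = [f"run{j + 1}" for j in range(cfg.runs_per_subject)]

    group_atlas = generate_atlas(cfg.V, cfg.N, _spawn(cfg.seed, 0))
    group_weights = sample_mode_weights(
        cfg.N,
        cfg.M,
        (cfg.sparsity_mean, cfg.sparsity_var),
        cfg.adjacency_strength,
        _spawn(cfg.seed, 1),
        neighbour_corr=cfg.weight_neighbour_corr,
    )
    subj_weight_list = sample_subject_weights(
        group_weights,
        cfg.subject_deviation_sparsity,
        cfg.deviation_scale,
        _spawn(cfg.seed, 2),
        S=cfg.S,
    )

    rng_group = np.random.default_rng(_spawn(cfg.seed, 3))
    group_corr = random_correlation(cfg.M, cfg.corr_rank, cfg.corr_strength, rng_group)

    kernels = hrf_basis(cfg.dt_neural)
    duration = cfg.T * cfg.tr

    subject_atlases: dict[str, ParcelAtlas] = {}
    subject_weights: dict[str, np.ndarray] = {}
    subject_maps: dict[str, np.ndarray] = {}
    neural_tc: dict[tuple[str, str], np.ndarray] = {}
    bold_tc: dict[tuple[str, str], np.ndarray] = {}
    clean_signal: dict[tuple[str, str], np.ndarray] = {}

    for i, s in enumerate(subjects):
        atlas = warp_atlas(group_atlas, cfg.max_shift_ratio, _spawn(cfg.seed, 4, i))
        subject_atlases[s] = atlas
        subject_weights[s] = subj_weight_list[i]
        indicator = atlas.indicator()
        subject_maps[s] = indicator @ subj_weight_list[i]

        rng_s = np.random.default_rng(_spawn(cfg.seed, 5, i))
        subj_corr = perturb_correlation(group_corr, cfg.corr_subject_jitter, rng_s)
        # One HRF per parcel for this subject (optionally per voxel).
        n_units = cfg.V if cfg.hrf_per_voxel else cfg.N
        hrf_assign = rng_s.integers(0, len(kernels), size=n_units)

        for j, r in enumerate(run_ids):
            rng_r = np.random.default_rng(_spawn(cfg.seed, 6, i, j))
            run_corr = perturb_correlation(subj_corr, cfg.corr_run_jitter, rng_r)
            x = sample_neural_timecourses(
                cfg.M,
                duration,
                cfg.dt_neural,
                run_corr,
                cfg.zero_fraction,
                _spawn(cfg.seed, 7, i, j),
                knee_hz=cfg.lowfreq_knee_hz,
                boost=cfg.lowfreq_boost,
            )
            neural_tc[(s, r)] = x
            bold_tc[(s, r)] = apply_haemodynamics(
                x, kernels, 0, cfg.dt_neural, cfg.tr, cfg.T
            )
            # Convolve each basis member once at the mode level, then assemble
            # voxel signals parcel-by-parcel (all voxels of a parcel share an
            # HRF), which is exact and far cheaper than voxelwise convolution.
            per_kernel = [
                apply_haemodynamics(x, kernels, k, cfg.dt_neural, cfg.tr, cfg.T)
                for k in range(len(kernels))
            ]
            clean = np.zeros((cfg.V, cfg.T))
            if cfg.hrf_per_voxel:
                vox_maps = subject_maps[s]
                for k in range(len(kernels)):
                    sel = hrf_assign == k
                    clean[sel] = vox_maps[sel] @ per_kernel[k]
            else:
                for k in range(len(kernels)):
                    parcels = np.flatnonzero(hrf_assign == k)
                    if parcels.size == 0:
                        continue
                    sel = np.isin(atlas.labels - 1, parcels)
                    clean[sel] = (
                        indicator[sel][:, parcels]
                        @ subj_weight_list[i][parcels]
                        @ per_kernel[k]
                    )
            clean_signal[(s, r)] = apply_saturation(clean, cfg.saturation_c)

    runs: dict[tuple[str, str], np.ndarray] = {}
    noise_store: dict[tuple[str, str], np.ndarray] = {}
    keys = sorted(clean_signal)
    if cfg.snr_per_run:
        for k_i, key in enumerate(keys):
            runs[key], noise_store[key] = add_noise(
                clean_signal[key], cfg.snr_db, _spawn(cfg.seed, 8, k_i)
            )
    else:
        # Whole-dataset SNR: one global rescaling of the drawn noise.
        p_signal = np.mean([np.mean(clean_signal[k] ** 2) for k in keys])
        drawn = {}
        for k_i, key in enumerate(keys):
            rng_n = np.random.default_rng(_spawn(cfg.seed, 8, k_i))
            drawn[key] = rng_n.standard_normal(clean_signal[key].shape)
        p_noise = np.mean([np.mean(drawn[k] ** 2) for k in keys])
        scale = np.sqrt(p_signal / 10.0 ** (cfg.snr_db / 10.0) / p_noise)
        for key in keys:
            noise_store[key] = drawn[key] * scale
            runs[key] = clean_signal[key] + noise_store[key]

    dataset = MultiRunDataset(runs=runs, tr=cfg.tr)
    truth = GroundTruth(
        config=cfg,
        group_atlas=group_atlas,
        subject_atlases=subject_atlases,
        group_weights=group_weights,
        subject_weights=subject_weights,
        subject_maps=subject_maps,
        neural_tc=neural_tc,
        bold_tc=bold_tc,
        clean_signal=clean_signal,
        noise=noise_store,
    )
    return dataset, truth
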