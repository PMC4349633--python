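"""Coordinate-ascent variational inference for probabilistic functional modes.

The model factorises every run of every subject as D = P A + noise, with a
hierarchical delta-Gaussian spatial prior shared across a subject's runs
(:mod:`pfmodes.spatial`), an HRF-autocorrelation Gaussian process prior on
each mode time course (:mod:`pfmodes.temporal`), and a white-noise model per
run (:mod:`pfmodes.noise`).  All factors are conjugate-exponential, so each
coordinate update is available in closed form and every full sweep cannot
decrease the evidence lower bound (ELBO).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, digamma, gammaln, xlogy

from .hrf import TemporalPrior, build_temporal_prior
from .noise import NoisePosterior, expected_residual_sq, update_noise
from .spatial import (
    GroupSpatialPosterior,
    SubjectMapPosterior,
    group_map_point_estimate,
    update_group_means,
    update_group_variances,
    update_mixture_weights,
    update_subject_maps,
)
from .temporal import (
    TemporalPrecisionPosterior,
    TimeCoursePosterior,
    update_temporal_precision,
    update_time_courses,
)

__all__ = [
    "MultiRunDataset",
    "Hyperparameters",
    "FitConfig",
    "ModelState",
    "initialize",
    "fit",
    "compute_elbo",
    "mode_strengths",
]

logger = logging.getLogger(__name__)

RunKey = tuple[str, str]


@dataclass
class MultiRunDataset:
    """All runs of all subjects: (subject, run) -> V x T matrix, plus the TR."""

    runs: dict[RunKey, np.ndarray]
    tr: float

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValueError("dataset contains no runs")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        V = None
        for key, mat in self.runs.items():
            mat = np.asarray(mat, dtype=float)
            self.runs[key] = mat
            if mat.ndim != 2 or mat.shape[1] < 2:
                raise ValueError(f"run {key} must be a V x T matrix with T >= 2")
            if not np.all(np.isfinite(mat)):
                raise ValueError(f"run {key} contains non-finite values")
            if V is None:
                V = mat.shape[0]
            elif mat.shape[0] != V:
                raise ValueError(
                    f"run {key} has V={mat.shape[0]}, expected {V} (all runs must share V)"
                )

    @property
    def V(self) -> int:
        return next(iter(self.runs.values())).shape[0]

    @property
    def subjects(self) -> list[str]:
        return sorted({s for s, _ in self.runs})

    def runs_of(self, subject: str) -> list[RunKey]:
        return sorted(k for k in self.runs if k[0] == subject)

    @property
    def total_timepoints(self) -> int:
        return sum(mat.shape[1] for mat in self.runs.values())


@dataclass
class Hyperparameters:
    """Prior parameters for every factor; all broad and config-exposed."""

    pi_a0: float = 1.0
    pi_b0: float = 1.0
    sigma_shape0: float = 1e-3
    sigma_rate0: float = 1e-3
    gamma_prec: float = 1.0
    lambda_sparsity: float | None = None  # default 5/M, capped at 0.95
    alpha_shape0: float = 1e-3
    alpha_rate0: float = 1e-3
    psi_shape0: float = 1e-3
    psi_rate0: float = 1e-3
    nu_var0: float = 1e4

    def resolved_lambda(self, M: int) -> float:
        lam = self.lambda_sparsity
        if lam is None:
            lam = min(5.0 / M, 0.95)
        if not 0.0 < lam <= 1.0 or (M > 1 and lam <= 1.0 / M):
            raise ValueError("lambda_sparsity must lie in (1/M, 1]")
        return lam


@dataclass
class FitConfig:
    """Sweep controls for :func:`fit`."""

    max_iter: int = 1000
    tol: float = 1e-8
    tol_sweeps: int = 5
    init_scheme: str = "svd"
    normalize: bool = True  # per-voxel, per-run variance normalisation
    elimination_threshold: float = 0.05
    hyper: Hyperparameters = field(default_factory=Hyperparameters)
    log_every: int = 10


@dataclass
class ModelState:
    """Full variational state of a decomposition."""

    M: int
    group: GroupSpatialPosterior
    subjects: dict[str, SubjectMapPosterior]
    timecourses: dict[RunKey, TimeCoursePosterior]
    alpha: TemporalPrecisionPosterior
    noise: dict[RunKey, NoisePosterior]
    priors: dict[int, TemporalPrior]  # keyed by run length T
    elbo_trace: list[float] = field(default_factory=list)
    rng_seed: int = 0

    def prior_for(self, tc: TimeCoursePosterior) -> TemporalPrior:
        return self.priors[tc.T]

    def group_maps(self) -> np.ndarray:
        return group_map_point_estimate(self.group)

    def subject_maps(self) -> dict[str, np.ndarray]:
        return {s: p.mean() for s, p in self.subjects.items()}


def _normalize_dataset(data: MultiRunDataset) -> MultiRunDataset:
    runs = {}
    for key, D in data.runs.items():
        sd = D.std(axis=1, keepdims=True)
        sd = np.where(sd > 1e-12, sd, 1.0)
        runs[key] = D / sd
    return MultiRunDataset(runs=runs, tr=data.tr)


def initialize(
    data: MultiRunDataset,
    M: int,
    seed: int,
    scheme: str = "random",
    hyper: Hyperparameters | None = None,
) -> ModelState:
    """Build a reproducible starting state.

    ``random`` draws subject slab means from N(0, 1) with q_prob = lambda;
    ``svd`` seeds the group and subject means from the top-M left singular
    vectors of the concatenated, demeaned data, scrambled by a seed-dependent
    random orthogonal rotation across modes — different seeds start from
    disparate points in mode space while sharing the data-driven subspace,
    and the non-Gaussian spatial prior is left to do the unmixing.  Both
    schemes then seed the time courses by least-squares regression of each
    run on the initial subject maps, so the first sweep starts from a
    sensible reconstruction.
    """
    hyper = hyper or Hyperparameters()
    V = data.V
    if not 1 <= M < min(V, data.total_timepoints):
        raise ValueError(f"M={M} out of range for V={V}")
    lam = hyper.resolved_lambda(M)
    rng = np.random.default_rng(seed)

    if scheme == "random":
        group_mu = np.zeros((V, M))
        rho = np.full((V, M), 0.5)
        subj_means = {
            s: rng.standard_normal((V, M)) for s in data.subjects
        }
        q0 = lam
    elif scheme == "svd":
        concat = np.concatenate(
            [D - D.mean(axis=1, keepdims=True) for D in data.runs.values()], axis=1
        )
        # economy SVD; deterministic up to column sign, which we fix by
        # making the largest-magnitude entry of each map positive.
        U, svals, _ = np.linalg.svd(concat, full_matrices=False)
        U = U[:, :M] * svals[:M] / np.sqrt(concat.shape[1])
        signs = np.sign(U[np.abs(U).argmax(axis=0), np.arange(M)])
        U = U * np.where(signs == 0, 1.0, signs)
        if M > 1:
            rot = np.linalg.qr(rng.standard_normal((M, M)))[0]
            U = U @ rot
        group_mu = U
        rho = np.full((V, M), 0.9)
        subj_means = {s: U.copy() for s in data.subjects}
        q0 = 0.5
    else:
        raise ValueError(f"unknown initialisation scheme: {scheme!r}")

    group = GroupSpatialPosterior(
        pi_a=np.full((V, M), hyper.pi_a0),
        pi_b=np.full((V, M), hyper.pi_b0),
        rho_prob=rho,
        mu_mean=group_mu,
        mu_var=np.ones((V, M)),
        sigma_shape=np.full((V, M), 2.0),
        sigma_rate=np.full((V, M), 1.0),
        gamma_prec=np.full(M, hyper.gamma_prec),
        lambda_sparsity=lam,
    )
    subjects = {
        s: SubjectMapPosterior(
            slab_mean=subj_means[s],
            slab_var=np.ones((V, M)),
            q_prob=np.full((V, M), q0),
        )
        for s in data.subjects
    }

    priors = {
        T: build_temporal_prior(T, data.tr)
        for T in sorted({D.shape[1] for D in data.runs.values()})
    }

    timecourses: dict[RunKey, TimeCoursePosterior] = {}
    noise: dict[RunKey, NoisePosterior] = {}
    for key, D in data.runs.items():
        s = key[0]
        pbar = subjects[s].mean()
        T = D.shape[1]
        gram = pbar.T @ pbar + 1e-8 * np.eye(M)
        mean = np.linalg.solve(gram, pbar.T @ (D - D.mean(axis=1, keepdims=True)))
        cov = np.broadcast_to(0.1 * np.eye(T), (M, T, T)).copy()
        timecourses[key] = TimeCoursePosterior(mean=mean, cov=cov)
        noise[key] = NoisePosterior(
            psi_shape=1.0, psi_rate=1.0, nu_mean=np.zeros(V), nu_var=np.full(V, 0.1)
        )

    return ModelState(
        M=M,
        group=group,
        subjects=subjects,
        timecourses=timecourses,
        alpha=TemporalPrecisionPosterior(shape=1.0, rate=1.0),
        noise=noise,
        priors=priors,
        elbo_trace=[],
        rng_seed=seed,
    )


def sweep(state: ModelState, data: MultiRunDataset, hyper: Hyperparameters) -> None:
    """One full coordinate-ascent sweep, in place.

    Order: subject maps -> group means -> group variances -> mixture weights
    -> time courses -> temporal precision -> noise.  Spatial factors go first
    so the time-course updates see subject-pooled maps; the precision update
    consumes fresh time-course second moments.
    """
    for s in data.subjects:
        runs = [
            (data.runs[k], state.timecourses[k], state.noise[k])
            for k in data.runs_of(s)
        ]
        state.subjects[s] = update_subject_maps(runs, state.group, state.subjects[s])

    g = state.group
    g.rho_prob, g.mu_mean, g.mu_var = update_group_means(state.subjects, g)
    g.sigma_shape, g.sigma_rate = update_group_variances(
        state.subjects, g, (hyper.sigma_shape0, hyper.sigma_rate0)
    )
    g.pi_a, g.pi_b = update_mixture_weights(
        state.subjects, (hyper.pi_a0, hyper.pi_b0)
    )

    for key, D in data.runs.items():
        s = key[0]
        moments = (state.subjects[s].mean(), state.subjects[s].second_moment())
        state.timecourses[key] = update_time_courses(
            D,
            moments,
            state.noise[key],
            state.alpha,
            state.priors[D.shape[1]],
            state.timecourses[key],
        )

    tc_priors = {k: state.priors[tc.T] for k, tc in state.timecourses.items()}
    state.alpha = update_temporal_precision(
        state.timecourses, tc_priors, (hyper.alpha_shape0, hyper.alpha_rate0)
    )

    for key, D in data.runs.items():
        s = key[0]
        moments = (state.subjects[s].mean(), state.subjects[s].second_moment())
        state.noise[key] = update_noise(
            D,
            moments,
            state.timecourses[key],
            (hyper.psi_shape0, hyper.psi_rate0, hyper.nu_var0),
            state.noise[key],
        )


def fit(data: MultiRunDataset, M: int, config: FitConfig | None = None,
        seed: int = 0) -> ModelState:
    """Run coordinate-ascent VB until the ELBO stabilises or max_iter sweeps."""
    config = config or FitConfig()
    hyper = config.hyper
    if config.normalize:
        data = _normalize_dataset(data)
    state = initialize(data, M, seed, scheme=config.init_scheme, hyper=hyper)

    stable = 0
    for it in range(config.max_iter):
        sweep(state, data, hyper)
        elbo = compute_elbo(state, data, hyper)
        if not np.isfinite(elbo):
            parts = compute_elbo(state, data, hyper, return_parts=True)
            raise FloatingPointError(f"non-finite ELBO at sweep {it}: {parts}")
        if state.elbo_trace:
            prev = state.elbo_trace[-1]
            rel = abs(elbo - prev) / max(abs(prev), 1.0)
            stable = stable + 1 if rel < config.tol else 0
        state.elbo_trace.append(elbo)
        if config.log_every and it % config.log_every == 0:
            logger.info("sweep %d: ELBO = %.6e", it, elbo)
        if stable >= config.tol_sweeps:
            logger.info("converged after %d sweeps (ELBO %.6e)", it + 1, elbo)
            break
    return state


# ----------------------------------------------------------------------------
# ELBO
# ----------------------------------------------------------------------------

_LOG2PI = np.log(2.0 * np.pi)


def _entropy_bernoulli(p: np.ndarray) -> np.ndarray:
    return -(xlogy(p, p) + xlogy(1.0 - p, 1.0 - p))


def compute_elbo(
    state: ModelState,
    data: MultiRunDataset,
    hyper: Hyperparameters | None = None,
    return_parts: bool = False,
):
    """Evidence lower bound: expected log joint minus posterior entropies.

    With ``return_parts=True`` a per-term breakdown is returned instead; the
    ``kl_*`` entries are exact KL divergences (each necessarily >= 0) of the
    conjugate factors from their priors.
    """
    hyper = hyper or Hyperparameters()
    g = state.group
    parts: dict[str, float] = {}

    e_log_pi = g.e_log_pi()
    e_log_1m_pi = g.e_log_1m_pi()
    e_inv_s2 = g.e_inv_sigma2()
    e_log_s2 = g.e_log_sigma2()
    e_mu = g.e_mu()
    e_mu2 = g.e_mu2()

    # Likelihood over runs.
    lik = 0.0
    for key, D in data.runs.items():
        s = key[0]
        subj = state.subjects[s]
        tc = state.timecourses[key]
        nz = state.noise[key]
        V, T = D.shape
        e_log_psi = digamma(nz.psi_shape) - np.log(nz.psi_rate)
        sq = expected_residual_sq(
            D, subj.mean(), subj.second_moment(), tc, nz.nu_mean, nz.nu_var
        )
        lik += -0.5 * V * T * _LOG2PI + 0.5 * V * T * e_log_psi - 0.5 * nz.psi_mean * sq
    parts["likelihood"] = lik

    # Time-course prior + entropy.
    e_log_alpha = digamma(state.alpha.shape) - np.log(state.alpha.rate)
    e_alpha = state.alpha.mean
    tc_term = 0.0
    for key, tc in state.timecourses.items():
        prior = state.priors[tc.T]
        quad = tc.prior_quadratic(prior).sum()
        tc_term += tc.M * (
            -0.5 * tc.T * _LOG2PI + 0.5 * tc.T * e_log_alpha - 0.5 * prior.logdet
        )
        tc_term += -0.5 * e_alpha * quad
        for m in range(tc.M):
            sign, ld = np.linalg.slogdet(tc.cov[m])
            tc_term += 0.5 * ld + 0.5 * tc.T * (_LOG2PI + 1.0)
    parts["timecourses"] = tc_term

    # Subject spatial factors.
    sp_term = 0.0
    for subj in state.subjects.values():
        m, v, q = subj.slab_mean, subj.slab_var, subj.q_prob
        dev = (m**2 + v) - 2.0 * m * e_mu + e_mu2
        cond = (
            e_log_pi - 0.5 * _LOG2PI - 0.5 * e_log_s2 - 0.5 * e_inv_s2 * dev
        )
        sp_term += float(np.sum(q * cond + (1.0 - q) * e_log_1m_pi))
        sp_term += float(
            np.sum(_entropy_bernoulli(q) + 0.5 * q * (_LOG2PI + 1.0 + np.log(v)))
        )
    parts["subject_maps"] = sp_term

    # Group spike-slab factor.
    lam = g.lambda_sparsity
    r, mmu, vmu = g.rho_prob, g.mu_mean, g.mu_var
    cond = (
        np.log(lam)
        + 0.5 * np.log(g.gamma_prec)[None, :]
        - 0.5 * _LOG2PI
        - 0.5 * g.gamma_prec[None, :] * (mmu**2 + vmu)
    )
    # With lambda = 1 the spike is excluded and rho = 1, so the spike term
    # vanishes; xlogy-style guard avoids 0 * (-inf).
    spike = (1.0 - r) * np.log1p(-lam) if lam < 1.0 else np.zeros_like(r)
    grp = float(np.sum(r * cond + spike))
    grp += float(np.sum(_entropy_bernoulli(r) + 0.5 * r * (_LOG2PI + 1.0 + np.log(vmu))))
    parts["group_means"] = grp

    # Exact KL terms for the remaining conjugate factors.
    parts["kl_pi"] = float(
        np.sum(_kl_beta(g.pi_a, g.pi_b, hyper.pi_a0, hyper.pi_b0))
    )
    parts["kl_sigma"] = float(
        np.sum(
            _kl_inverse_gamma(
                g.sigma_shape, g.sigma_rate, hyper.sigma_shape0, hyper.sigma_rate0
            )
        )
    )
    parts["kl_alpha"] = float(
        _kl_gamma(
            state.alpha.shape, state.alpha.rate, hyper.alpha_shape0, hyper.alpha_rate0
        )
    )
    kl_psi = 0.0
    kl_nu = 0.0
    for nz in state.noise.values():
        kl_psi += float(
            _kl_gamma(nz.psi_shape, nz.psi_rate, hyper.psi_shape0, hyper.psi_rate0)
        )
        kl_nu += float(
            np.sum(_kl_gaussian(nz.nu_mean, nz.nu_var, 0.0, hyper.nu_var0))
        )
    parts["kl_psi"] = kl_psi
    parts["kl_nu"] = kl_nu

    if return_parts:
        return parts
    return (
        parts["likelihood"]
        + parts["timecourses"]
        + parts["subject_maps"]
        + parts["group_means"]
        - parts["kl_pi"]
        - parts["kl_sigma"]
        - parts["kl_alpha"]
        - parts["kl_psi"]
        - parts["kl_nu"]
    )


def _kl_beta(a, b, a0, b0):
    return (
        betaln(a0, b0)
        - betaln(a, b)
        + (a - a0) * digamma(a)
        + (b - b0) * digamma(b)
        + (a0 - a + b0 - b) * digamma(a + b)
    )


def _kl_gamma(a, b, a0, b0):
    return (
        (a - a0) * digamma(a)
        - gammaln(a)
        + gammaln(a0)
        + a0 * (np.log(b) - np.log(b0))
        + a * (b0 - b) / b
    )


def _kl_inverse_gamma(a, b, a0, b0):
    # KL(IG(a,b) || IG(a0,b0)); same form as the gamma KL with the rate
    # entering through E[1/x] = a/b.
    return (
        (a - a0) * digamma(a)
        - gammaln(a)
        + gammaln(a0)
        + a0 * (np.log(b) - np.log(b0))
        + (b0 - b) * a / b
    )


def _kl_gaussian(m, v, m0, v0):
    return 0.5 * (np.log(v0 / v) + (v + (m - m0) ** 2) / v0 - 1.0)


# ----------------------------------------------------------------------------
# Reporting utilities
# ----------------------------------------------------------------------------

def mode_strengths(state: ModelState, normalize_by: str = "global") -> np.ndarray:
    """Per-mode group-map standard deviations, normalised for elimination checks.

    With ``normalize_by='global'`` the strengths are divided by the strongest
    mode's (the 'global component's) standard deviation; with ``'none'`` the
    raw standard deviations are returned.  Modes whose normalised strength is
    close to zero have been eliminated by the Bayesian model regularisation.
    """
    maps = state.group_maps()
    sd = maps.std(axis=0)
    if normalize_by == "global":
        ref = sd.max()
        return sd / ref if ref > 0 else sd
    if normalize_by == "none":
        return sd
    raise ValueError("normalize_by must be 'global' or 'none'")


def eliminated_modes(state: ModelState, threshold: float = 0.05) -> np.ndarray:
    """Indices of modes whose normalised strength falls below ``threshold``."""
    return np.flatnonzero(mode_strengths(state) < threshold)
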