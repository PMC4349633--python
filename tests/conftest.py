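"""Shared fixtures: tiny datasets, concentrated posteriors, FD-gradient helper."""

from __future__ import annotations

import copy

import numpy as np
import pytest

from pfmodes.engine import (
    Hyperparameters,
    MultiRunDataset,
    compute_elbo,
    initialize,
    sweep,
)
from pfmodes.noise import NoisePosterior
from pfmodes.simulate import SimConfig, simulate_dataset
from pfmodes.spatial import GroupSpatialPosterior
from pfmodes.temporal import TimeCoursePosterior


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_sim():
    """Small simulated dataset with ground truth for structural tests."""
    cfg = SimConfig(V=300, N=20, M=4, S=2, runs_per_subject=2, T=40, seed=7)
    data, truth = simulate_dataset(cfg)
    return cfg, data, truth


@pytest.fixture
def tiny_state():
    """A tiny model state advanced a few sweeps, for ELBO-based checks."""
    cfg = SimConfig(V=10, N=5, M=2, S=2, runs_per_subject=1, T=12, seed=3)
    data, _ = simulate_dataset(cfg)
    hyper = Hyperparameters()
    state = initialize(data, 2, seed=0, scheme="random", hyper=hyper)
    for _ in range(3):
        sweep(state, data, hyper)
    return state, data, hyper


def elbo_fd_grad(state, data, hyper, get, set_, h=1e-5):
    """Central-difference ELBO gradient w.r.t. a parameter vector."""
    x0 = np.atleast_1d(np.asarray(get(state), dtype=float)).copy()
    grad = np.zeros_like(x0)
    for i in range(x0.size):
        es = []
        for sign in (1.0, -1.0):
            st = copy.deepcopy(state)
            xp = x0.copy()
            xp[i] += sign * h
            set_(st, xp)
            es.append(compute_elbo(st, data, hyper))
        grad[i] = (es[0] - es[1]) / (2.0 * h)
    return grad


def concentrated_group(
    V: int,
    M: int,
    pi: float,
    sigma2: float,
    mu: np.ndarray,
    lam: float = 0.5,
    gamma: float = 1.0,
    conc: float = 1e8,
) -> GroupSpatialPosterior:
    """Group posterior numerically concentrated at given point values.

    Lets conjugate updates be compared against exact Bayes computations in
    which the hyperparameters are known constants.
    """
    return GroupSpatialPosterior(
        pi_a=np.full((V, M), max(pi * conc, 1e-8)),
        pi_b=np.full((V, M), max((1.0 - pi) * conc, 1e-8)),
        rho_prob=np.ones((V, M)),
        mu_mean=np.broadcast_to(np.asarray(mu, dtype=float), (V, M)).copy(),
        mu_var=np.full((V, M), 1e-14),
        sigma_shape=np.full((V, M), conc),
        sigma_rate=np.full((V, M), conc * sigma2),
        gamma_prec=np.full(M, gamma),
        lambda_sparsity=lam,
    )


def point_mass_tc(mean: np.ndarray) -> TimeCoursePosterior:
    """Time-course posterior with (numerically) zero covariance."""
    mean = np.atleast_2d(np.asarray(mean, dtype=float))
    M, T = mean.shape
    return TimeCoursePosterior(mean=mean, cov=np.zeros((M, T, T)))


def point_mass_noise(V: int, psi: float, conc: float = 1e10) -> NoisePosterior:
    """Noise posterior concentrated at precision ``psi`` with zero means."""
    return NoisePosterior(
        psi_shape=conc,
        psi_rate=conc / psi,
        nu_mean=np.zeros(V),
        nu_var=np.full(V, 1e-14),
    )


def gaussian_noise_dataset(V: int, T: int, S: int, runs: int, seed: int) -> MultiRunDataset:
    rng = np.random.default_rng(seed)
    return MultiRunDataset(
        runs={
            (f"s{i}", f"r{j}"): rng.standard_normal((V, T))
            for i in range(S)
            for j in range(runs)
        },
        tr=0.72,
    )
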