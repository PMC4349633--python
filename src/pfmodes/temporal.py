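"""Variational posteriors and updates for mode time courses and their precision.

Each run's time courses carry a Gaussian posterior per mode (full T x T
covariance), factorised across modes and runs.  The prior on every time course
is N(0, alpha^-1 K_A), where K_A is the HRF-autocorrelation Toeplitz matrix
(see :mod:`pfmodes.hrf`) and alpha is a global precision scalar with a gamma
posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .hrf import TemporalPrior

__all__ = [
    "TimeCoursePosterior",
    "TemporalPrecisionPosterior",
    "update_time_courses",
    "update_temporal_precision",
]


@dataclass
class TimeCoursePosterior:
    """Gaussian posterior over one run's mode time courses.

    mean : (M, T) posterior means.
    cov  : (M, T, T) posterior covariances, one per mode.
    """

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.mean.ndim != 2 or self.cov.shape != self.mean.shape + (self.mean.shape[1],):
            raise ValueError("mean must be (M, T) and cov (M, T, T)")

    @property
    def M(self) -> int:
        return self.mean.shape[0]

    @property
    def T(self) -> int:
        return self.mean.shape[1]

    def second_moment_diag(self) -> np.ndarray:
        """E[A_mt^2] as an (M, T) array."""
        return self.mean**2 + np.einsum("mtt->mt", self.cov)

    def prior_quadratic(self, prior: TemporalPrior) -> np.ndarray:
        """Per-mode E[A K_A^-1 A^T] = tr(K_A^-1 (Sigma_m + a_m a_m^T))."""
        kinv = prior.inverse
        quad = np.einsum("ij,mji->m", kinv, self.cov)
        quad += np.einsum("mi,ij,mj->m", self.mean, kinv, self.mean)
        return quad


@dataclass
class TemporalPrecisionPosterior:
    """Gamma posterior over the global time-course precision alpha."""

    shape: float
    rate: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.rate <= 0:
            raise ValueError("gamma shape and rate must be positive")

    @property
    def mean(self) -> float:
        return self.shape / self.rate


def update_time_courses(
    run_data: np.ndarray,
    map_moments: tuple[np.ndarray, np.ndarray],
    noise,
    alpha: TemporalPrecisionPosterior,
    prior: TemporalPrior,
    current: TimeCoursePosterior,
) -> TimeCoursePosterior:
    """Conjugate coordinate update of q(A) for one run, mode by mode.

    For mode m the posterior precision is ``E[alpha] K_A^-1 + E[psi]
    (sum_v E[P_vm^2]) I`` and the mean is the standard Gaussian linear-model
    solution against the residual left after subtracting the voxel means and
    the other modes' current mean reconstructions.  Modes are swept
    sequentially so each update is an exact coordinate-ascent step.
    """
    D = np.asarray(run_data, dtype=float)
    pbar, p2 = map_moments
    V, T = D.shape
    M = pbar.shape[1]
    if pbar.shape != (V, M) or p2.shape != (V, M):
        raise ValueError("map moment shapes inconsistent with run data")
    if prior.T != T:
        raise ValueError("temporal prior does not match run length")
    if current.mean.shape != (M, T):
        raise ValueError("current time-course posterior has wrong shape")

    e_alpha = alpha.mean
    e_psi = noise.psi_mean
    mean = current.mean.copy()
    cov = np.empty((M, T, T))

    # Residual of the full current reconstruction; per mode we add that
    # mode's own contribution back in.
    resid = D - noise.nu_mean[:, None] - pbar @ mean
    col_sq = (p2).sum(axis=0)  # sum_v E[P_vm^2], length M
    for m in range(M):
        resid_m = resid + np.outer(pbar[:, m], mean[m])
        prec = e_alpha * prior.inverse + (e_psi * col_sq[m]) * np.eye(T)
        c, low = cho_factor(prec)
        rhs = e_psi * (pbar[:, m] @ resid_m)
        new_mean = cho_solve((c, low), rhs)
        cov_m = cho_solve((c, low), np.eye(T))
        cov[m] = (cov_m + cov_m.T) / 2.0
        resid = resid_m - np.outer(pbar[:, m], new_mean)
        mean[m] = new_mean
    return TimeCoursePosterior(mean=mean, cov=cov)


def update_temporal_precision(
    timecourses: dict,
    priors: dict,
    hyper: tuple[float, float],
) -> TemporalPrecisionPosterior:
    """Conjugate gamma update for the global precision alpha.

    shape = shape0 + (total modes x runs x T)/2;
    rate  = rate0 + 1/2 sum over runs and modes of E[A K_A^-1 A^T].

    ``timecourses`` maps run keys to :class:`TimeCoursePosterior`; ``priors``
    maps run keys to the matching :class:`TemporalPrior`.
    """
    shape0, rate0 = hyper
    shape = shape0
    rate = rate0
    for key, tc in timecourses.items():
        prior = priors[key]
        shape += tc.M * tc.T / 2.0
        rate += 0.5 * tc.prior_quadratic(prior).sum()
    return TemporalPrecisionPosterior(shape=shape, rate=rate)
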