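"""Hierarchical spatial model: subject maps under a delta-Gaussian mixture and
group-level spike-slab posteriors.

Each voxel-mode weight for a subject is either exactly zero (the delta
component: no effect) or drawn from a Gaussian slab N(mu, sigma^2) describing
the group-mean effect size and its between-subject variability.  The slab
membership probability pi carries a beta hyperprior, sigma^2 an inverse-gamma
hyperprior, and the group means mu themselves carry a spike-slab hyperprior
N(0, gamma^-1) with sparsity lambda, so that entire voxel-mode effects can be
switched off at the group level.

The variational posterior keeps (P, q) as a structured pair — a
Bernoulli-gated Gaussian — so the slab moments are conditional on membership
and the implied first moment is E[P] = q_prob * slab_mean.  The same structure
is used for (mu, rho) at the group level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, expit

__all__ = [
    "SubjectMapPosterior",
    "GroupSpatialPosterior",
    "update_subject_maps",
    "update_group_means",
    "update_group_variances",
    "update_mixture_weights",
    "group_map_point_estimate",
]


@dataclass
class SubjectMapPosterior:
    """Bernoulli-gated Gaussian posterior over one subject's map weights.

    slab_mean, slab_var : (V, M) moments of the weight conditional on the
        voxel being active for that mode in this subject.
    q_prob : (V, M) posterior probability of activity.
    """

    slab_mean: np.ndarray
    slab_var: np.ndarray
    q_prob: np.ndarray

    def __post_init__(self) -> None:
        self.slab_mean = np.asarray(self.slab_mean, dtype=float)
        self.slab_var = np.asarray(self.slab_var, dtype=float)
        self.q_prob = np.asarray(self.q_prob, dtype=float)
        if not (self.slab_mean.shape == self.slab_var.shape == self.q_prob.shape):
            raise ValueError("subject posterior fields must share one (V, M) shape")
        if np.any(self.slab_var <= 0):
            raise ValueError("slab_var must be strictly positive")
        if np.any((self.q_prob < 0) | (self.q_prob > 1)):
            raise ValueError("q_prob must lie in [0, 1]")

    def mean(self) -> np.ndarray:
        """E[P] = q_prob * slab_mean."""
        return self.q_prob * self.slab_mean

    def second_moment(self) -> np.ndarray:
        """E[P^2] = q_prob * (slab_mean^2 + slab_var)."""
        return self.q_prob * (self.slab_mean**2 + self.slab_var)


@dataclass
class GroupSpatialPosterior:
    """Group-level posteriors for the spatial hierarchy (all arrays V x M)."""

    pi_a: np.ndarray
    pi_b: np.ndarray
    rho_prob: np.ndarray
    mu_mean: np.ndarray
    mu_var: np.ndarray
    sigma_shape: np.ndarray
    sigma_rate: np.ndarray
    gamma_prec: np.ndarray  # length M
    lambda_sparsity: float

    def __post_init__(self) -> None:
        for name in ("pi_a", "pi_b", "rho_prob", "mu_mean", "mu_var",
                     "sigma_shape", "sigma_rate"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.gamma_prec = np.asarray(self.gamma_prec, dtype=float)
        V, M = self.mu_mean.shape
        if self.gamma_prec.shape != (M,):
            raise ValueError("gamma_prec must have length M")
        if np.any(self.pi_a <= 0) or np.any(self.pi_b <= 0):
            raise ValueError("beta parameters must be positive")
        if np.any(self.mu_var <= 0):
            raise ValueError("mu_var must be strictly positive")
        if np.any(self.sigma_shape <= 0) or np.any(self.sigma_rate <= 0):
            raise ValueError("inverse-gamma parameters must be positive")
        if np.any((self.rho_prob < 0) | (self.rho_prob > 1)):
            raise ValueError("rho_prob must lie in [0, 1]")
        if not 0 < self.lambda_sparsity <= 1:
            raise ValueError("lambda_sparsity must lie in (0, 1]")

    # Expectations consumed by the updates -------------------------------

    def e_log_pi(self) -> np.ndarray:
        return digamma(self.pi_a) - digamma(self.pi_a + self.pi_b)

    def e_log_1m_pi(self) -> np.ndarray:
        return digamma(self.pi_b) - digamma(self.pi_a + self.pi_b)

    def e_inv_sigma2(self) -> np.ndarray:
        return self.sigma_shape / self.sigma_rate

    def e_log_sigma2(self) -> np.ndarray:
        return np.log(self.sigma_rate) - digamma(self.sigma_shape)

    def e_mu(self) -> np.ndarray:
        return self.rho_prob * self.mu_mean

    def e_mu2(self) -> np.ndarray:
        return self.rho_prob * (self.mu_mean**2 + self.mu_var)


def update_subject_maps(
    runs: list[tuple[np.ndarray, object, object]],
    group: GroupSpatialPosterior,
    current: SubjectMapPosterior,
    active_mask: np.ndarray | None = None,
) -> SubjectMapPosterior:
    """Structured (P, q) update for one subject, pooling all of their runs.

    ``runs`` is a list of ``(data, tc_posterior, noise_posterior)`` triples.
    Evidence from every run is combined, weighted by that run's expected noise
    precision E[psi], so high-SNR runs count for more.  Slab moments come from
    the conjugate Gaussian update against the group prior N(E[mu], E[sigma^2]);
    q_prob comes from the log-odds of the slab against the delta, including
    the E[log pi] - E[log(1 - pi)] prior term.

    Modes are swept sequentially (each sweep is an exact coordinate-ascent
    step on the structured factor); voxels are independent given the time
    courses and are updated in parallel.
    """
    V, M = current.slab_mean.shape
    e_inv_s2 = group.e_inv_sigma2()
    e_log_s2 = group.e_log_sigma2()
    e_mu = group.e_mu()
    e_mu2 = group.e_mu2()
    log_odds_prior = group.e_log_pi() - group.e_log_1m_pi()

    pbar = current.mean().copy()
    slab_mean = current.slab_mean.copy()
    slab_var = current.slab_var.copy()
    q_prob = current.q_prob.copy()

    prepared = []
    for D, tc, noise in runs:
        if D.shape[0] != V or tc.mean.shape[0] != M:
            raise ValueError("run dimensions inconsistent with subject posterior")
        resid = D - noise.nu_mean[:, None] - pbar @ tc.mean
        a2_sum = tc.second_moment_diag().sum(axis=1)  # per mode
        prepared.append([resid, tc.mean, a2_sum, noise.psi_mean])

    for m in range(M):
        beta = 0.0
        b = np.zeros(V)
        for resid, abar, a2_sum, e_psi in prepared:
            resid_m = resid + np.outer(pbar[:, m], abar[m])
            beta += e_psi * a2_sum[m]
            b += e_psi * (resid_m @ abar[m])
        prec = e_inv_s2[:, m] + beta
        mean_m = (e_inv_s2[:, m] * e_mu[:, m] + b) / prec
        log_odds = (
            log_odds_prior[:, m]
            + 0.5 * mean_m**2 * prec
            - 0.5 * e_inv_s2[:, m] * e_mu2[:, m]
            - 0.5 * e_log_s2[:, m]
            - 0.5 * np.log(prec)
        )
        q_m = expit(log_odds)
        if active_mask is not None:
            q_m = np.where(active_mask, q_m, 0.0)
        new_pbar_m = q_m * mean_m
        delta = new_pbar_m - pbar[:, m]
        for entry in prepared:
            resid, abar = entry[0], entry[1]
            entry[0] = resid - np.outer(delta, abar[m])
        pbar[:, m] = new_pbar_m
        slab_mean[:, m] = mean_m
        slab_var[:, m] = 1.0 / prec
        q_prob[:, m] = q_m

    return SubjectMapPosterior(slab_mean=slab_mean, slab_var=slab_var, q_prob=q_prob)


def update_group_means(
    subjects: dict[str, SubjectMapPosterior],
    group: GroupSpatialPosterior,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spike-slab update for the group means (rho_prob, mu_mean, mu_var).

    Each subject contributes a pseudo-observation of the group mean, weighted
    by its slab membership probability and the expected slab precision
    E[sigma^-2]; the slab prior is N(0, gamma_m^-1) and the spike log-odds
    include log(lambda) - log(1 - lambda).
    """
    if not subjects:
        raise ValueError("at least one subject is required")
    e_inv_s2 = group.e_inv_sigma2()
    lam = group.lambda_sparsity

    q_sum = sum(s.q_prob for s in subjects.values())
    qm_sum = sum(s.q_prob * s.slab_mean for s in subjects.values())

    prec = group.gamma_prec[None, :] + e_inv_s2 * q_sum
    mu_mean = e_inv_s2 * qm_sum / prec
    mu_var = 1.0 / prec
    with np.errstate(divide="ignore"):
        log_odds = (
            np.log(lam)
            - np.log1p(-lam)
            + 0.5 * mu_mean**2 * prec
            + 0.5 * np.log(group.gamma_prec)[None, :]
            - 0.5 * np.log(prec)
        )
    rho_prob = expit(log_odds)
    return rho_prob, mu_mean, mu_var


def update_group_variances(
    subjects: dict[str, SubjectMapPosterior],
    group: GroupSpatialPosterior,
    hyper: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Conjugate inverse-gamma update for the slab variances sigma^2.

    shape = shape0 + 1/2 sum_s q_prob_s;
    rate  = rate0 + 1/2 sum_s q_prob_s E[(P_vm^s - mu_vm)^2].
    """
    if not subjects:
        raise ValueError("at least one subject is required")
    shape0, rate0 = hyper
    e_mu = group.e_mu()
    e_mu2 = group.e_mu2()
    shape = np.full_like(group.sigma_shape, float(shape0))
    rate = np.full_like(group.sigma_rate, float(rate0))
    for s in subjects.values():
        second = s.slab_mean**2 + s.slab_var
        dev = second - 2.0 * s.slab_mean * e_mu + e_mu2
        shape += 0.5 * s.q_prob
        rate += 0.5 * s.q_prob * dev
    return shape, rate


def update_mixture_weights(
    subjects: dict[str, SubjectMapPosterior],
    hyper: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Conjugate beta update for pi: count expected activations per voxel-mode."""
    if not subjects:
        raise ValueError("at least one subject is required")
    a0, b0 = hyper
    q_sum = sum(s.q_prob for s in subjects.values())
    S = len(subjects)
    return a0 + q_sum, b0 + (S - q_sum)


def group_map_point_estimate(group: GroupSpatialPosterior) -> np.ndarray:
    """Marginal posterior mean of the group spatial maps, E[rho * mu]."""
    return group.rho_prob * group.mu_mean


def variance_normalize_modes(
    maps: np.ndarray, timecourses: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve the map/time-course scale ambiguity for reporting.

    Rescales each mode's time course to unit variance and moves the scale
    onto the map, leaving the product unchanged.  Modes with (numerically)
    zero time-course variance are left untouched.
    """
    sd = timecourses.std(axis=-1)
    sd = np.where(sd > 1e-12, sd, 1.0)
    return maps * sd[None, :], timecourses / sd[:, None]
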