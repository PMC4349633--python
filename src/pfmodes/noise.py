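"""Per-run white Gaussian noise model with voxelwise means.

The residual at every time point of a run is modelled as
N(nu, psi^-1 I): a per-voxel mean nu (Gaussian hyperprior) and a single
per-run precision psi (gamma hyperprior).  The expected residual power used
in the psi update is computed with the *full* second moments of the maps and
time courses, not just their squared means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NoisePosterior", "update_noise", "expected_residual_sq"]


@dataclass
class NoisePosterior:
    """Gamma posterior on the run precision psi and Gaussian posterior on nu."""

    psi_shape: float
    psi_rate: float
    nu_mean: np.ndarray
    nu_var: np.ndarray

    def __post_init__(self) -> None:
        if self.psi_shape <= 0 or self.psi_rate <= 0:
            raise ValueError("psi gamma parameters must be positive")
        self.nu_mean = np.asarray(self.nu_mean, dtype=float)
        self.nu_var = np.asarray(self.nu_var, dtype=float)
        if np.any(self.nu_var <= 0):
            raise ValueError("nu_var must be strictly positive")

    @property
    def psi_mean(self) -> float:
        return self.psi_shape / self.psi_rate


def expected_residual_sq(
    run_data: np.ndarray,
    pbar: np.ndarray,
    p2: np.ndarray,
    tc,
    nu_mean: np.ndarray,
    nu_var: np.ndarray,
) -> float:
    """E[ || D - nu 1^T - P A ||_F^2 ] under the factorised posterior.

    Uses E[P^2] and E[A A^T] (via the diagonal of the time-course second
    moments); cross-mode and map-by-time-course cross terms reduce to products
    of means because the factors are independent under q.
    """
    abar = tc.mean
    a2 = tc.second_moment_diag()
    T = abar.shape[1]
    rbar = run_data - nu_mean[:, None] - pbar @ abar
    sq = float(np.sum(rbar**2))
    sq += T * float(np.sum(nu_var))
    sq += float(np.sum(p2 @ a2)) - float(np.sum(pbar**2 @ abar**2))
    return sq


def update_noise(
    run_data: np.ndarray,
    map_moments: tuple[np.ndarray, np.ndarray],
    tc,
    hyper: tuple[float, float, float],
    current: NoisePosterior,
) -> NoisePosterior:
    """Conjugate update of (nu, psi) for one run: mean first, then scale.

    nu combines its vague zero-mean Gaussian prior with the per-voxel mean of
    the reconstruction residual (weighted by the current E[psi]); psi then
    takes shape0 + VT/2 and a rate built from the full expected residual
    power under the fresh nu posterior.
    """
    D = np.asarray(run_data, dtype=float)
    pbar, p2 = map_moments
    V, T = D.shape
    if pbar.shape[0] != V or tc.mean.shape[1] != T:
        raise ValueError("dimensions of maps/time courses do not match run data")
    psi_shape0, psi_rate0, nu_var0 = hyper

    e_psi = current.psi_mean
    recon = pbar @ tc.mean
    nu_prec = 1.0 / nu_var0 + T * e_psi
    nu_mean = e_psi * (D - recon).sum(axis=1) / nu_prec
    nu_var = np.full(V, 1.0 / nu_prec)

    sq = expected_residual_sq(D, pbar, p2, tc, nu_mean, nu_var)
    psi_shape = psi_shape0 + V * T / 2.0
    psi_rate = psi_rate0 + 0.5 * sq
    return NoisePosterior(
        psi_shape=psi_shape, psi_rate=psi_rate, nu_mean=nu_mean, nu_var=nu_var
    )
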