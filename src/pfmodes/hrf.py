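"""Canonical haemodynamic response function and the HRF-induced temporal prior.

The BOLD signal is well approximated as the convolution of an underlying
neural process with a haemodynamic response function (HRF).  If the neural
process is white at the sampling rate of the scanner, the autocorrelation of
the observed signal is exactly the autocorrelation of the HRF itself,

    E[y(t1) y(t2)] = sum_tau h(tau) h(tau - (t1 - t2)).

That autocorrelation sequence, evaluated at multiples of the repetition time
(TR) and assembled into a Toeplitz matrix, is the prior covariance ``K_A``
placed on every mode time course.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, toeplitz
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "HRFKernel",
    "TemporalPrior",
    "canonical_hrf",
    "hrf_autocovariance",
    "build_temporal_prior",
]

#: Widely used double-gamma parameters (seconds): response peak at ~5 s,
#: undershoot peaking at ~15 s, undershoot 1/6 the height of the response.
DEFAULT_HRF_PARAMS = {
    "peak_delay": 6.0,
    "undershoot_delay": 16.0,
    "peak_dispersion": 1.0,
    "undershoot_dispersion": 1.0,
    "undershoot_ratio": 1.0 / 6.0,
}

#: Default kernel length in seconds.
DEFAULT_HRF_DURATION = 32.0


@dataclass(frozen=True)
class HRFKernel:
    """A sampled HRF: amplitudes at spacing ``dt`` covering ``duration`` seconds."""

    samples: np.ndarray
    dt: float
    duration: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("HRF kernel must be a 1-D vector of length >= 2")
        if not np.all(np.isfinite(samples)):
            raise ValueError("HRF kernel contains non-finite values")
        if samples.max() <= 0:
            raise ValueError("HRF kernel maximum must be strictly positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class TemporalPrior:
    """Unit-diagonal Toeplitz prior covariance over the T time points of a run.

    ``inverse`` and ``logdet`` are cached at construction; they are consumed on
    every time-course and temporal-precision update.
    """

    covariance: np.ndarray
    tr: float
    T: int
    inverse: np.ndarray = field(repr=False, default=None)
    logdet: float = None

    def __post_init__(self) -> None:
        K = np.asarray(self.covariance, dtype=float)
        if K.shape != (self.T, self.T):
            raise ValueError("covariance shape does not match T")
        if not np.allclose(K, K.T):
            raise ValueError("temporal prior covariance must be symmetric")
        if self.inverse is None:
            c, low = cho_factor(K)
            inv = cho_solve((c, low), np.eye(self.T))
            object.__setattr__(self, "inverse", (inv + inv.T) / 2.0)
            object.__setattr__(self, "logdet", 2.0 * np.log(np.diag(c)).sum())


def canonical_hrf(
    dt: float,
    duration: float = DEFAULT_HRF_DURATION,
    *,
    peak_delay: float = DEFAULT_HRF_PARAMS["peak_delay"],
    undershoot_delay: float = DEFAULT_HRF_PARAMS["undershoot_delay"],
    peak_dispersion: float = DEFAULT_HRF_PARAMS["peak_dispersion"],
    undershoot_dispersion: float = DEFAULT_HRF_PARAMS["undershoot_dispersion"],
    undershoot_ratio: float = DEFAULT_HRF_PARAMS["undershoot_ratio"],
) -> HRFKernel:
    """Sample the canonical double-gamma HRF at spacing ``dt``.

    The kernel is the difference of two gamma densities (response minus
    scaled undershoot), evaluated at ``k * dt`` for
    ``k = 0 .. round(duration/dt) - 1`` and rescaled to unit peak.
    """
    if dt <= 0 or duration <= 0:
        raise ValueError("dt and duration must be positive")
    n = int(round(duration / dt))
    if n < 2:
        raise ValueError("duration must cover at least two samples")
    t = np.arange(n) * dt
    peak = _gamma_dist.pdf(t, peak_delay / peak_dispersion, scale=peak_dispersion)
    under = _gamma_dist.pdf(
        t, undershoot_delay / undershoot_dispersion, scale=undershoot_dispersion
    )
    h = peak - undershoot_ratio * under
    h = h / h.max()
    return HRFKernel(samples=h, dt=dt, duration=duration)


def hrf_autocovariance(h: HRFKernel, max_lag: int) -> np.ndarray:
    """Autocovariance of the HRF kernel at lags ``0 .. max_lag``.

    Element ``d`` is ``sum_tau h(tau) h(tau - d)`` — the autocorrelation a
    white neural process acquires after convolution with ``h``.
    """
    samples = h.samples
    if not 0 <= max_lag < samples.size:
        raise ValueError(
            f"max_lag must be in [0, {samples.size - 1}], got {max_lag}"
        )
    full = np.correlate(samples, samples, mode="full")
    centre = samples.size - 1
    return full[centre : centre + max_lag + 1].copy()


def build_temporal_prior(
    T: int, tr: float, *, hrf: HRFKernel | None = None, ridge_scale: float = 1e-6
) -> TemporalPrior:
    """Build the T x T temporal prior covariance ``K_A`` for a run.

    The HRF autocovariance at multiples of ``tr`` fills a Toeplitz matrix,
    rescaled to unit diagonal so that the precision scalar placed on top is
    interpretable as the marginal time-course precision.  Lags beyond the
    kernel length are exactly zero.  A ridge of ``ridge_scale`` times the
    largest eigenvalue is added until the matrix is positive definite.
    """
    if T < 2:
        raise ValueError("T must be at least 2")
    if tr <= 0:
        raise ValueError("tr must be positive")
    if hrf is None:
        hrf = canonical_hrf(tr, DEFAULT_HRF_DURATION)
    max_lag = min(T - 1, len(hrf) - 1)
    ac = hrf_autocovariance(hrf, max_lag)
    row = np.zeros(T)
    row[: max_lag + 1] = ac / ac[0]
    K = toeplitz(row)
    evals = np.linalg.eigvalsh(K)
    eps = ridge_scale * evals.max()
    shift = 0.0
    while evals.min() + shift < eps:
        K += eps * np.eye(T)
        shift += eps
    if shift > 0:
        K /= K[0, 0]  # restore the exact unit diagonal; still PD
    return TemporalPrior(covariance=K, tr=tr, T=T)
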