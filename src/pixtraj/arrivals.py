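"""Poisson photon-detection process over an exposure interval.

Photon detection times on the detector plane form a Poisson process with a
non-negative, piecewise-continuous intensity ``Lambda(tau)`` (photons/s) on
the exposure interval ``[t0, t]``.  Conditional on exactly ``L`` detections,
the ordered arrival times are the order statistics of ``L`` i.i.d. draws from
the normalized intensity, with joint density

    p(tau_1, ..., tau_L | L) = L! * prod_l Lambda(tau_l) / Lambda_bar^L

on the ordered simplex, where ``Lambda_bar = int_{t0}^t Lambda``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.special import gammaln

__all__ = ["ArrivalProcess"]

_GRID_N = 4096  # resolution of the numeric inverse CDF for callable rates


@dataclass(frozen=True)
class ArrivalProcess:
    """Photon arrival process on ``[t0, t]``.

    ``rate`` may be a non-negative constant (photons/s), a pair
    ``(edges, values)`` describing a piecewise-constant intensity, or any
    callable ``Lambda(tau)``.
    """

    t0: float
    t: float
    rate: object = 1.0

    def __post_init__(self):
        if not self.t > self.t0:
            raise ValueError("exposure interval must satisfy t > t0")
        if np.isscalar(self.rate) and float(self.rate) < 0:
            raise ValueError("intensity must be non-negative")

    # -- intensity ----------------------------------------------------------

    @property
    def _is_constant(self) -> bool:
        return (not callable(self.rate)
                and not isinstance(self.rate, (tuple, list))
                and np.ndim(self.rate) == 0)

    def intensity(self, tau) -> np.ndarray:
        tau = np.asarray(tau, dtype=float)
        if callable(self.rate):
            return np.asarray(self.rate(tau), dtype=float)
        if self._is_constant:
            return np.full(tau.shape, float(self.rate))
        edges, values = self.rate
        idx = np.clip(np.searchsorted(edges, tau, side="right") - 1, 0,
                      len(values) - 1)
        return np.asarray(values, dtype=float)[idx]

    @property
    def total_intensity(self) -> float:
        """``Lambda_bar = int_{t0}^{t} Lambda(psi) dpsi`` (expected photons)."""
        if callable(self.rate):
            val, _ = quad(self.rate, self.t0, self.t)
            return val
        if self._is_constant:
            return float(self.rate) * (self.t - self.t0)
        edges, values = (np.asarray(a, dtype=float) for a in self.rate)
        lo = np.clip(edges[:-1], self.t0, self.t)
        hi = np.clip(edges[1:], self.t0, self.t)
        return float(np.sum(values[: len(lo)] * np.maximum(hi - lo, 0.0)))

    # -- counts -------------------------------------------------------------

    def log_p_L(self, L: int) -> float:
        """Log Poisson probability of detecting exactly L photons."""
        if L < 0 or L != int(L):
            raise ValueError("L must be a non-negative integer")
        mu = self.total_intensity
        if mu == 0.0:
            return 0.0 if L == 0 else -np.inf
        return float(L * np.log(mu) - mu - gammaln(L + 1))

    def p_L(self, L: int) -> float:
        return float(np.exp(self.log_p_L(L)))

    def sample_count(self, rng: np.random.Generator) -> int:
        return int(rng.poisson(self.total_intensity))

    # -- conditional arrival times -----------------------------------------

    def _inverse_cdf(self, u: np.ndarray) -> np.ndarray:
        if self._is_constant:
            return self.t0 + u * (self.t - self.t0)
        grid = np.linspace(self.t0, self.t, _GRID_N)
        lam = np.clip(self.intensity(grid), 0.0, None)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (lam[1:] + lam[:-1])
                                               * np.diff(grid))])
        cdf /= cdf[-1]
        return np.interp(u, cdf, grid)

    def sample_times_conditional(self, L: int, rng: np.random.Generator
                                 ) -> np.ndarray:
        """Ordered arrival times given exactly ``L`` photons in ``[t0, t]``.

        Uses the order-statistics representation: L i.i.d. draws from the
        normalized intensity, sorted.
        """
        if L < 0:
            raise ValueError("L must be non-negative")
        if L == 0:
            return np.empty(0)
        u = rng.uniform(size=L)
        return np.sort(self._inverse_cdf(u))

    def log_time_density(self, times) -> float:
        """Log of the conditional joint arrival-time density on the simplex."""
        times = np.asarray(times, dtype=float)
        L = len(times)
        if L == 0:
            return 0.0
        if np.any(times < self.t0) or np.any(times > self.t):
            raise ValueError("times outside the exposure interval")
        if np.any(np.diff(times) < 0):
            raise ValueError("times must be ordered (support is the simplex)")
        mu = self.total_intensity
        lam = self.intensity(times)
        if np.any(lam <= 0):
            return -np.inf
        return float(gammaln(L + 1) + np.sum(np.log(lam)) - L * np.log(mu))
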