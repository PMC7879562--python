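"""Linear SDE motion models for single-molecule trajectories.

The molecule position ``X(t)`` in the object space follows the linear vector
stochastic differential equation

    dX(t) = (V + F X(t)) dt + G dB(t),

with first-order drift matrix ``F`` (1/s), zero-order drift ``V`` (um/s),
diffusion matrix ``G`` (um/sqrt(s), convention ``G = sqrt(2 D) I`` for a scalar
diffusion coefficient ``D`` in um^2/s) and a standard vector Brownian motion
``B``.  The exact discrete-time solution at times ``t_l < t_{l+1}`` is the
Gauss-Markov recursion

    X(t_{l+1}) = phi(dt) X(t_l) + a(dt) + w,   w ~ N(0, Q(dt)),

where ``phi(dt) = expm(F dt)``, ``a(dt) = (int_0^dt expm(F s) ds) V`` and
``Q(dt) = int_0^dt expm(F s) G G^T expm(F^T s) ds``.

Only time-invariant coefficient matrices are supported.  Units are um and
seconds throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad_vec
from scipy.linalg import expm

__all__ = [
    "MotionModel",
    "Trajectory",
    "DegenerateDensityError",
]

_COND_LIMIT = 1e8  # condition-number guard for the F^{-1} closed-form path


class DegenerateDensityError(ValueError):
    """Transition covariance is singular; the transition density does not exist."""


@dataclass(frozen=True)
class Trajectory:
    """Positions of a molecule at strictly increasing time points."""

    times: np.ndarray  # (L,) seconds
    positions: np.ndarray  # (L, d) um

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if times.ndim != 1 or len(times) != pos.shape[0]:
            raise ValueError("times and positions must have matching length")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", pos)

    def to_frame(self) -> pd.DataFrame:
        cols = ["x_um", "y_um", "z_um"][: self.positions.shape[1]]
        df = pd.DataFrame(self.positions, columns=cols)
        df.insert(0, "time_s", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _as_matrix(value, d: int, cols: int | None = None) -> np.ndarray:
    cols = d if cols is None else cols
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        out = np.eye(d, cols) * float(arr)
    else:
        out = np.atleast_2d(arr)
    if out.shape != (d, cols):
        raise ValueError(f"expected shape {(d, cols)}, got {out.shape}")
    return out


@dataclass(frozen=True)
class MotionModel:
    """Time-invariant linear SDE specification.

    Parameters
    ----------
    dim :
        Spatial dimension d (1, 2 or 3).
    F :
        d x d first-order drift matrix (1/s); scalars mean ``f * I``.
    G :
        d x r diffusion matrix (um/sqrt(s)); scalars mean ``g * I``.
    V :
        Zero-order drift vector (um/s).
    x0 :
        Fixed initial position (um), used when ``init_cov`` is None.
    init_mean, init_cov :
        Optional Gaussian initial law.  When ``init_cov`` is given it takes
        precedence over the fixed ``x0``.
    H :
        Observation matrix mapping state to position (identity by default).
    """

    dim: int = 2
    F: np.ndarray = 0.0
    G: np.ndarray = 0.0
    V: np.ndarray = 0.0
    x0: np.ndarray | None = None
    init_mean: np.ndarray | None = None
    init_cov: np.ndarray | None = None
    H: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        d = int(self.dim)
        if d not in (1, 2, 3):
            raise ValueError("dim must be 1, 2 or 3")
        F = _as_matrix(self.F, d)
        G = np.asarray(self.G, dtype=float)
        if G.ndim == 0:
            G = float(G) * np.eye(d)
        G = np.atleast_2d(G)
        if G.shape[0] != d:
            raise ValueError("G must have d rows")
        V = np.broadcast_to(np.asarray(self.V, dtype=float).ravel(), (d,)).copy() \
            if np.ndim(self.V) else np.full(d, float(self.V))
        H = np.eye(d) if self.H is None else _as_matrix(self.H, d)
        x0 = None if self.x0 is None else np.broadcast_to(
            np.asarray(self.x0, dtype=float).ravel(), (d,)).copy()
        init_mean = None if self.init_mean is None else np.asarray(
            self.init_mean, dtype=float).ravel()
        init_cov = None if self.init_cov is None else _as_matrix(self.init_cov, d)
        if x0 is None and init_cov is None:
            x0 = np.zeros(d)
        object.__setattr__(self, "dim", d)
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "G", G)
        object.__setattr__(self, "V", V)
        object.__setattr__(self, "H", H)
        object.__setattr__(self, "x0", x0)
        object.__setattr__(self, "init_mean", init_mean)
        object.__setattr__(self, "init_cov", init_cov)

    # -- convenience constructors ------------------------------------------

    @classmethod
    def ou(cls, f: float = -10.0, D: float = 1.0, dim: int = 2,
           V=0.0, x0=0.0) -> "MotionModel":
        """Ornstein-Uhlenbeck model: ``F = f I``, ``G = sqrt(2 D) I``."""
        return cls(dim=dim, F=f, G=np.sqrt(2.0 * D), V=V, x0=x0)

    @classmethod
    def stationary(cls, x0, dim: int | None = None) -> "MotionModel":
        x0 = np.atleast_1d(np.asarray(x0, dtype=float))
        return cls(dim=dim or len(x0), F=0.0, G=0.0, V=0.0, x0=x0)

    # -- structure queries --------------------------------------------------

    @property
    def diffusion_cov_rate(self) -> np.ndarray:
        """``G G^T`` (um^2/s); equals ``2 D I`` for scalar diffusion."""
        return self.G @ self.G.T

    @property
    def is_deterministic(self) -> bool:
        return not np.any(self.diffusion_cov_rate) and self.init_cov is None

    @property
    def is_stationary(self) -> bool:
        """Molecule never moves and starts at a fixed point."""
        return (self.is_deterministic and not np.any(self.F)
                and not np.any(self.V))

    def _scalar_f(self) -> float | None:
        """If ``F = f I``, return f, else None."""
        f = self.F[0, 0]
        if np.allclose(self.F, f * np.eye(self.dim), atol=0.0):
            return float(f)
        return None

    # -- discrete-time solution --------------------------------------------

    def state_transition(self, dt: float) -> np.ndarray:
        """State transition matrix ``phi(dt) = expm(F dt)``."""
        if dt < 0:
            raise ValueError("dt must be non-negative")
        f = self._scalar_f()
        if f is not None:
            return np.exp(f * dt) * np.eye(self.dim)
        return expm(self.F * dt)

    def drift_increment(self, dt: float) -> np.ndarray:
        """Deterministic displacement ``a(dt) = (int_0^dt expm(F s) ds) V``."""
        if dt < 0:
            raise ValueError("dt must be non-negative")
        if not np.any(self.V) or dt == 0:
            return np.zeros(self.dim)
        f = self._scalar_f()
        if f == 0.0:
            return dt * self.V
        if f is not None:
            return ((np.exp(f * dt) - 1.0) / f) * self.V
        if np.linalg.cond(self.F) < _COND_LIMIT:
            return np.linalg.solve(self.F, (self.state_transition(dt) - np.eye(self.dim)) @ self.V)
        integral, _ = quad_vec(lambda s: expm(self.F * s), 0.0, dt, epsabs=1e-12)
        return integral @ self.V

    def process_noise_cov(self, dt: float) -> np.ndarray:
        """Covariance ``Q(dt)`` of the Gaussian increment over ``dt``."""
        if dt < 0:
            raise ValueError("dt must be non-negative")
        S = self.diffusion_cov_rate
        if dt == 0 or not np.any(S):
            return np.zeros((self.dim, self.dim))
        f = self._scalar_f()
        if f == 0.0:
            return S * dt
        if f is not None and np.allclose(S, S[0, 0] * np.eye(self.dim)):
            return S * ((np.exp(2.0 * f * dt) - 1.0) / (2.0 * f))
        # non-commuting case: quadrature of the defining integral
        integral, _ = quad_vec(
            lambda s: expm(self.F * s) @ S @ expm(self.F * s).T, 0.0, dt,
            epsabs=1e-12)
        return 0.5 * (integral + integral.T)

    # -- sampling and densities --------------------------------------------

    def sample_initial(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        if self.init_cov is not None:
            mean = self.init_mean if self.init_mean is not None else np.zeros(self.dim)
            return rng.multivariate_normal(mean, self.init_cov, size=size)
        return np.broadcast_to(self.x0, (size, self.dim)).copy()

    def sample_trajectory(self, times, rng: np.random.Generator,
                          t0: float | None = None) -> Trajectory:
        """Sample one path at the given strictly increasing time points.

        The initial law applies at ``t0`` (default: the first time point),
        then the exact Gauss-Markov recursion is iterated.
        """
        times = np.asarray(times, dtype=float)
        if times.ndim != 1 or len(times) == 0:
            raise ValueError("times must be a non-empty 1D sequence")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        t_prev = times[0] if t0 is None else float(t0)
        if times[0] < t_prev:
            raise ValueError("first time point precedes t0")
        x = self.sample_initial(rng, size=1)[0]
        out = np.empty((len(times), self.dim))
        for l, t in enumerate(times):
            dt = t - t_prev
            if dt > 0:
                phi = self.state_transition(dt)
                a = self.drift_increment(dt)
                Q = self.process_noise_cov(dt)
                w = _sample_gaussian(Q, rng) if np.any(Q) else 0.0
                x = phi @ x + a + w
            out[l] = x
            t_prev = t
        return Trajectory(times=times, positions=out @ self.H.T)

    def transition_density(self, x_next, x_prev, dt: float) -> float:
        """Gaussian transition density value (um^-d)."""
        Q = self.process_noise_cov(dt)
        if dt == 0 or np.linalg.matrix_rank(Q) < self.dim:
            raise DegenerateDensityError(
                "transition covariance is singular; density is degenerate")
        mean = self.state_transition(dt) @ np.asarray(x_prev, dtype=float) \
            + self.drift_increment(dt)
        diff = np.asarray(x_next, dtype=float) - mean
        sign, logdet = np.linalg.slogdet(Q)
        quad = diff @ np.linalg.solve(Q, diff)
        return float(np.exp(-0.5 * (quad + logdet + self.dim * np.log(2 * np.pi))))


def _sample_gaussian(Q: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    try:
        chol = np.linalg.cholesky(Q)
    except np.linalg.LinAlgError:
        # PSD but rank-deficient: use eigendecomposition
        w, U = np.linalg.eigh(Q)
        chol = U @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    return chol @ rng.standard_normal(Q.shape[0])
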