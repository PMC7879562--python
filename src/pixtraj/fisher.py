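"""Fisher information matrices and Cramér-Rao lower bounds.

The Fisher information matrix (FIM) of a data model with log-likelihood
``l(theta)`` is ``I(theta) = E[ (dl/dtheta)^T (dl/dtheta) ]``; the CRLB says
any unbiased estimator has covariance at least ``I(theta)^{-1}``, and the
square root of the inverse-FIM diagonal is the best achievable per-parameter
standard deviation (the *localization accuracy* for position parameters).

Three data models are covered, with an information ordering (pixelation and
camera noise can only lose information):

* fundamental (exact impact points)  --  :func:`fim_fundamental_conditional`
  and the Poisson-averaged :func:`fim_fundamental_total`;
* practical (pixel counts)  --  :func:`fim_practical`;
* noisy practical (intensities)  --  :func:`fim_practical_noisy`.

For a stationary emitter the practical FIM has the multinomial closed form

    I = L * sum_k (dp_k/dtheta)^T (dp_k/dtheta) / p_k,

with ``p_k`` the pixel-hit probabilities; this is the production path for
localization accuracy.  Moving molecules use the score-based Monte Carlo
estimator: simulate images at theta, form scores by central finite
differences of the (common-random-number) log-likelihood, and average the
outer products.  The literal definition-form sum over count vectors is kept
as an exact oracle for tiny systems (:func:`fim_practical_exact_small`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .inference import ParameterSpec
from .likelihood import (MCConfig, ModelBundle, loglik_fundamental_mc,
                         loglik_noisy, loglik_practical_infinite,
                         stationary_practical_closed_form)
from .optics import Gaussian2D

__all__ = [
    "FIMResult",
    "crlb",
    "fim_fundamental_conditional",
    "fim_fundamental_total",
    "fim_practical",
    "fim_practical_noisy",
    "fim_practical_exact_small",
]

_FD_STEP = 1e-3  # central-difference step in transformed parameter units


@dataclass
class FIMResult:
    """Fisher information matrix with per-parameter CRLB diagnostics."""

    matrix: np.ndarray
    names: tuple[str, ...]
    method: str
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        self.matrix = 0.5 * (m + m.T)

    @property
    def crlb_sd(self) -> np.ndarray:
        """sqrt of the inverse-FIM diagonal; inf along null directions."""
        return crlb(self)

    @property
    def condition_number(self) -> float:
        try:
            return float(np.linalg.cond(self.matrix))
        except np.linalg.LinAlgError:
            return np.inf


def crlb(fim: FIMResult | np.ndarray) -> np.ndarray:
    """Per-parameter lower-bound standard deviations from a FIM."""
    m = fim.matrix if isinstance(fim, FIMResult) else np.asarray(fim, float)
    n = m.shape[0]
    try:
        inv = np.linalg.inv(m)
        diag = np.diag(inv)
        if np.any(diag < 0):
            raise np.linalg.LinAlgError
        return np.sqrt(diag)
    except np.linalg.LinAlgError:
        # singular: invert on the range, infinite bound on the null space
        w, U = np.linalg.eigh(m)
        tol = max(m.shape[0] * np.max(np.abs(w)) * 1e-12, 1e-300)
        out = np.empty(n)
        for j in range(n):
            null_weight = np.sum(U[j, w < tol] ** 2)
            if null_weight > 1e-12:
                out[j] = np.inf
            else:
                inv_diag = np.sum(U[j, w >= tol] ** 2 / w[w >= tol])
                out[j] = np.sqrt(inv_diag)
        return out


# ---------------------------------------------------------------------------
# fundamental data model
# ---------------------------------------------------------------------------

def _is_location_only(spec: ParameterSpec) -> bool:
    return set(spec.names) <= {"x0", "y0"}


def fim_fundamental_conditional(bundle: ModelBundle, spec: ParameterSpec,
                                L: int, method: str = "auto",
                                mc: MCConfig | None = None,
                                n_datasets: int = 2000,
                                fd_step: float = _FD_STEP) -> FIMResult:
    """FIM of exact impact locations given exactly ``L`` detected photons.

    Methods: ``closed_form`` (stationary emitter, Gaussian optics, location
    parameters: ``I = (L / sigma^2) I``), ``quadrature`` (stationary
    emitter, any image function: per-photon information by 2D quadrature,
    multiplied by L since impacts are then i.i.d.), or ``mc_score``
    (simulate impact sets, average outer products of finite-difference
    scores).
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    model = bundle.motion
    if method == "auto":
        if model.is_stationary and _is_location_only(spec):
            method = "closed_form" \
                if isinstance(bundle.optics.image_function, Gaussian2D) \
                else "quadrature"
        else:
            method = "mc_score"
    if method == "closed_form":
        if not (model.is_stationary and _is_location_only(spec)
                and isinstance(bundle.optics.image_function, Gaussian2D)):
            raise ValueError("closed form needs a stationary emitter, "
                             "Gaussian optics and location parameters")
        sigma = bundle.optics.image_function.sigma
        return FIMResult(matrix=(L / sigma ** 2) * np.eye(spec.n),
                         names=spec.names, method="closed_form")
    if method == "quadrature":
        if not model.is_stationary:
            raise ValueError("quadrature path requires a stationary emitter")
        unit = _fundamental_unit_fim_quadrature(bundle, spec, fd_step)
        return FIMResult(matrix=L * unit, names=spec.names,
                         method="quadrature")
    if method != "mc_score":
        raise ValueError(f"unknown method {method!r}")
    mc = mc or MCConfig(n_temporal=20, n_spatial=200)
    return _fim_mc_score(
        bundle, spec, mc, n_datasets, fd_step,
        simulate=lambda b, rng: _simulate_impacts(b, L, rng),
        loglik=lambda b, data, m: loglik_fundamental_mc(b, data, m),
        method_tag="mc_score")


def _fundamental_unit_fim_quadrature(bundle, spec, fd_step):
    """Per-photon FIM of the impact-location density, by tensor quadrature."""
    from .optics import _gl_grid, Rect

    optics = bundle.optics
    x0 = bundle.motion.x0[:2]
    img_center = optics.M @ x0
    diag = optics._diag_scales or (1.0, 1.0)
    # quadrature box: +/- 10 image-space widths around the image of x0
    q = optics.image_function
    if isinstance(q, Gaussian2D):
        half = 10.0 * q.sigma
    else:
        half = 40.0 / q.alpha
    box = Rect(img_center[0] - half * abs(diag[0]),
               img_center[0] + half * abs(diag[0]),
               img_center[1] - half * abs(diag[1]),
               img_center[1] + half * abs(diag[1]))
    pts, wts = _gl_grid(box, 96)
    theta0 = spec.pack({n: {"x0": x0[0], "y0": x0[1]}[n] for n in spec.names})

    def dens(theta):
        motion = spec.build_motion(bundle.motion, theta)
        return optics.image_profile(motion.x0[:2], pts)

    p = dens(theta0)
    grads = np.empty((spec.n, len(pts)))
    for j in range(spec.n):
        e = np.zeros(spec.n)
        e[j] = fd_step
        grads[j] = (dens(theta0 + e) - dens(theta0 - e)) / (2 * fd_step)
    mask = p > 1e-300
    weighted = grads[:, mask] / p[mask]
    return (weighted * wts[mask]) @ grads[:, mask].T


def _simulate_impacts(bundle: ModelBundle, L: int, rng: np.random.Generator
                      ) -> np.ndarray:
    times = bundle.arrivals.sample_times_conditional(L, rng)
    traj = bundle.motion.sample_trajectory(times, rng, t0=bundle.arrivals.t0)
    return bundle.optics.sample_impact(traj.positions[:, :2], rng)


def fim_fundamental_total(bundle: ModelBundle, spec: ParameterSpec,
                          L_max: int | None = None, tail: float = 1e-10,
                          **kwargs) -> FIMResult:
    """Poisson-averaged fundamental FIM ``sum_L p_L I_{N=L}``."""
    mu = bundle.arrivals.total_intensity
    if L_max is None:
        L_max = int(np.ceil(mu + 12.0 * np.sqrt(mu) + 25.0))
    total = np.zeros((spec.n, spec.n))
    for L in range(1, L_max + 1):
        pL = bundle.arrivals.p_L(L)
        if L > mu and pL < tail:
            break
        total += pL * fim_fundamental_conditional(bundle, spec, L,
                                                  **kwargs).matrix
    return FIMResult(matrix=total, names=spec.names, method="poisson_mixture",
                     diagnostics={"L_max": L})


# ---------------------------------------------------------------------------
# practical data model
# ---------------------------------------------------------------------------

def _pixel_probs_and_grads(bundle: ModelBundle, spec: ParameterSpec,
                           fd_step: float):
    """Stationary pixel probabilities p_k and dp_k/dtheta over all pixels
    plus the complement cell.  Analytic error-function derivatives for
    Gaussian optics with diagonal magnification, finite differences
    otherwise.  Pixels with negligible mass are dropped."""
    optics, grid = bundle.optics, bundle.grid
    x0 = bundle.motion.x0[:2]
    q = optics.image_function
    diag = optics._diag_scales
    centers = grid.centers()
    # preselect pixels within a generous radius of the image of the emitter
    img_center = optics.M @ x0
    if isinstance(q, Gaussian2D) and diag is not None:
        radius = 10.0 * q.sigma * max(abs(diag[0]), abs(diag[1]))
    else:
        radius = 200.0 / q.alpha * (max(np.abs(np.diag(optics.M)))
                                    if diag else 1.0)
    half_diag = 0.5 * np.hypot(grid.pixel_width, grid.pixel_height)
    near = np.flatnonzero(np.hypot(*(centers - img_center).T)
                          <= radius + half_diag)

    if isinstance(q, Gaussian2D) and diag is not None \
            and _is_location_only(spec):
        sigma = q.sigma
        sx, sy = diag

        def phi(v):
            return np.exp(-0.5 * (v / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))

        # object-space pixel edges relative to the emitter, vectorized
        c = centers[near]
        xlo = (c[:, 0] - grid.pixel_width / 2) / sx - x0[0]
        xhi = (c[:, 0] + grid.pixel_width / 2) / sx - x0[0]
        ylo = (c[:, 1] - grid.pixel_height / 2) / sy - x0[1]
        yhi = (c[:, 1] + grid.pixel_height / 2) / sy - x0[1]
        if sx < 0:
            xlo, xhi = xhi, xlo
        if sy < 0:
            ylo, yhi = yhi, ylo
        s2 = sigma * np.sqrt(2)
        ix = 0.5 * (_erf(xhi / s2) - _erf(xlo / s2))
        iy = 0.5 * (_erf(yhi / s2) - _erf(ylo / s2))
        dix = phi(xlo) - phi(xhi)
        diy = phi(ylo) - phi(yhi)
        p = ix * iy
        grad = {"x0": dix * iy, "y0": ix * diy}
        grads = np.stack([grad[n] for n in spec.names], axis=-1)
    else:
        theta0 = _theta_at_truth(bundle, spec)

        def probs(theta):
            motion = spec.build_motion(bundle.motion, theta)
            xq = motion.x0[:2]
            return np.array([optics.pixel_integral(xq, grid.pixel_rect(k + 1))
                             for k in near], dtype=float)

        p = probs(theta0)
        grads = np.zeros((len(near), spec.n))
        for j in range(spec.n):
            e = np.zeros(spec.n)
            e[j] = fd_step
            grads[:, j] = (probs(theta0 + e) - probs(theta0 - e)) / (2 * fd_step)
    # complement cell: the rest of the plane
    p_comp = max(1.0 - float(p.sum()), 0.0)
    p = np.append(p, p_comp)
    grads = np.vstack([grads, -grads.sum(axis=0)])
    keep = p > 1e-14
    return p[keep], grads[keep]


def _erf(v):
    from scipy.special import erf
    return erf(v)


def _theta_at_truth(bundle: ModelBundle, spec: ParameterSpec) -> np.ndarray:
    model = bundle.motion
    x0 = model.x0 if model.x0 is not None else np.zeros(model.dim)
    S = model.diffusion_cov_rate
    vals = {"x0": x0[0], "y0": x0[1] if model.dim > 1 else 0.0,
            "D": max(S[0, 0] / 2.0, 1e-12), "F": model.F[0, 0],
            "Vx": model.V[0], "Vy": model.V[1] if model.dim > 1 else 0.0}
    return spec.pack({n: vals[n] for n in spec.names})


def fim_practical(bundle: ModelBundle, spec: ParameterSpec,
                  L: int | None = None, method: str = "auto",
                  mc: MCConfig | None = None, n_images: int = 2000,
                  fd_step: float = _FD_STEP) -> FIMResult:
    """FIM of the pixel-count (infinite practical) data model.

    ``L`` conditions on exactly L detected photons; ``L=None`` averages over
    the Poisson photon-number distribution.  Stationary emitters use the
    multinomial closed form ``L * sum_k (dp_k)^T (dp_k) / p_k`` (the Poisson
    average replaces L with the mean photon number); moving molecules use
    the score-based Monte Carlo estimator.
    """
    model = bundle.motion
    if method == "auto":
        method = "closed_form" if model.is_stationary else "mc_score"
    if method == "closed_form":
        if not model.is_stationary:
            raise ValueError("closed form requires a stationary emitter")
        p, grads = _pixel_probs_and_grads(bundle, spec, fd_step)
        unit = (grads / p[:, None]).T @ grads
        n_eff = float(L) if L is not None else bundle.arrivals.total_intensity
        return FIMResult(matrix=n_eff * unit, names=spec.names,
                         method="closed_form",
                         diagnostics={"n_cells": len(p),
                                      "coverage": float(p[:-1].sum())})
    if method != "mc_score":
        raise ValueError(f"unknown method {method!r}")
    mc = mc or MCConfig(n_temporal=20, n_spatial=200)

    def simulate(b, rng):
        from .experiment import simulate_image
        img, _ = simulate_image(b, rng, n_photons=L)
        return img

    return _fim_mc_score(bundle, spec, mc, n_images, fd_step,
                         simulate=simulate,
                         loglik=_practical_loglik_dispatch,
                         method_tag="mc_score")


def _practical_loglik_dispatch(b: ModelBundle, image, m: MCConfig) -> float:
    if b.motion.is_stationary:
        return stationary_practical_closed_form(b, image)
    return loglik_practical_infinite(b, image, m)


def fim_practical_noisy(bundle: ModelBundle, spec: ParameterSpec,
                        L: int | None = None, mc: MCConfig | None = None,
                        n_images: int = 400,
                        fd_step: float = _FD_STEP) -> FIMResult:
    """FIM of the noisy practical model, by the score-based MC estimator."""
    if bundle.noise is None:
        raise ValueError("noisy FIM requires a noise model")
    mc = mc or MCConfig(n_temporal=10, n_spatial=100)

    def simulate(b, rng):
        from .experiment import simulate_image
        img, _ = simulate_image(b, rng, n_photons=L)
        return b.noise.apply(img, rng)

    def loglik(b, image, m):
        return loglik_noisy(b, image, m)

    return _fim_mc_score(bundle, spec, mc, n_images, fd_step,
                         simulate=simulate, loglik=loglik,
                         method_tag="mc_score_noisy")


def fim_noisy_single_pixel(bundle: ModelBundle, spec: ParameterSpec,
                           fd_step: float = _FD_STEP,
                           z_max: int | None = None) -> FIMResult:
    """Noisy-model FIM for a single pixel, by direct 1D integration.

    ``I = int (sum_z p(i|z) dPr_z/dtheta)^T (same) / (sum_z p(i|z) Pr_z) di``
    for a stationary emitter, with the count distribution differentiated by
    central finite differences.
    """
    if bundle.grid.K != 1:
        raise ValueError("single-pixel path requires K = 1")
    if bundle.noise is None:
        raise ValueError("requires a noise model")
    mu = bundle.arrivals.total_intensity
    z_max = z_max or int(np.ceil(mu + 10 * np.sqrt(mu) + 15))
    theta0 = _theta_at_truth(bundle, spec)
    noise = bundle.noise

    def count_probs(theta):
        motion = spec.build_motion(bundle.motion, theta)
        b = bundle.with_motion(motion)
        return np.array([np.exp(stationary_practical_closed_form(b, [z]))
                         for z in range(z_max + 1)])

    pr = count_probs(theta0)
    dpr = np.zeros((z_max + 1, spec.n))
    for j in range(spec.n):
        e = np.zeros(spec.n)
        e[j] = fd_step
        dpr[:, j] = (count_probs(theta0 + e) - count_probs(theta0 - e)) \
            / (2 * fd_step)
    zs = np.arange(z_max + 1)

    def integrand(i, a, b2):
        pi_z = np.exp(noise.log_conditional_density(i, zs))
        denom = float(pi_z @ pr)
        if denom <= 0:
            return 0.0
        return float((pi_z @ dpr[:, a]) * (pi_z @ dpr[:, b2]) / denom)

    s = float(np.max(np.atleast_1d(noise.sigma_read)))
    eta = float(np.max(np.atleast_1d(noise.eta)))
    lo, hi = -6 * s + eta - 1, z_max + eta + 6 * s + 1
    m = np.zeros((spec.n, spec.n))
    for a in range(spec.n):
        for b2 in range(a, spec.n):
            val, _ = quad(integrand, lo, hi, args=(a, b2), limit=200)
            m[a, b2] = m[b2, a] = val
    return FIMResult(matrix=m, names=spec.names, method="quadrature_1d")


def fim_practical_exact_small(bundle: ModelBundle, spec: ParameterSpec,
                              L: int, K_cells: int | None = None,
                              mc: MCConfig | None = None,
                              fd_step: float = _FD_STEP,
                              conditional: bool = True) -> FIMResult:
    """Definition-form FIM oracle for tiny systems.

    Enumerates every count vector with total ``L`` over the grid's pixels and
    sums ``(dPr/dtheta)^T (dPr/dtheta) / Pr`` with finite-difference
    derivatives of the count likelihood.  Exponential in K and L -- a test
    oracle, not a production path.
    """
    import itertools

    K = K_cells or bundle.grid.K
    if K > 4 or L > 3:
        raise ValueError("exact oracle limited to K <= 4 cells and L <= 3")
    mc = mc or MCConfig(n_temporal=50, n_spatial=2000)
    theta0 = _theta_at_truth(bundle, spec)

    def prob(theta, z):
        motion = spec.build_motion(bundle.motion, theta)
        b = bundle.with_motion(motion)
        ll = _practical_loglik_dispatch(b, np.asarray(z), mc)
        val = np.exp(ll)
        if conditional:
            val /= bundle.arrivals.p_L(int(np.sum(z)))
        return val

    m = np.zeros((spec.n, spec.n))
    for z in itertools.product(range(L + 1), repeat=K):
        if sum(z) != L:
            continue
        pr = prob(theta0, z)
        if pr <= 0:
            continue
        dpr = np.zeros(spec.n)
        for j in range(spec.n):
            e = np.zeros(spec.n)
            e[j] = fd_step
            dpr[j] = (prob(theta0 + e, z) - prob(theta0 - e, z)) / (2 * fd_step)
        m += np.outer(dpr, dpr) / pr
    return FIMResult(matrix=m, names=spec.names, method="exact_enumeration")


# ---------------------------------------------------------------------------
# score-based Monte Carlo estimator (shared machinery)
# ---------------------------------------------------------------------------

def _fim_mc_score(bundle, spec, mc, n_datasets, fd_step, simulate, loglik,
                  method_tag):
    theta0 = _theta_at_truth(bundle, spec)
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=int(mc.seed) % (2 ** 31), spawn_key=(10_007,)))
    shifted = []
    for j in range(spec.n):
        e = np.zeros(spec.n)
        e[j] = fd_step
        shifted.append((bundle.with_motion(spec.build_motion(bundle.motion,
                                                             theta0 + e)),
                        bundle.with_motion(spec.build_motion(bundle.motion,
                                                             theta0 - e))))
    total = np.zeros((spec.n, spec.n))
    scores = np.empty((n_datasets, spec.n))
    for i in range(n_datasets):
        data = simulate(bundle, rng)
        for j, (b_plus, b_minus) in enumerate(shifted):
            lp = loglik(b_plus, data, mc)
            lm = loglik(b_minus, data, mc)
            scores[i, j] = (lp - lm) / (2 * fd_step)
        total += np.outer(scores[i], scores[i])
    fim = total / n_datasets
    se = scores.std(axis=0, ddof=1) / np.sqrt(n_datasets)
    return FIMResult(matrix=fim, names=spec.names, method=method_tag,
                     diagnostics={"n_datasets": n_datasets,
                                  "score_se": se.tolist(),
                                  "fd_step": fd_step})
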