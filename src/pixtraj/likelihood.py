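"""Likelihood functions for photon data from moving single molecules.

Four data models are covered, all sharing the same three stochastic layers
(photon arrival times, molecule trajectory, photon impact optics):

* *fundamental*: exact impact locations and (marginalized) arrival times on
  an unpixelated detector -- :func:`loglik_fundamental_mc`;
* *infinite practical*: per-pixel photon counts on a pixel array assumed to
  tile the whole detector plane -- :func:`loglik_practical_infinite`;
* *(finite) practical*: counts on a finite array, photons may miss the
  detector entirely (complement region) -- :func:`loglik_practical_finite`;
* *noisy practical*: real-valued intensities after Poisson background and
  Gaussian readout noise -- :func:`loglik_noisy`.

The count likelihood of an image ``z`` with ``L = sum z_k`` photons is

    Pr[S = z] = p_L * E[ sum_{v in A(z)} prod_l I_{C_{v_l}}(X(tau_l)) ],

where the expectation runs over the conditional arrival times ``tau_{1:L}``
and the trajectory ``X``, ``A(z)`` is the set of photon-to-pixel label
vectors consistent with ``z``, and ``I_C(x)`` is the probability that a
photon emitted at object position ``x`` lands in pixel ``C``.  The
expectation is approximated by nested Monte Carlo: ``N`` conditional
arrival-time sequences, ``M_c`` trajectories each.  Common random numbers
(a fixed seed stream, independent of the motion parameters) keep the Monte
Carlo likelihood surface smooth for the optimizer.

For a stationary emitter the expectation collapses and the likelihood has a
multinomial (infinite model) or thinned-Poisson product (finite model)
closed form, used automatically as an exact fast path.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammaln, logsumexp

from .arrivals import ArrivalProcess
from .detector import NoiseModel, PixelGrid, PixelatedImage
from .labelsets import count_label_vectors, enumerate_label_vectors
from .motion import MotionModel
from .optics import OpticalMap

__all__ = [
    "MCConfig",
    "ModelBundle",
    "DegenerateDataError",
    "loglik_fundamental_mc",
    "loglik_practical_infinite",
    "loglik_practical_finite",
    "loglik_noisy",
    "stationary_practical_closed_form",
    "stationary_finite_closed_form",
    "likelihood_report",
]


class DegenerateDataError(ValueError):
    """Observed data carry no probability mass under the model."""


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo sizes for likelihood evaluation.

    ``n_temporal`` (N) conditional arrival-time sequences, ``n_spatial``
    (M_c) trajectories per sequence.  ``z_truncation`` bounds the
    missed-photon sum of the finite practical model, terminated early once a
    term falls below ``tail_tol`` relative to the running sum.
    """

    n_temporal: int = 100
    n_spatial: int = 1000
    seed: int = 0
    z_truncation: int = 20
    tail_tol: float = 1e-8
    label_cap: int = 10 ** 6

    def __post_init__(self):
        if self.n_temporal < 1 or self.n_spatial < 1:
            raise ValueError("Monte Carlo sizes must be >= 1")


@dataclass(frozen=True)
class ModelBundle:
    """Everything needed to evaluate a likelihood: motion, optics, arrivals,
    detector geometry and (optionally) the camera noise model."""

    motion: MotionModel
    optics: OpticalMap
    arrivals: ArrivalProcess
    grid: PixelGrid
    noise: NoiseModel | None = None

    def with_motion(self, motion: MotionModel) -> "ModelBundle":
        return replace(self, motion=motion)


# ---------------------------------------------------------------------------
# Monte Carlo path sampling (common random numbers)
# ---------------------------------------------------------------------------

def _rng_for(mc: MCConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(mc.seed) % (2 ** 31),
                               spawn_key=(stream,)))


def sample_paths(bundle: ModelBundle, L: int, mc: MCConfig, stream: int = 0):
    """Draw N arrival-time sequences and M_c trajectories per sequence.

    Returns ``times`` (N, L) and object positions ``X`` (N, M_c, L, d).
    The underlying uniforms/normals depend only on ``(mc.seed, stream)``, so
    repeated calls with different motion parameters share random numbers.
    """
    model = bundle.motion
    proc = bundle.arrivals
    N, Mc, d = mc.n_temporal, mc.n_spatial, model.dim
    rng = _rng_for(mc, stream)
    times = np.sort(proc._inverse_cdf(rng.uniform(size=(N, L))), axis=1)
    normals = rng.standard_normal((N, Mc, L, d))
    if model.init_cov is not None:
        mean = model.init_mean if model.init_mean is not None else np.zeros(d)
        chol0 = np.linalg.cholesky(model.init_cov)
        x = mean + rng.standard_normal((N, Mc, d)) @ chol0.T
    else:
        x = np.broadcast_to(model.x0, (N, Mc, d)).copy()

    X = np.empty((N, Mc, L, d))
    f = model._scalar_f()
    S = model.diffusion_cov_rate
    scalar_S = np.allclose(S, S[0, 0] * np.eye(d), atol=0.0)
    cholS = _psd_cholesky(S)
    prev = np.full(N, proc.t0)
    for l in range(L):
        dt = times[:, l] - prev  # (N,)
        prev = times[:, l]
        if f is not None and scalar_S:
            phi = np.exp(f * dt)  # (N,)
            if np.any(model.V):
                a_scale = np.where(dt > 0,
                                   dt if f == 0.0 else (phi - 1.0) / f, 0.0)
                a = a_scale[:, None] * model.V
            else:
                a = np.zeros((N, d))
            q_scale = dt if f == 0.0 else (np.exp(2.0 * f * dt) - 1.0) / (2.0 * f)
            w = np.sqrt(np.clip(q_scale, 0.0, None))[:, None, None] \
                * (normals[:, :, l] @ cholS.T)
            x = phi[:, None, None] * x + a[:, None, :] + w
        else:
            new = np.empty_like(x)
            for n in range(N):
                phi = model.state_transition(dt[n])
                a = model.drift_increment(dt[n])
                cholQ = _psd_cholesky(model.process_noise_cov(dt[n]))
                new[n] = x[n] @ phi.T + a + normals[n, :, l] @ cholQ.T
            x = new
        X[:, :, l, :] = x
    return times, X @ model.H.T


def _psd_cholesky(S: np.ndarray) -> np.ndarray:
    if not np.any(S):
        return np.zeros_like(S)
    try:
        return np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        w, U = np.linalg.eigh(S)
        return U @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def _pixel_prob_matrix(bundle: ModelBundle, X: np.ndarray,
                       labels: np.ndarray) -> np.ndarray:
    """I_{C_k}(x) for each trajectory point and each pixel label; (..., R)."""
    xy = X[..., :2]
    cols = [bundle.optics.pixel_integral(xy, bundle.grid.pixel_rect(k))
            for k in labels]
    return np.stack(cols, axis=-1)


def _label_sum(P: np.ndarray, z_occ: np.ndarray, cap: int) -> np.ndarray:
    """sum over label vectors v of prod_l P[..., l, v_l]; shape (...)."""
    L = int(np.sum(z_occ))
    idx_l = np.arange(L)
    acc = np.zeros(P.shape[:-2])
    for v in enumerate_label_vectors(z_occ, cap):
        acc += np.prod(P[..., idx_l, np.asarray(v) - 1], axis=-1)
    return acc


# ---------------------------------------------------------------------------
# Fundamental data model
# ---------------------------------------------------------------------------

def loglik_fundamental_mc(bundle: ModelBundle, impacts, mc: MCConfig,
                          full_output: bool = False):
    """Monte Carlo log-likelihood of exact photon impact locations.

    ``impacts`` are the L >= 1 chronologically ordered impact points (um) on
    the unpixelated detector plane; arrival times are marginalized.
    """
    impacts = np.asarray(impacts, dtype=float).reshape(-1, 2)
    L = len(impacts)
    if L < 1:
        raise ValueError("the fundamental model conditions on L >= 1 photons")
    model = bundle.motion
    if model.is_stationary:
        dens = bundle.optics.image_profile(model.x0[:2], impacts)
        val = float(np.sum(np.log(dens)))
        return (val, {"method": "closed_form", "mc_se_log": 0.0}) \
            if full_output else val
    _, X = sample_paths(bundle, L, mc, stream=0)
    dens = bundle.optics.image_profile(X[..., :2], impacts)  # (N, Mc, L)
    prod = np.prod(dens, axis=-1)  # (N, Mc)
    per_n = prod.mean(axis=1)
    like = float(per_n.mean())
    diag = _mc_diag(per_n, like)
    with np.errstate(divide="ignore"):
        val = float(np.log(like)) if like > 0 else -np.inf
    return (val, diag) if full_output else val


def _mc_diag(per_n: np.ndarray, like: float) -> dict:
    se = float(per_n.std(ddof=1) / np.sqrt(len(per_n))) if len(per_n) > 1 else 0.0
    return {"method": "mc", "mc_se": se,
            "mc_se_log": se / like if like > 0 else np.inf}


# ---------------------------------------------------------------------------
# Practical data models
# ---------------------------------------------------------------------------

def _counts(image) -> np.ndarray:
    if isinstance(image, PixelatedImage):
        if image.counts is None:
            raise ValueError("image has no integer counts")
        return image.counts
    return np.asarray(image, dtype=np.int64).ravel()


def stationary_practical_closed_form(bundle: ModelBundle, image) -> float:
    """Exact infinite-practical log-likelihood for a stationary emitter.

    ``log[p_L * L!/(prod z_k!) * prod_k p_k^{z_k}]`` with
    ``p_k = I_{C_k}(x0)``.  Deterministic; the Monte Carlo estimator
    converges to it, so it doubles as a test oracle.
    """
    model = bundle.motion
    if not model.is_stationary:
        raise ValueError("closed form requires a stationary motion model")
    z = _counts(image)
    L = int(z.sum())
    log_pL = bundle.arrivals.log_p_L(L)
    if L == 0:
        return float(log_pL)
    occ = np.flatnonzero(z)
    x0 = model.x0[:2]
    logp = 0.0
    for k, zk in zip(occ, z[occ]):
        p = float(bundle.optics.pixel_integral(x0, bundle.grid.pixel_rect(k + 1)))
        if p <= 0.0:
            return -np.inf
        logp += zk * np.log(p)
    log_mult = gammaln(L + 1) - np.sum(gammaln(z[occ] + 1))
    return float(log_pL + log_mult + logp)


def stationary_finite_closed_form(bundle: ModelBundle, image) -> float:
    """Exact finite-practical log-likelihood for a stationary emitter.

    Poisson thinning makes the per-pixel counts independent Poissons with
    means ``Lambda_bar * p_k``; photons missing the detector are integrated
    out exactly.
    """
    model = bundle.motion
    if not model.is_stationary:
        raise ValueError("closed form requires a stationary motion model")
    z = _counts(image)
    mu = bundle.arrivals.total_intensity
    x0 = model.x0[:2]
    coverage = float(bundle.optics.region_integral(x0, bundle.grid.bounds)[0])
    occ = np.flatnonzero(z)
    out = -mu * coverage
    for k, zk in zip(occ, z[occ]):
        p = float(bundle.optics.pixel_integral(x0, bundle.grid.pixel_rect(k + 1)))
        if p <= 0.0:
            return -np.inf
        out += zk * np.log(mu * p) - gammaln(zk + 1)
    return float(out)


def loglik_practical_infinite(bundle: ModelBundle, image, mc: MCConfig,
                              full_output: bool = False):
    """Log-likelihood of per-pixel counts under the infinite practical model.

    The pixel array is assumed to tile the detector plane, so every photon
    is captured; stationary emitters take the exact multinomial fast path.
    """
    z = _counts(image)
    L = int(z.sum())
    if bundle.motion.is_stationary:
        val = stationary_practical_closed_form(bundle, z)
        return (val, {"method": "closed_form", "mc_se_log": 0.0}) \
            if full_output else val
    log_pL = bundle.arrivals.log_p_L(L)
    if L == 0:
        return (float(log_pL), {"method": "exact", "mc_se_log": 0.0}) \
            if full_output else float(log_pL)
    occ = np.flatnonzero(z)
    z_occ = z[occ]
    _, X = sample_paths(bundle, L, mc, stream=0)
    P = _pixel_prob_matrix(bundle, X, occ + 1)  # (N, Mc, L, R)
    acc = _label_sum(P, z_occ, mc.label_cap)  # (N, Mc)
    per_n = acc.mean(axis=1)
    like = float(per_n.mean())
    diag = _mc_diag(per_n, like)
    with np.errstate(divide="ignore"):
        val = float(log_pL + np.log(like)) if like > 0 else -np.inf
    return (val, diag) if full_output else val


def loglik_practical_finite(bundle: ModelBundle, image, mc: MCConfig,
                            full_output: bool = False):
    """Log-likelihood of counts on a finite detector (photon loss allowed).

    Sums over the unobserved number of photons that missed the pixel array,
    truncated at ``mc.z_truncation`` or once a term falls below
    ``mc.tail_tol`` of the running sum.  Stationary emitters use the exact
    thinned-Poisson product.
    """
    z = _counts(image)
    L = int(z.sum())
    if bundle.motion.is_stationary:
        val = stationary_finite_closed_form(bundle, z)
        return (val, {"method": "closed_form", "mc_se_log": 0.0}) \
            if full_output else val
    occ = np.flatnonzero(z)
    z_occ = z[occ]
    bounds = bundle.grid.bounds
    total = 0.0
    terms = []
    for miss in range(mc.z_truncation + 1):
        L_tot = L + miss
        if L_tot == 0:
            term = bundle.arrivals.p_L(0)
        else:
            _, X = sample_paths(bundle, L_tot, mc, stream=miss + 1)
            xy = X[..., :2]
            if len(occ):
                P = _pixel_prob_matrix(bundle, X, occ + 1)
            else:
                P = np.empty(xy.shape[:-1] + (0,))
            if miss:
                flat = xy.reshape(-1, 2)
                cov = bundle.optics.region_integral(flat, bounds)
                p_miss = np.clip(1.0 - cov.reshape(xy.shape[:-1]), 0.0, 1.0)
                P = np.concatenate([P, p_miss[..., None]], axis=-1)
                z_ext = np.append(z_occ, miss)
            else:
                z_ext = z_occ
            acc = _label_sum(P, z_ext, mc.label_cap)
            term = bundle.arrivals.p_L(L_tot) * float(acc.mean())
        total += term
        terms.append(term)
        if miss >= 1 and total > 0 and term < mc.tail_tol * total:
            break
    diag = {"method": "mc", "n_miss_terms": len(terms), "terms": terms}
    with np.errstate(divide="ignore"):
        val = float(np.log(total)) if total > 0 else -np.inf
    return (val, diag) if full_output else val


# ---------------------------------------------------------------------------
# Noisy practical data model
# ---------------------------------------------------------------------------

def loglik_noisy(bundle: ModelBundle, image, mc: MCConfig,
                 count_model: str = "infinite",
                 config_cap: int = 200_000) -> float:
    """Log-likelihood of real-valued pixel intensities after camera noise.

    ``log sum_z p(i | z) Pr[S = z]`` where the sum over integer photon-count
    configurations ``z`` is truncated to, per pixel, counts whose Gaussian
    readout support contains ``i_k`` within 6 sigma, and overall to totals
    within the bulk of the photon-number distribution.
    """
    if bundle.noise is None:
        raise ValueError("noisy likelihood requires a noise model")
    if isinstance(image, PixelatedImage):
        if image.intensities is None:
            raise ValueError("image has no intensities; use a count likelihood")
        i = image.intensities
    else:
        i = np.asarray(image, dtype=float).ravel()
    K = bundle.grid.K
    if i.shape != (K,):
        raise ValueError("intensity vector does not match the grid")
    noise = bundle.noise
    b, e, s = noise._per_pixel(K)
    mu = bundle.arrivals.total_intensity
    L_hi = int(np.ceil(mu + 10.0 * np.sqrt(mu) + 10.0))
    cands = []
    for k in range(K):
        hi = int(np.floor(i[k] - e[k] + 6.0 * s[k]))
        if hi < 0:
            raise DegenerateDataError(
                f"intensity {i[k]:g} in pixel {k + 1} is below the readout "
                "support of every photon count")
        cands.append(range(min(hi, L_hi) + 1))
    n_cfg = int(np.prod([len(c) for c in cands]))
    if n_cfg > config_cap:
        raise TooManyZConfigsError(n_cfg, config_cap)
    count_fn = {"infinite": loglik_practical_infinite,
                "finite": loglik_practical_finite}[count_model]
    log_terms = []
    for cfg in itertools.product(*cands):
        zc = np.asarray(cfg, dtype=np.int64)
        if zc.sum() > L_hi:
            continue
        log_noise = float(np.sum(noise.log_conditional_density(i, zc)))
        if not np.isfinite(log_noise):
            continue
        log_count = count_fn(bundle, zc, mc)
        if np.isfinite(log_count):
            log_terms.append(log_noise + log_count)
    if not log_terms:
        raise DegenerateDataError(
            "no photon-count configuration carries mass for these intensities")
    return float(logsumexp(log_terms))


class TooManyZConfigsError(ValueError):
    """The truncated count-configuration sum is still too large."""

    def __init__(self, count: int, cap: int):
        super().__init__(f"{count} count configurations exceed the cap {cap}")


# ---------------------------------------------------------------------------
# Evaluation report
# ---------------------------------------------------------------------------

def likelihood_report(bundle: ModelBundle, image, mc: MCConfig,
                      model: str = "infinite") -> dict:
    """Evaluate a likelihood and package diagnostics as a JSON-ready dict."""
    fn = {"infinite": loglik_practical_infinite,
          "finite": loglik_practical_finite}[model]
    val, diag = fn(bundle, image, mc, full_output=True)
    return {
        "loglik": val,
        "model": model,
        "n_temporal": mc.n_temporal,
        "n_spatial": mc.n_spatial,
        "seed": mc.seed,
        **{k: (float(v) if isinstance(v, (int, float, np.floating,
                                          np.integer)) else v)
           for k, v in diag.items()},
    }
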