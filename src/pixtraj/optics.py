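"""Image functions (PSF models) and the magnified image profile.

An *image function* ``q`` is the probability density of the impact location of
a photon on the detector plane for an object at the origin, at unit lateral
magnification.  Three standard models are provided:

* :class:`Airy` -- in-focus diffraction-limited point source,
  ``q(u) = J_1^2(alpha |u|) / (pi |u|^2)`` with ``alpha = 2 pi n_a / lambda``;
* :class:`Gaussian2D` -- the common isotropic Gaussian approximation;
* :class:`BornWolf` -- classical defocused point-source model.

The *image profile* of an object at position ``x`` seen through a lateral
magnification matrix ``M`` is

    f_x(r) = q(M^{-1} r - x) / |det M|,   r in the detector plane,

and :meth:`OpticalMap.pixel_integral` evaluates ``int_C f_x(r) dr`` over
rectangular pixels (closed-form error functions for the Gaussian model,
fixed-order Gauss-Legendre quadrature otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import erf, j0, j1

__all__ = [
    "ImageFunction",
    "Gaussian2D",
    "Airy",
    "BornWolf",
    "OpticalMap",
    "Rect",
    "WHOLE_PLANE",
    "UnsupportedRegionError",
]


class UnsupportedRegionError(ValueError):
    """Region type not supported by the requested integration path."""


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle ``[xmin, xmax) x [ymin, ymax)`` in um."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self):
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError("degenerate rectangle")

    @property
    def center(self) -> np.ndarray:
        return np.array([0.5 * (self.xmin + self.xmax),
                         0.5 * (self.ymin + self.ymax)])

    def scaled(self, sx: float, sy: float) -> "Rect":
        lo_x, hi_x = sorted((self.xmin / sx, self.xmax / sx))
        lo_y, hi_y = sorted((self.ymin / sy, self.ymax / sy))
        return Rect(lo_x, hi_x, lo_y, hi_y)


WHOLE_PLANE = object()  # sentinel region covering all of R^2


@lru_cache(maxsize=32)
def _gl_nodes(order: int):
    x, w = np.polynomial.legendre.leggauss(order)
    return x, w


def _gl_grid(rect: Rect, order: int):
    """Tensor Gauss-Legendre nodes/weights on a rectangle."""
    x, w = _gl_nodes(order)
    cx, hx = 0.5 * (rect.xmin + rect.xmax), 0.5 * (rect.xmax - rect.xmin)
    cy, hy = 0.5 * (rect.ymin + rect.ymax), 0.5 * (rect.ymax - rect.ymin)
    gx = cx + hx * x
    gy = cy + hy * x
    pts = np.stack(np.meshgrid(gx, gy, indexing="ij"), axis=-1).reshape(-1, 2)
    wts = (hx * hy) * np.outer(w, w).ravel()
    return pts, wts


class ImageFunction:
    """Base class: a rotationally managed 2D photon-impact density."""

    def density(self, points) -> np.ndarray:
        """Density q at ``points`` (..., 2), in um^-2."""
        raise NotImplementedError

    def density_approx(self, points) -> np.ndarray:
        """Density for bulk quadrature; may use a cached interpolation table."""
        return self.density(points)

    def radial_cdf(self, rho) -> np.ndarray:
        """Probability mass within radius ``rho`` of the center."""
        raise NotImplementedError

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw n impact offsets (n, 2) from q."""
        raise NotImplementedError


@dataclass(frozen=True)
class Gaussian2D(ImageFunction):
    """Isotropic bivariate Gaussian image function with width ``sigma`` (um)."""

    sigma: float = 0.1

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def density(self, points):
        pts = np.asarray(points, dtype=float)
        r2 = np.sum(pts * pts, axis=-1)
        s2 = self.sigma ** 2
        return np.exp(-0.5 * r2 / s2) / (2.0 * np.pi * s2)

    def radial_cdf(self, rho):
        rho = np.asarray(rho, dtype=float)
        return 1.0 - np.exp(-0.5 * (rho / self.sigma) ** 2)

    def sample(self, rng, n):
        return self.sigma * rng.standard_normal((n, 2))

    def rect_mass(self, rect: Rect, center) -> np.ndarray:
        """Closed-form integral of ``q(u - center)`` over ``rect``.

        ``center`` may have any leading shape (..., 2).
        """
        c = np.asarray(center, dtype=float)
        s = self.sigma * np.sqrt(2.0)
        ix = 0.5 * (erf((rect.xmax - c[..., 0]) / s) - erf((rect.xmin - c[..., 0]) / s))
        iy = 0.5 * (erf((rect.ymax - c[..., 1]) / s) - erf((rect.ymin - c[..., 1]) / s))
        return ix * iy


class _RadialSamplerMixin:
    """Inverse-CDF sampling of a radial density via a cached radius table."""

    def _radius_table(self):
        raise NotImplementedError

    def sample(self, rng, n):
        cdf, rho = self._radius_table()
        u = rng.uniform(0.0, cdf[-1], size=n)
        r = np.interp(u, cdf, rho)
        phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
        return np.stack([r * np.cos(phi), r * np.sin(phi)], axis=-1)


@dataclass(frozen=True)
class Airy(_RadialSamplerMixin, ImageFunction):
    """Airy profile.

    Either give ``alpha`` (um^-1) directly, or a numerical aperture ``n_a``
    and emission wavelength ``lambda_em`` (um), whence
    ``alpha = 2 pi n_a / lambda_em``.
    """

    alpha: float | None = None
    n_a: float | None = None
    lambda_em: float | None = None

    def __post_init__(self):
        if self.alpha is None:
            if self.n_a is None or self.lambda_em is None:
                raise ValueError("give alpha, or n_a and lambda_em")
            object.__setattr__(self, "alpha",
                               2.0 * np.pi * self.n_a / self.lambda_em)
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    def density(self, points):
        pts = np.asarray(points, dtype=float)
        r2 = np.sum(pts * pts, axis=-1)
        r = np.sqrt(r2)
        a = self.alpha
        with np.errstate(divide="ignore", invalid="ignore"):
            val = j1(a * r) ** 2 / (np.pi * r2)
        # removable singularity at the origin: lim = alpha^2 / (4 pi)
        return np.where(r2 > 0, val, a * a / (4.0 * np.pi))

    def radial_cdf(self, rho):
        u = self.alpha * np.asarray(rho, dtype=float)
        return 1.0 - j0(u) ** 2 - j1(u) ** 2

    @lru_cache(maxsize=1)
    def _density_table(self):
        rho = np.linspace(0.0, 60.0 / self.alpha, 30_000)
        dens = self.density(np.stack([rho, np.zeros_like(rho)], axis=-1))
        return rho, dens

    def density_approx(self, points):
        # radial interpolation; exact Bessel evaluation beyond the table
        pts = np.asarray(points, dtype=float)
        r = np.sqrt(np.sum(pts * pts, axis=-1))
        rho, dens = self._density_table()
        out = np.asarray(np.interp(r, rho, dens))
        far = r > rho[-1]
        if np.any(far):
            out[far] = self.density(pts[far])
        return out

    @lru_cache(maxsize=1)
    def _radius_table(self):
        # table out to the 1 - 1e-6 quantile; the tail is heavy (~2/(pi a r))
        rmax = 2.0 / (np.pi * self.alpha * 1e-6)
        rho = np.concatenate([
            np.linspace(0.0, 20.0 / self.alpha, 4000, endpoint=False),
            np.geomspace(20.0 / self.alpha, rmax, 4000),
        ])
        cdf = self.radial_cdf(rho)
        keep = np.concatenate([[True], np.diff(cdf) > 0])
        return cdf[keep], rho[keep]


@dataclass(frozen=True)
class BornWolf(_RadialSamplerMixin, ImageFunction):
    """Born & Wolf defocused point-source model.

    Parameters: numerical aperture ``n_a``, emission wavelength ``lambda_em``
    (um), immersion-medium refractive index ``n_o`` and axial position ``z0``
    (um).  At ``z0 = 0`` this reduces to the Airy profile.
    """

    n_a: float
    lambda_em: float
    n_o: float = 1.515
    z0: float = 0.0
    quad_order: int = 64

    def __post_init__(self):
        if min(self.n_a, self.lambda_em, self.n_o) <= 0:
            raise ValueError("n_a, lambda_em and n_o must be positive")

    @property
    def alpha(self) -> float:
        return 2.0 * np.pi * self.n_a / self.lambda_em

    def density(self, points):
        pts = np.asarray(points, dtype=float)
        r = np.sqrt(np.sum(pts * pts, axis=-1))
        nodes, w = _gl_nodes(self.quad_order)
        rho = 0.5 * (nodes + 1.0)  # map to [0, 1]
        wts = 0.5 * w
        phase = np.exp(1j * np.pi * self.n_a ** 2 * self.z0
                       / (self.n_o * self.lambda_em) * rho ** 2)
        integrand = j0(self.alpha * r[..., None] * rho) * phase * rho
        integral = np.tensordot(integrand, wts, axes=([-1], [0]))
        return (4.0 * np.pi * self.n_a ** 2 / self.lambda_em ** 2) \
            * np.abs(integral) ** 2

    @lru_cache(maxsize=1)
    def _mass_table(self):
        # cumulative radial mass by trapezoid of 2 pi rho q(rho)
        rmax = 200.0 / self.alpha
        rho = np.concatenate([np.linspace(0.0, 20.0 / self.alpha, 3000,
                                          endpoint=False),
                              np.linspace(20.0 / self.alpha, rmax, 3000)])
        dens = self.density(np.stack([rho, np.zeros_like(rho)], axis=-1))
        integrand = 2.0 * np.pi * rho * dens
        mass = np.concatenate([[0.0],
                               np.cumsum(0.5 * (integrand[1:] + integrand[:-1])
                                         * np.diff(rho))])
        return rho, mass

    def radial_cdf(self, rho):
        grid, mass = self._mass_table()
        return np.interp(np.asarray(rho, dtype=float), grid, mass)

    @lru_cache(maxsize=1)
    def _radius_table(self):
        grid, mass = self._mass_table()
        keep = np.concatenate([[True], np.diff(mass) > 0])
        return mass[keep], grid[keep]


@dataclass(frozen=True)
class OpticalMap:
    """Image function plus an invertible 2x2 lateral magnification matrix.

    With ``pixel_table=True``, pixel integrals of non-Gaussian image
    functions are served from a cached table over emitter-pixel offsets
    (bilinear interpolation, ~1e-3 relative accuracy) instead of per-call
    quadrature -- the Monte Carlo likelihood evaluates millions of such
    integrals.
    """

    image_function: ImageFunction
    M: np.ndarray = 100.0
    quad_order: int = 16
    pixel_table: bool = False
    _table_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        M = np.asarray(self.M, dtype=float)
        if M.ndim == 0:
            M = float(M) * np.eye(2)
        if M.shape != (2, 2) or np.linalg.det(M) == 0:
            raise ValueError("M must be an invertible 2x2 matrix")
        object.__setattr__(self, "M", M)

    @property
    def abs_det_M(self) -> float:
        return abs(float(np.linalg.det(self.M)))

    @property
    def _diag_scales(self):
        """(sx, sy) if M is diagonal, else None."""
        if self.M[0, 1] == 0.0 and self.M[1, 0] == 0.0:
            return float(self.M[0, 0]), float(self.M[1, 1])
        return None

    def image_profile(self, x, r) -> np.ndarray:
        """Density ``f_x(r)``; ``x`` (..., 2) object um, ``r`` (..., 2) image um."""
        x = np.asarray(x, dtype=float)
        r = np.asarray(r, dtype=float)
        Minv = np.linalg.inv(self.M)
        offsets = r @ Minv.T - x
        return self.image_function.density(offsets) / self.abs_det_M

    def sample_impact(self, x, rng: np.random.Generator) -> np.ndarray:
        """Draw photon impact points ``r ~ f_x`` for objects at x (n, 2)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        offsets = self.image_function.sample(rng, len(x))
        return (x + offsets) @ self.M.T

    # -- pixel integrals ----------------------------------------------------

    def pixel_integral(self, x, pixel, order: int | None = None) -> np.ndarray:
        """Probability ``int_pixel f_x(r) dr`` for object positions x (..., 2).

        ``pixel`` is a :class:`Rect` in image-plane um, or :data:`WHOLE_PLANE`.
        Gaussian image functions with diagonal M use the closed-form error
        function product; other cases use tensor Gauss-Legendre quadrature.
        """
        x = np.asarray(x, dtype=float)
        if pixel is WHOLE_PLANE:
            return np.ones(x.shape[:-1])
        if not isinstance(pixel, Rect):
            raise UnsupportedRegionError(f"unsupported region {pixel!r}")
        order = order or self.quad_order
        diag = self._diag_scales
        if diag is not None:
            obj_rect = pixel.scaled(*diag)  # pixel mapped to object space
            q = self.image_function
            if isinstance(q, Gaussian2D):
                return q.rect_mass(obj_rect, x)
            if self.pixel_table:
                return self._table_lookup(obj_rect, x, order)
            pts, wts = _gl_grid(obj_rect, order)
            dens = q.density_approx(pts - x[..., None, :])  # (..., n_nodes)
            return dens @ wts
        # general M: quadrature in the image plane
        pts, wts = _gl_grid(pixel, order)
        dens = self.image_profile(x[..., None, :], pts)
        return dens @ wts

    def _table_lookup(self, obj_rect: Rect, x: np.ndarray, order: int
                      ) -> np.ndarray:
        """Bilinear lookup of the pixel integral as a function of the
        emitter-to-pixel-center offset; direct quadrature beyond the table."""
        w = obj_rect.xmax - obj_rect.xmin
        h = obj_rect.ymax - obj_rect.ymin
        key = (round(w, 9), round(h, 9), order)
        if key not in self._table_cache:
            self._table_cache[key] = self._build_table(w, h, order)
        grid_ax, table = self._table_cache[key]
        offset = obj_rect.center - x  # (..., 2): pixel center minus emitter
        step = grid_ax[1] - grid_ax[0]
        fx = (offset[..., 0] - grid_ax[0]) / step
        fy = (offset[..., 1] - grid_ax[0]) / step
        n = len(grid_ax)
        inside = (fx >= 0) & (fx <= n - 1) & (fy >= 0) & (fy <= n - 1)
        ix = np.clip(fx.astype(np.int64), 0, n - 2)
        iy = np.clip(fy.astype(np.int64), 0, n - 2)
        tx = np.clip(fx - ix, 0.0, 1.0)
        ty = np.clip(fy - iy, 0.0, 1.0)
        out = ((1 - tx) * (1 - ty) * table[ix, iy]
               + tx * (1 - ty) * table[ix + 1, iy]
               + (1 - tx) * ty * table[ix, iy + 1]
               + tx * ty * table[ix + 1, iy + 1])
        if not np.all(inside):
            pts, wts = _gl_grid(Rect(-w / 2, w / 2, -h / 2, h / 2), order)
            far = ~inside
            dens = self.image_function.density_approx(
                pts + offset[far][..., None, :])
            out = np.asarray(out)
            out[far] = dens @ wts
        return out

    def _build_table(self, w: float, h: float, order: int):
        """Integral of q over a centered w x h rectangle vs emitter offset."""
        reach = 2.0 + max(w, h)  # um; covers the bright core generously
        step = 0.008
        ax = np.arange(-reach, reach + step / 2, step)
        pts, wts = _gl_grid(Rect(-w / 2, w / 2, -h / 2, h / 2), order)
        table = np.empty((len(ax), len(ax)))
        q = self.image_function
        chunk = 200
        for i0 in range(0, len(ax), chunk):
            dx = ax[i0:i0 + chunk]
            offs = np.stack(np.meshgrid(dx, ax, indexing="ij"),
                            axis=-1)  # (c, n, 2)
            dens = q.density_approx(pts + offs[..., None, :])
            table[i0:i0 + chunk] = dens @ wts
        return ax, table

    def region_integral(self, x, rect: Rect, order: int | None = None,
                        n_phi: int = 256) -> np.ndarray:
        """Integral of ``f_x`` over a large rectangle (detector coverage).

        For radial image functions with isotropic magnification and the image
        of ``x`` strictly inside ``rect``, uses the exact angular form
        ``(1/2pi) int_0^{2pi} P(R(phi)) dphi`` of the radial mass function
        ``P``; otherwise falls back to Gauss-Legendre quadrature.
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        diag = self._diag_scales
        q = self.image_function
        if diag is not None and isinstance(q, Gaussian2D):
            return q.rect_mass(rect.scaled(*diag), x)
        if diag is not None and abs(diag[0]) == abs(diag[1]):
            obj_rect = rect.scaled(*diag)
            rel = np.stack([
                np.stack([obj_rect.xmin - x[..., 0], obj_rect.xmax - x[..., 0]], -1),
                np.stack([obj_rect.ymin - x[..., 1], obj_rect.ymax - x[..., 1]], -1),
            ], axis=-2)  # (..., 2 axes, 2 bounds)
            inside = np.all(rel[..., 0] < 0, axis=-1) & np.all(rel[..., 1] > 0, axis=-1)
            out = np.empty(x.shape[:-1])
            if np.any(inside):
                out[inside] = _radial_rect_mass(q, rel[inside], n_phi)
            if np.any(~inside):
                sub = x[~inside]
                pts, wts = _gl_grid(obj_rect, order or 32)
                dens = q.density(pts[:, None, :] - sub[None, :, :])
                out[~inside] = wts @ dens
            return out
        pts, wts = _gl_grid(rect, order or 32)
        dens = self.image_profile(x[..., None, :], pts)
        return dens @ wts


def _radial_rect_mass(q: ImageFunction, rel_bounds: np.ndarray,
                      n_phi: int) -> np.ndarray:
    """Mass of radial density q over rects given by bounds relative to center.

    ``rel_bounds``: (n, 2, 2) = [[xlo, xhi], [ylo, yhi]] with xlo<0<xhi etc.
    """
    phi = (np.arange(n_phi) + 0.5) * (2.0 * np.pi / n_phi)
    c, s = np.cos(phi), np.sin(phi)
    with np.errstate(divide="ignore"):
        tx = np.where(c > 0, rel_bounds[:, 0, 1:2] / c,
                      rel_bounds[:, 0, 0:1] / np.where(c < 0, c, -1.0))
        tx = np.where(c == 0, np.inf, tx)
        ty = np.where(s > 0, rel_bounds[:, 1, 1:2] / s,
                      rel_bounds[:, 1, 0:1] / np.where(s < 0, s, -1.0))
        ty = np.where(s == 0, np.inf, ty)
    R = np.minimum(tx, ty)  # (n, n_phi) distance to the boundary along phi
    return q.radial_cdf(R).mean(axis=-1)
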