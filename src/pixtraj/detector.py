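"""Pixelated detector geometry, photon binning and the camera noise model.

A :class:`PixelGrid` is a rectangular array of disjoint half-open pixels
``C_1, ..., C_K`` in detector-plane um, labelled row-major and 1-based, with
an implicit complement region ``C_{K+1}`` (the rest of the plane: photons
landing there are detected by no pixel).  :func:`bin_photons` converts photon
impact points into per-pixel counts; :class:`NoiseModel` adds the standard
CCD corruption ``i_k = z_k + Poisson(beta_k) + Normal(eta_k, sigma_k^2)``
(Poisson background plus Gaussian readout noise) and evaluates the
Poisson-Gaussian convolution density ``p(i_k | z_k)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .optics import Rect

__all__ = ["PixelGrid", "PixelatedImage", "NoiseModel", "bin_photons"]


@dataclass(frozen=True)
class PixelGrid:
    """Rectangular pixel array; ``origin`` is the low corner in um."""

    n_rows: int
    n_cols: int
    pixel_width: float
    pixel_height: float | None = None
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one pixel")
        if self.pixel_height is None:
            object.__setattr__(self, "pixel_height", self.pixel_width)
        if self.pixel_width <= 0 or self.pixel_height <= 0:
            raise ValueError("pixel dimensions must be positive")

    @property
    def K(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def width(self) -> float:
        return self.n_cols * self.pixel_width

    @property
    def height(self) -> float:
        return self.n_rows * self.pixel_height

    @property
    def bounds(self) -> Rect:
        """Bounding rectangle of the full pixel array."""
        ox, oy = self.origin
        return Rect(ox, ox + self.width, oy, oy + self.height)

    def pixel_rect(self, k: int) -> Rect:
        """Rectangle of pixel ``k`` (1-based, row-major)."""
        if not 1 <= k <= self.K:
            raise ValueError(f"pixel label {k} outside 1..{self.K}")
        row, col = divmod(k - 1, self.n_cols)
        ox, oy = self.origin
        x0 = ox + col * self.pixel_width
        y0 = oy + row * self.pixel_height
        return Rect(x0, x0 + self.pixel_width, y0, y0 + self.pixel_height)

    def pixel_center(self, k: int) -> np.ndarray:
        return self.pixel_rect(k).center

    def centers(self) -> np.ndarray:
        """Centers of all pixels, shape (K, 2), label order."""
        ox, oy = self.origin
        cx = ox + (np.arange(self.n_cols) + 0.5) * self.pixel_width
        cy = oy + (np.arange(self.n_rows) + 0.5) * self.pixel_height
        gx, gy = np.meshgrid(cx, cy)  # row-major: y varies over rows
        return np.stack([gx.ravel(), gy.ravel()], axis=-1)

    def pixel_of(self, points) -> np.ndarray:
        """Label in 1..K+1 of the pixel containing each point.

        Pixels are half-open ``[lo, hi)``, so boundary points belong to the
        higher-coordinate pixel; points outside the array get label K+1.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ox, oy = self.origin
        col = np.floor((pts[..., 0] - ox) / self.pixel_width).astype(np.int64)
        row = np.floor((pts[..., 1] - oy) / self.pixel_height).astype(np.int64)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        labels = np.where(inside, row * self.n_cols + col + 1, self.K + 1)
        return labels


@dataclass
class PixelatedImage:
    """Per-pixel photon counts (or noisy real intensities) on a grid."""

    grid: PixelGrid
    counts: np.ndarray | None = None  # (K,) non-negative integers
    intensities: np.ndarray | None = None  # (K,) real, after noise
    n_missed: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.counts is not None:
            c = np.asarray(self.counts)
            if c.shape == (self.grid.n_rows, self.grid.n_cols):
                c = c.ravel()
            if c.shape != (self.grid.K,):
                raise ValueError("counts shape does not match the grid")
            if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
                c = c.astype(np.int64)
                if np.any(c < 0):
                    raise ValueError("counts must be non-negative")
            self.counts = c.astype(np.int64)
        if self.intensities is not None:
            i = np.asarray(self.intensities, dtype=float).ravel()
            if i.shape != (self.grid.K,):
                raise ValueError("intensities shape does not match the grid")
            if not np.all(np.isfinite(i)):
                raise ValueError("intensities must be finite")
            self.intensities = i

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())

    def as_array(self) -> np.ndarray:
        values = self.counts if self.intensities is None else self.intensities
        return values.reshape(self.grid.n_rows, self.grid.n_cols)

    # -- plain-text / TIFF I/O ---------------------------------------------

    def to_tiff(self, path) -> None:
        import tifffile

        arr = self.as_array()
        arr = arr.astype(np.float32) if self.intensities is not None \
            else arr.astype(np.uint16)
        tifffile.imwrite(path, arr)
        sidecar = str(path) + ".json"
        with open(sidecar, "w") as fh:
            json.dump(_jsonable(self.metadata), fh, indent=1)

    def to_csv(self, path) -> None:
        arr = self.as_array()
        rows, cols = np.nonzero(np.ones_like(arr))
        with open(path, "w") as fh:
            fh.write("row,col,value\n")
            for r, c in zip(rows, cols):
                fh.write(f"{r},{c},{arr[r, c]}\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def bin_photons(grid: PixelGrid, impacts) -> PixelatedImage:
    """Bin photon impact points (n, 2) into per-pixel counts.

    Photons outside the array are counted in ``n_missed`` (the complement
    region), so detected plus missed photons equal the number of impacts.
    """
    impacts = np.asarray(impacts, dtype=float).reshape(-1, 2)
    labels = grid.pixel_of(impacts) if len(impacts) else np.empty(0, dtype=np.int64)
    counts = np.bincount(labels - 1, minlength=grid.K + 1)[: grid.K] \
        if len(impacts) else np.zeros(grid.K, dtype=np.int64)
    missed = int(np.sum(labels == grid.K + 1)) if len(impacts) else 0
    return PixelatedImage(grid=grid, counts=counts.astype(np.int64),
                          n_missed=missed)


@dataclass(frozen=True)
class NoiseModel:
    """Poisson background (mean ``beta``) + Gaussian readout (``eta``, ``sigma_read``).

    All three parameters are scalars or arrays broadcastable to the grid.
    """

    beta: float | np.ndarray = 0.0
    eta: float | np.ndarray = 0.0
    sigma_read: float | np.ndarray = 1.0
    tail_tol: float = 1e-12

    def __post_init__(self):
        if np.any(np.asarray(self.beta) < 0):
            raise ValueError("beta must be non-negative")
        if np.any(np.asarray(self.sigma_read) <= 0):
            raise ValueError("sigma_read must be positive")

    def _per_pixel(self, K: int):
        b = np.broadcast_to(np.asarray(self.beta, dtype=float), (K,))
        e = np.broadcast_to(np.asarray(self.eta, dtype=float), (K,))
        s = np.broadcast_to(np.asarray(self.sigma_read, dtype=float), (K,))
        return b, e, s

    def apply(self, image: PixelatedImage, rng: np.random.Generator
              ) -> PixelatedImage:
        """Corrupt integer counts into real-valued intensities."""
        if image.counts is None:
            raise ValueError("apply expects an integer-count image")
        K = image.grid.K
        b, e, s = self._per_pixel(K)
        i = image.counts + rng.poisson(b) + rng.normal(e, s)
        return PixelatedImage(grid=image.grid, counts=image.counts,
                              intensities=i, n_missed=image.n_missed,
                              metadata=dict(image.metadata))

    def log_conditional_density(self, i, z, beta=None, eta=None, sigma=None
                                ) -> np.ndarray:
        """Log of ``p(i | z)``: Poisson(beta)-Gaussian(eta, sigma) convolution.

        The series over the background count is truncated once the remaining
        Poisson tail mass is below ``tail_tol``.
        """
        from scipy.special import logsumexp

        beta = self.beta if beta is None else beta
        eta = self.eta if eta is None else eta
        sigma = self.sigma_read if sigma is None else sigma
        shape = np.broadcast_shapes(np.shape(i), np.shape(z), np.shape(beta),
                                    np.shape(eta), np.shape(sigma))
        b = np.broadcast_to(np.asarray(beta, dtype=float), shape)[..., None]
        e = np.broadcast_to(np.asarray(eta, dtype=float), shape)[..., None]
        s = np.broadcast_to(np.asarray(sigma, dtype=float), shape)[..., None]
        iv = np.broadcast_to(np.asarray(i, dtype=float), shape)[..., None]
        zv = np.broadcast_to(np.asarray(z, dtype=float), shape)[..., None]
        bmax = float(np.max(b)) if b.size else 0.0
        l_max = int(np.ceil(bmax + 10.0 * np.sqrt(bmax) + 10.0))
        ls = np.arange(l_max + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_pois = ls * np.log(np.where(b > 0, b, 1.0)) - b - gammaln(ls + 1)
        log_pois = np.where(b > 0, log_pois, np.where(ls == 0, 0.0, -np.inf))
        resid = iv - ls - e - zv
        log_norm = -0.5 * (resid / s) ** 2 - np.log(np.sqrt(2.0 * np.pi) * s)
        out = logsumexp(log_pois + log_norm, axis=-1)
        return out if shape else float(out)

    def conditional_density(self, i, z) -> np.ndarray:
        return np.exp(self.log_conditional_density(i, z))
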