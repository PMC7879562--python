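"""Configuration files and image I/O.

A model configuration is a YAML or JSON document with blocks::

    motion:   {dim: 2, F: -10.0, D: 1.5, V: 0.0, x0: [2.3, 2.3]}
    optics:   {kind: gaussian, sigma_um: 0.1, M: 100.0}
    arrivals: {t0_ms: 0.0, t_ms: 20.0, photon_rate: 200.0}
    grid:     {n_rows: 60, n_cols: 60, pixel_um: 6.5, origin: [0.0, 0.0]}
    noise:    {beta: 0.0, eta: 0.0, sigma_read: 1.0}   # optional

Times in configuration files are milliseconds (the convention of the
experimental literature); they are converted to seconds on load, and all
lengths are um.  ``optics.kind`` is one of ``gaussian``, ``airy``
(``alpha`` or ``n_a`` + ``lambda_um``) or ``born_wolf``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .arrivals import ArrivalProcess
from .detector import NoiseModel, PixelatedImage, PixelGrid
from .likelihood import ModelBundle
from .motion import MotionModel
from .optics import Airy, BornWolf, Gaussian2D, OpticalMap

__all__ = ["load_bundle", "load_config", "read_image"]


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def _motion_from(cfg: dict) -> MotionModel:
    dim = int(cfg.get("dim", 2))
    if "G" in cfg:
        G = np.asarray(cfg["G"], dtype=float)
    else:
        G = np.sqrt(2.0 * float(cfg.get("D", 0.0)))
    kwargs = dict(dim=dim, F=np.asarray(cfg.get("F", 0.0), dtype=float),
                  G=G, V=np.asarray(cfg.get("V", 0.0), dtype=float))
    if "init_cov" in cfg:
        kwargs["init_mean"] = np.asarray(cfg.get("init_mean", np.zeros(dim)),
                                         dtype=float)
        kwargs["init_cov"] = np.asarray(cfg["init_cov"], dtype=float)
    else:
        kwargs["x0"] = np.asarray(cfg.get("x0", np.zeros(dim)), dtype=float)
    return MotionModel(**kwargs)


def _optics_from(cfg: dict) -> OpticalMap:
    kind = cfg.get("kind", "gaussian")
    if kind in ("gaussian", "gaussian2d", "gauss"):
        q = Gaussian2D(sigma=float(cfg.get("sigma_um", 0.1)))
    elif kind == "airy":
        if "alpha" in cfg:
            q = Airy(alpha=float(cfg["alpha"]))
        else:
            q = Airy(n_a=float(cfg["n_a"]), lambda_em=float(cfg["lambda_um"]))
    elif kind in ("born_wolf", "bornwolf"):
        q = BornWolf(n_a=float(cfg["n_a"]), lambda_em=float(cfg["lambda_um"]),
                     n_o=float(cfg.get("n_o", 1.515)),
                     z0=float(cfg.get("z0_um", 0.0)))
    else:
        raise ValueError(f"unknown image-function kind {kind!r}")
    M = cfg.get("M", 100.0)
    return OpticalMap(image_function=q, M=np.asarray(M, dtype=float),
                      quad_order=int(cfg.get("quad_order", 16)))


def _arrivals_from(cfg: dict) -> ArrivalProcess:
    t0 = float(cfg.get("t0_ms", 0.0)) * 1e-3
    t = float(cfg["t_ms"]) * 1e-3
    if "piecewise" in cfg:
        edges = [float(e) * 1e-3 for e in cfg["piecewise"]["edges_ms"]]
        values = [float(v) for v in cfg["piecewise"]["rates"]]
        return ArrivalProcess(t0=t0, t=t, rate=(edges, values))
    return ArrivalProcess(t0=t0, t=t, rate=float(cfg.get("photon_rate", 1.0)))


def _grid_from(cfg: dict) -> PixelGrid:
    w = float(cfg.get("pixel_um", cfg.get("pixel_width_um", 1.0)))
    h = float(cfg.get("pixel_height_um", w))
    origin = tuple(float(v) for v in cfg.get("origin", (0.0, 0.0)))
    return PixelGrid(n_rows=int(cfg["n_rows"]), n_cols=int(cfg["n_cols"]),
                     pixel_width=w, pixel_height=h, origin=origin)


def load_bundle(config) -> ModelBundle:
    """Build a :class:`~pixtraj.likelihood.ModelBundle` from a config dict
    or a YAML/JSON file path."""
    if not isinstance(config, dict):
        config = load_config(config)
    noise = None
    if "noise" in config and config["noise"]:
        n = config["noise"]
        noise = NoiseModel(beta=n.get("beta", 0.0), eta=n.get("eta", 0.0),
                           sigma_read=n.get("sigma_read", 1.0))
    return ModelBundle(motion=_motion_from(config.get("motion", {})),
                       optics=_optics_from(config.get("optics", {})),
                       arrivals=_arrivals_from(config["arrivals"]),
                       grid=_grid_from(config["grid"]),
                       noise=noise)


def read_image(path, grid: PixelGrid) -> PixelatedImage:
    """Read a single-frame TIFF or (row, col, value) CSV into an image."""
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        import tifffile

        arr = np.asarray(tifffile.imread(path))
    else:
        import pandas as pd

        df = pd.read_csv(path)
        arr = np.zeros((grid.n_rows, grid.n_cols))
        arr[df["row"].to_numpy(), df["col"].to_numpy()] = df["value"].to_numpy()
    if arr.shape != (grid.n_rows, grid.n_cols):
        raise ValueError("image shape does not match the grid")
    if np.issubdtype(arr.dtype, np.integer):
        return PixelatedImage(grid=grid, counts=arr.ravel())
    if np.allclose(arr, np.round(arr)):
        return PixelatedImage(grid=grid, counts=arr.astype(np.int64).ravel())
    return PixelatedImage(grid=grid, intensities=arr.ravel())
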