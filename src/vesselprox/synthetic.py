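"""Synthetic microscopy-like fixtures with known ground truth.

Emulates the structure of a fetal long-bone ossification centre scan: a
tubular vessel network inside an elongated (elliptical) tissue region,
extravascular cell placements with tunable distance-dependent attraction to
the vessels, a junction polyline across the distal end, and smooth intensity
channels over an out-of-tissue background.

Vessels are correlated random walks (fixed step length, Gaussian heading
increments) dilated to a physical radius; tortuosity and caliber are
controlled by two parameters, enough to span the contrast between a dense
fine network and a small number of larger vessels.  Cells are drawn from
extravascular pixel centres with probability proportional to
``(1 − alpha) + alpha · exp(−d/lam)`` where ``d`` is the nearest-vessel
distance, so ``alpha = 0`` is exactly uniform (complete spatial randomness
over extravascular pixels) and ``alpha, lam`` are recoverable ground truth.
All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from vesselprox import __version__
from vesselprox.core import (
    Calibration,
    CellSet,
    JunctionLine,
    RegionOfInterest,
    VesselMask,
    rasterize_roi,
    write_cells,
    write_junction,
    write_mask,
    write_roi,
)
from vesselprox.profile import Axis, IntensityRaster
from vesselprox.proximity import compute_distance_field

__all__ = ["SyntheticConfig", "Scene", "generate_vessel_mask", "make_roi",
           "place_cells", "generate_scene", "write_scene"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic scene.

    Defaults emulate a single embryonic ossification-centre field of view at
    1 μm/px: a 400×600 px grid, an inscribed elliptical tissue ROI, a dozen
    tortuous tubes of ~6 μm radius (vessel area fraction ≈ 0.2, nearest-
    vessel distances of a few tens of μm), 300 cells, and two intensity
    channels — a mid-axis Gaussian bump ("peak") and a broad central
    "plateau" — on a constant background with additive Gaussian noise.
    """

    shape: tuple[int, int] = (400, 600)      # (rows, cols) px
    pixel_size: float = 1.0                  # μm/px
    n_tubes: int = 12
    tube_step: float = 6.0                   # μm per walk step
    tube_steps: int = 60
    tube_radius: float = 6.0                 # μm
    turn_sd: float = 0.3                     # rad, heading increment SD
    roi_shape: str = "ellipse"               # "ellipse" | "rectangle"
    roi_margin: float = 10.0                 # μm inset from the grid edge
    n_cells: int = 300
    alpha: float = 0.0                       # attraction weight in [0, 1]
    lam: float = 15.0                        # attraction length scale, μm
    seed: int = 0
    background_level: float = 10.0
    noise_sd: float = 2.0
    channels: tuple = (
        ("peak", "gaussian_bump", 100.0, 0.5, 40.0),      # amp, center_frac, sigma μm
        ("plateau", "plateau", 80.0, 0.25, 0.75),         # amp, start_frac, stop_frac
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if min(self.n_tubes, self.tube_steps, self.n_cells) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def calibration(self) -> Calibration:
        return Calibration(pixel_size=self.pixel_size)

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the grid in μm."""
        h, w = self.shape
        return w * self.pixel_size, h * self.pixel_size


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg_seed, spawn_key=(stream,)))


def make_roi(cfg: SyntheticConfig, n_vertices: int = 64) -> RegionOfInterest:
    """Elongated tissue ROI as a polygon inscribed in the grid.

    The canonical representation is the polygon (an ``n_vertices``-gon on
    the inset ellipse, or a rectangle); spatial operations rasterize it.
    """
    wx, wy = cfg.extent_um
    m = cfg.roi_margin
    if cfg.roi_shape == "rectangle":
        poly = np.array([[m, m], [wx - m, m], [wx - m, wy - m], [m, wy - m]])
    elif cfg.roi_shape == "ellipse":
        cx, cy = wx / 2.0, wy / 2.0
        a, b = wx / 2.0 - m, wy / 2.0 - m
        th = 2 * np.pi * np.arange(n_vertices) / n_vertices
        poly = np.column_stack([cx + a * np.cos(th), cy + b * np.sin(th)])
    else:
        raise ValueError(f"unknown roi_shape {cfg.roi_shape!r}")
    return RegionOfInterest(polygon_um=poly, name="POC")


def generate_vessel_mask(cfg: SyntheticConfig) -> VesselMask:
    """Union of dilated correlated-random-walk tubes, clipped to the grid.

    Each tube starts uniformly inside the ROI with a uniform heading; at
    every step the heading receives a Normal(0, turn_sd) increment and the
    walk advances ``tube_step`` μm.  The walk's polyline is rasterized at
    sub-pixel sampling and dilated to ``tube_radius`` via the Euclidean
    distance transform, so the tube caliber is a true physical radius.
    """
    s = cfg.pixel_size
    h, w = cfg.shape
    if cfg.tube_radius < s / 2.0:
        warnings.warn("tube_radius below half a pixel: tubes may be sub-pixel thin",
                      RuntimeWarning)
    centerline = np.zeros(cfg.shape, dtype=bool)
    if cfg.n_tubes == 0:
        warnings.warn("n_tubes = 0: generated mask is empty", RuntimeWarning)
        return VesselMask(grid=centerline, calibration=cfg.calibration)
    roi_raster = rasterize_roi(
        make_roi(cfg), VesselMask(grid=centerline, calibration=cfg.calibration)
    ).raster
    cand_i, cand_j = np.nonzero(roi_raster)
    rng = _rng(cfg.seed, 0)
    n_sub = max(2, int(np.ceil(cfg.tube_step / (0.5 * s))))
    for _ in range(cfg.n_tubes):
        k = rng.integers(0, cand_i.size)
        pos = np.array([(cand_j[k] + 0.5) * s, (cand_i[k] + 0.5) * s])
        heading = rng.uniform(0, 2 * np.pi)
        pts = [pos.copy()]
        for _ in range(cfg.tube_steps):
            heading += rng.normal(0.0, cfg.turn_sd)
            pos = pos + cfg.tube_step * np.array([np.cos(heading), np.sin(heading)])
            pts.append(pos.copy())
        pts = np.asarray(pts)
        # rasterize the polyline at <= s/2 spacing
        for p0, p1 in zip(pts[:-1], pts[1:]):
            frac = np.linspace(0.0, 1.0, n_sub + 1)[:, None]
            xy = p0 + frac * (p1 - p0)
            jj = np.floor(xy[:, 0] / s).astype(int)
            ii = np.floor(xy[:, 1] / s).astype(int)
            ok = (ii >= 0) & (ii < h) & (jj >= 0) & (jj < w)
            centerline[ii[ok], jj[ok]] = True
    if not centerline.any():
        return VesselMask(grid=centerline, calibration=cfg.calibration)
    dist = ndimage.distance_transform_edt(~centerline) * s
    grid = dist <= cfg.tube_radius
    return VesselMask(grid=grid, calibration=cfg.calibration)


def place_cells(
    mask: VesselMask,
    roi: RegionOfInterest,
    n_cells: int,
    alpha: float,
    lam: float,
    seed: int,
    label: str = "",
) -> CellSet:
    """Sample cells on extravascular pixel centres with vessel attraction.

    Pixel ``p`` (extravascular, inside the ROI) is drawn with probability
    proportional to ``(1 − alpha) + alpha · exp(−d_p / lam)`` where ``d_p``
    is its nearest-vessel distance; sampling is with replacement.
    ``alpha = 0`` reduces exactly to the uniform (CSR) null.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if lam <= 0:
        raise ValueError("lam must be > 0")
    field = compute_distance_field(mask, roi)
    extra = field.roi & (field.values > 0)
    ii, jj = np.nonzero(extra)
    if ii.size == 0:
        raise ValueError("ROI contains no extravascular pixels")
    if n_cells == 0:
        return CellSet(points=np.empty((0, 2)), label=label)
    d = field.values[ii, jj]
    weights = (1.0 - alpha) + alpha * np.exp(-d / lam)
    weights /= weights.sum()
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    idx = rng.choice(ii.size, size=n_cells, replace=True, p=weights)
    s = mask.pixel_size
    pts = np.column_stack([(jj[idx] + 0.5) * s, (ii[idx] + 0.5) * s])
    return CellSet(points=pts, label=label)


def _intensity_channels(
    cfg: SyntheticConfig, roi_raster: np.ndarray, axis: Axis
) -> tuple[dict[str, np.ndarray], dict]:
    """Noise-free channel fields (tissue signal over a constant background)."""
    s = cfg.pixel_size
    h, w = cfg.shape
    xs = (np.arange(w) + 0.5) * s
    ys = (np.arange(h) + 0.5) * s
    X, Y = np.meshgrid(xs, ys)
    p0, p1 = axis.points
    u = p1 - p0
    L = float(np.hypot(*u))
    t = ((X - p0[0]) * u[0] + (Y - p0[1]) * u[1]) / L  # axial position, μm
    fields: dict[str, np.ndarray] = {}
    truth: dict = {}
    for spec in cfg.channels:
        name, kind = spec[0], spec[1]
        base = np.full(cfg.shape, cfg.background_level, dtype=float)
        if kind == "gaussian_bump":
            amp, center_frac, sigma = spec[2], spec[3], spec[4]
            signal = amp * np.exp(-0.5 * ((t - center_frac * L) / sigma) ** 2)
            truth[name] = {"kind": kind, "amplitude": amp,
                           "center_um": center_frac * L, "sigma_um": sigma}
        elif kind == "plateau":
            amp, lo_frac, hi_frac = spec[2], spec[3], spec[4]
            signal = np.where((t >= lo_frac * L) & (t <= hi_frac * L), amp, 0.0)
            truth[name] = {"kind": kind, "amplitude": amp,
                           "start_um": lo_frac * L, "stop_um": hi_frac * L}
        elif kind == "ramp":
            amp = spec[2]
            signal = amp * np.clip(t / L, 0.0, 1.0)
            truth[name] = {"kind": kind, "amplitude": amp}
        else:
            raise ValueError(f"unknown channel kind {kind!r}")
        base[roi_raster] += signal[roi_raster]
        fields[name] = base
    return fields, truth


@dataclass
class Scene:
    """A complete synthetic fixture plus its ground-truth manifest."""

    mask: VesselMask
    cells: CellSet
    roi: RegionOfInterest
    junction: JunctionLine
    raster: IntensityRaster
    axis: Axis
    truth: dict


def generate_scene(cfg: SyntheticConfig) -> Scene:
    """Generate a full scene: mask, attracted cells, ROI, junction, channels.

    The junction polyline crosses the ROI's distal end (a shallow chevron at
    80% of the major axis); channels are the configured noise-free fields
    plus additive Gaussian noise (SD ``noise_sd``) clipped at zero.  The
    truth manifest records the config, seed, and per-channel ground truth.
    """
    mask = generate_vessel_mask(cfg)
    roi = make_roi(cfg)
    roi_raster = rasterize_roi(roi, mask).raster
    cells = place_cells(mask, roi, cfg.n_cells, cfg.alpha, cfg.lam, cfg.seed)

    wx, wy = cfg.extent_um
    cy = wy / 2.0
    half = 0.35 * wy
    xj = cfg.roi_margin + 0.8 * (wx - 2 * cfg.roi_margin)
    junction = JunctionLine(vertices=np.array([
        [xj, cy - half], [xj - 0.02 * wx, cy], [xj, cy + half]
    ]))

    axis = Axis(points=np.array([[cfg.roi_margin, cy], [wx - cfg.roi_margin, cy]]))
    fields, channel_truth = _intensity_channels(cfg, roi_raster, axis)
    rng = _rng(cfg.seed, 2)
    noisy = {
        name: np.clip(arr + rng.normal(0.0, cfg.noise_sd, size=arr.shape), 0.0, None)
        for name, arr in fields.items()
    }
    raster = IntensityRaster(channels=noisy, calibration=cfg.calibration)
    truth = {
        "generator": {"software": "vesselprox", "version": __version__},
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "alpha": cfg.alpha,
        "lam_um": cfg.lam,
        "axis_points_um": axis.points.tolist(),
        "channels": channel_truth,
    }
    return Scene(mask=mask, cells=cells, roi=roi, junction=junction,
                 raster=raster, axis=axis, truth=truth)


def write_scene(scene: Scene, outdir: str | Path) -> dict[str, Path]:
    """Write a scene in the standard on-disk formats; returns the paths."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "channels").mkdir(exist_ok=True)
    paths = {
        "mask": outdir / "mask.tif",
        "cells": outdir / "cells.csv",
        "roi": outdir / "roi.json",
        "junction": outdir / "junction.csv",
        "truth": outdir / "truth.json",
    }
    write_mask(scene.mask, paths["mask"])
    write_cells(scene.cells, paths["cells"])
    write_roi(scene.roi, paths["roi"])
    write_junction(scene.junction, paths["junction"])
    for name, arr in scene.raster.channels.items():
        p = outdir / "channels" / f"{name}.tif"
        tifffile.imwrite(p, arr.astype(np.float32))
        paths[f"channel:{name}"] = p
    with open(paths["truth"], "w") as fh:
        json.dump(scene.truth, fh, indent=2, sort_keys=True)
    return paths
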