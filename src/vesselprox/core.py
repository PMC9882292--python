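"""Shared data model, calibration conventions, and file I/O.

Coordinate convention
---------------------
Rasters are indexed ``grid[i, j]`` with ``i`` the row (y direction) and ``j``
the column (x direction), both 0-based.  Physical coordinates are in
micrometres with isotropic square pixels: the *centre* of pixel ``(i, j)``
sits at ``x = (j + 0.5) * s``, ``y = (i + 0.5) * s`` where ``s`` is the pixel
size in μm.  External CSV/JSON files always carry μm coordinates; pixel
indices never leave the library.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import LineString, Polygon

log = logging.getLogger("vesselprox")

__all__ = [
    "Calibration",
    "VesselMask",
    "CellSet",
    "RegionOfInterest",
    "JunctionLine",
    "pixel_centers",
    "um_to_index",
    "index_to_um",
    "read_mask",
    "write_mask",
    "read_cells",
    "write_cells",
    "read_roi",
    "write_roi",
    "read_junction",
    "write_junction",
    "rasterize_roi",
    "make_manifest",
    "sha256_file",
]


@dataclass(frozen=True)
class Calibration:
    """Isotropic physical pixel calibration.

    Parameters
    ----------
    pixel_size : float
        Edge length of one (square) pixel in μm.  Must be positive.
    """

    pixel_size: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.pixel_size) or self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be finite and > 0, got {self.pixel_size}")


@dataclass
class VesselMask:
    """Binary raster of vessel-positive pixels with physical calibration."""

    grid: np.ndarray
    calibration: Calibration

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {self.grid.shape}")
        if self.grid.dtype != bool:
            raise ValueError(f"mask must be boolean, got dtype {self.grid.dtype}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def pixel_size(self) -> float:
        return self.calibration.pixel_size

    @property
    def n_vessel_pixels(self) -> int:
        return int(self.grid.sum())

    def vessel_pixel_centers_um(self) -> np.ndarray:
        """(n, 2) array of [x, y] μm centres of all vessel pixels."""
        ii, jj = np.nonzero(self.grid)
        s = self.pixel_size
        return np.column_stack([(jj + 0.5) * s, (ii + 0.5) * s])


@dataclass
class CellSet:
    """Centroid coordinates of labelled cells in μm.

    ``points`` is an ``(n, 2)`` float array of ``[x, y]`` μm coordinates;
    an empty set is valid (downstream operations define the behaviour).
    """

    points: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must be (n, 2), got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("cell coordinates must be finite")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class RegionOfInterest:
    """Region of interest as a simple polygon (μm) and/or a boolean raster.

    Exactly one representation is required at construction; all spatial
    operations consume the raster form (see :func:`rasterize_roi`).
    """

    polygon_um: np.ndarray | None = None
    raster: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.polygon_um is None and self.raster is None:
            raise ValueError("ROI needs a polygon or a raster")
        if self.polygon_um is not None:
            poly = np.asarray(self.polygon_um, dtype=float)
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise ValueError("polygon must be (n>=3, 2) vertices in μm")
            shp = Polygon(poly)
            if not shp.is_valid or not shp.is_simple:
                raise ValueError("ROI polygon must be simple (non-self-intersecting)")
            self.polygon_um = poly
        if self.raster is not None:
            r = np.asarray(self.raster)
            if r.ndim != 2 or r.dtype != bool:
                raise ValueError("raster ROI must be a 2D boolean array")
            if not r.any():
                raise ValueError("raster ROI is empty")
            self.raster = r

    @property
    def is_raster(self) -> bool:
        return self.raster is not None

    def shapely_polygon(self) -> Polygon:
        if self.polygon_um is None:
            raise ValueError("ROI has no polygon representation")
        return Polygon(self.polygon_um)


@dataclass
class JunctionLine:
    """Ordered polyline (μm) marking the chondro-osseous junction."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValueError("junction needs >= 2 (x, y) vertices")
        if np.any(np.all(np.diff(v, axis=0) == 0, axis=1)):
            raise ValueError("consecutive junction vertices must be distinct")
        self.vertices = v

    def shapely_line(self) -> LineString:
        return LineString(self.vertices)

    @property
    def length(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.vertices, axis=0).T)))


# ---------------------------------------------------------------------------
# coordinate helpers


def pixel_centers(shape: tuple[int, int], pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(x, y)`` μm centre coordinates for every pixel of ``shape``.

    Both arrays have the raster's shape; ``x`` varies along columns, ``y``
    along rows.
    """
    h, w = shape
    s = pixel_size
    x = (np.arange(w) + 0.5) * s
    y = (np.arange(h) + 0.5) * s
    return np.meshgrid(x, y)


def um_to_index(points_um: np.ndarray, pixel_size: float) -> np.ndarray:
    """Map μm coordinates ``[x, y]`` to containing pixel indices ``[i, j]``.

    A coordinate exactly on a pixel boundary belongs to the pixel on its
    high side (floor rule), matching the half-open pixel footprint
    ``[j*s, (j+1)*s) × [i*s, (i+1)*s)``.
    """
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    idx = np.floor(pts / pixel_size).astype(int)
    return idx[:, ::-1]  # (x, y) -> (i, j)


def index_to_um(indices: np.ndarray, pixel_size: float) -> np.ndarray:
    """Map pixel indices ``[i, j]`` to their centre coordinates ``[x, y]`` μm."""
    idx = np.atleast_2d(np.asarray(indices))
    s = pixel_size
    return np.column_stack([(idx[:, 1] + 0.5) * s, (idx[:, 0] + 0.5) * s])


# ---------------------------------------------------------------------------
# readers / writers


def _read_raster(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    return np.asarray(arr)


def read_mask(
    path: str | Path,
    calibration: Calibration,
    threshold: float | None = None,
) -> VesselMask:
    """Read a single-channel TIFF/PNG raster as a binary vessel mask.

    Boolean rasters pass through unchanged.  Grayscale rasters are binarized
    with a strict ``value > threshold`` rule; ``threshold`` is then required.
    Multi-channel images are rejected (channel selection is upstream).  An
    all-false result is legal but logged as a warning.
    """
    arr = _read_raster(path)
    arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel 2D raster, got shape {arr.shape}"
        )
    if arr.dtype == bool:
        grid = arr
    else:
        if threshold is None:
            raise ValueError(f"{path}: grayscale input requires a threshold")
        grid = arr > threshold
    if not grid.any():
        log.warning("%s: mask has zero vessel pixels", path)
    return VesselMask(grid=grid, calibration=calibration)


def write_mask(mask: VesselMask, path: str | Path) -> None:
    """Write a mask as an 8-bit TIFF/PNG (0 background, 1 foreground)."""
    path = Path(path)
    data = mask.grid.astype(np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, data)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, data)


def read_cells(path: str | Path) -> CellSet:
    """Read cell centroids from a CSV with columns ``x_um,y_um[,label]``."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"x_um", "y_um"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    try:
        pts = df[["x_um", "y_um"]].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric coordinates") from exc
    label = ""
    if "label" in df.columns and len(df):
        label = str(df["label"].iloc[0])
    return CellSet(points=pts, label=label)


def write_cells(cells: CellSet, path: str | Path) -> None:
    """Write cells as CSV; floats use shortest-repr so round trips are bitwise."""
    with open(path, "w") as fh:
        header = "x_um,y_um" + (",label" if cells.label else "")
        fh.write(header + "\n")
        for x, y in cells.points:
            row = f"{float(x)!r},{float(y)!r}"
            if cells.label:
                row += f",{cells.label}"
            fh.write(row + "\n")


def read_roi(path: str | Path, name: str = "") -> RegionOfInterest:
    """Read an ROI from JSON ``{"polygon_um": [[x, y], ...]}`` or a TIFF mask."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            obj = json.load(fh)
        if "polygon_um" not in obj:
            raise ValueError(f"{path}: JSON ROI must contain 'polygon_um'")
        return RegionOfInterest(
            polygon_um=np.asarray(obj["polygon_um"], dtype=float),
            name=name or obj.get("name", ""),
        )
    arr = np.squeeze(_read_raster(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: ROI raster must be 2D")
    return RegionOfInterest(raster=arr.astype(bool), name=name)


def write_roi(roi: RegionOfInterest, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        if roi.polygon_um is None:
            raise ValueError("raster-only ROI cannot be written to JSON")
        obj = {"polygon_um": [[float(x), float(y)] for x, y in roi.polygon_um]}
        if roi.name:
            obj["name"] = roi.name
        with open(path, "w") as fh:
            json.dump(obj, fh)
    else:
        if roi.raster is None:
            raise ValueError("polygon-only ROI cannot be written as raster")
        tifffile.imwrite(path, roi.raster.astype(np.uint8))


def read_junction(path: str | Path) -> JunctionLine:
    """Read junction polyline vertices from a CSV with columns ``x_um,y_um``."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"x_um", "y_um"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return JunctionLine(vertices=df[["x_um", "y_um"]].to_numpy(dtype=float))


def write_junction(junction: JunctionLine, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("x_um,y_um\n")
        for x, y in junction.vertices:
            fh.write(f"{float(x)!r},{float(y)!r}\n")


# ---------------------------------------------------------------------------
# rasterization


def rasterize_roi(roi: RegionOfInterest, mask: VesselMask) -> RegionOfInterest:
    """Rasterize a polygon ROI onto a mask's grid by the pixel-centre rule.

    A pixel belongs to the ROI iff its centre ``((j+0.5)s, (i+0.5)s)`` lies
    strictly inside the polygon.  Raster ROIs pass through after a shape
    check.  Raises if the rasterization is empty (polygon outside the grid).
    """
    if roi.is_raster:
        if roi.raster.shape != mask.shape:
            raise ValueError(
                f"raster ROI shape {roi.raster.shape} != mask shape {mask.shape}"
            )
        return roi
    poly = roi.shapely_polygon()
    xs, ys = pixel_centers(mask.shape, mask.pixel_size)
    inside = shapely.contains_xy(poly, xs.ravel(), ys.ravel()).reshape(mask.shape)
    if not inside.any():
        raise ValueError("ROI polygon does not cover any pixel centre of the grid")
    return RegionOfInterest(polygon_um=roi.polygon_um, raster=inside, name=roi.name)


# ---------------------------------------------------------------------------
# provenance


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def make_manifest(
    inputs: dict[str, str | Path] | None = None,
    parameters: dict | None = None,
    seed: int | None = None,
) -> dict:
    """Build a reproducibility manifest: version, seed, parameters, checksums."""
    from vesselprox import __version__

    manifest: dict = {"software": "vesselprox", "version": __version__, "seed": seed}
    manifest["parameters"] = dict(parameters or {})
    manifest["inputs"] = {
        key: {"path": str(p), "sha256": sha256_file(p)}
        for key, p in (inputs or {}).items()
    }
    return manifest
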