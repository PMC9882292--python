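"""Nearest-vessel distance field and per-cell proximity distributions.

The central quantity is the Euclidean distance from each labelled cell to the
nearest vessel pixel.  Distances are measured between a cell's continuous μm
coordinate and vessel *pixel centres*; the per-pixel field uses the same
centre-to-centre metric, so placing a point on a pixel centre reproduces the
field value exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from vesselprox.core import (
    Calibration,
    CellSet,
    RegionOfInterest,
    VesselMask,
    rasterize_roi,
    um_to_index,
)

log = logging.getLogger("vesselprox")

__all__ = ["DistanceField", "ProximitySummary", "compute_distance_field",
           "cell_distances", "summarize", "ecdf"]


@dataclass
class DistanceField:
    """Per-pixel Euclidean distance (μm) to the nearest vessel pixel centre.

    ``values`` covers the full grid (distances are always measured to the
    nearest vessel pixel anywhere on the grid); ``roi`` marks where the field
    is considered defined for downstream statistics.  Vessel pixels are
    exactly zero.
    """

    values: np.ndarray
    roi: np.ndarray
    calibration: Calibration

    @property
    def pixel_size(self) -> float:
        return self.calibration.pixel_size

    @property
    def vessel(self) -> np.ndarray:
        """Boolean raster of vessel pixels (recovered as the zero level set)."""
        return self.values == 0.0

    def masked(self) -> np.ndarray:
        """Field with NaN outside the ROI."""
        out = self.values.copy()
        out[~self.roi] = np.nan
        return out

    def extravascular_distances(self) -> np.ndarray:
        """Distances at every extravascular pixel centre inside the ROI."""
        return self.values[self.roi & ~self.vessel]


def compute_distance_field(
    mask: VesselMask, roi: RegionOfInterest | None = None
) -> DistanceField:
    """Exact Euclidean distance transform of the vessel mask, in μm.

    Parameters
    ----------
    mask : VesselMask
        Binary vessel raster; must contain at least one vessel pixel.
    roi : RegionOfInterest, optional
        Polygon or raster ROI; rasterized onto the mask grid.  Defaults to
        the whole grid.

    Returns
    -------
    DistanceField
        ``values[i, j]`` is the distance from the centre of pixel ``(i, j)``
        to the nearest vessel pixel centre, anywhere on the grid.
    """
    if not mask.grid.any():
        raise ValueError("mask has no vessel pixels; distance field undefined")
    if roi is None:
        roi_raster = np.ones(mask.shape, dtype=bool)
    else:
        roi_raster = rasterize_roi(roi, mask).raster
    values = ndimage.distance_transform_edt(~mask.grid) * mask.pixel_size
    return DistanceField(values=values, roi=roi_raster, calibration=mask.calibration)


def cell_distances(cells: CellSet, field: DistanceField) -> np.ndarray:
    """Exact distance (μm) from each cell to the nearest vessel pixel centre.

    Cells are matched against vessel pixel centres with a k-d tree on their
    continuous μm coordinates — not by snapping to the grid — so a cell whose
    coordinate coincides with a vessel pixel centre scores exactly zero.
    Cells whose containing pixel lies outside the ROI (or off the grid) are
    dropped with a logged count.  An empty cell set yields an empty array.
    """
    if len(cells) == 0:
        return np.empty(0, dtype=float)
    s = field.pixel_size
    idx = um_to_index(cells.points, s)
    h, w = field.values.shape
    on_grid = (
        (idx[:, 0] >= 0) & (idx[:, 0] < h) & (idx[:, 1] >= 0) & (idx[:, 1] < w)
    )
    inside = on_grid.copy()
    inside[on_grid] = field.roi[idx[on_grid, 0], idx[on_grid, 1]]
    n_dropped = int((~inside).sum())
    if n_dropped:
        log.info("cell_distances: dropped %d cell(s) outside the ROI", n_dropped)
    pts = cells.points[inside]
    if pts.shape[0] == 0:
        return np.empty(0, dtype=float)
    ii, jj = np.nonzero(field.vessel)
    centers = np.column_stack([(jj + 0.5) * s, (ii + 0.5) * s])
    tree = cKDTree(centers)
    dist, _ = tree.query(pts, k=1)
    return np.asarray(dist, dtype=float)


def ecdf(sample: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous empirical CDF: sorted values and cumulative fractions."""
    x = np.sort(np.asarray(sample, dtype=float))
    y = np.arange(1, x.size + 1) / x.size
    return x, y


@dataclass
class ProximitySummary:
    """Summary of a per-cell nearest-vessel distance sample.

    ``mean``/``sd`` use the sample (n−1) standard deviation; ``sd`` is NaN
    for fewer than two distances.  The histogram lives on uniform bins of
    ``bin_width`` μm starting at ``bin_start``; the ECDF is the
    right-continuous step function through the sorted distances.
    """

    distances: np.ndarray
    mean: float
    sd: float
    bin_edges: np.ndarray
    counts: np.ndarray
    ecdf_x: np.ndarray
    ecdf_y: np.ndarray

    @property
    def n(self) -> int:
        return self.distances.size

    def ecdf_at(self, x) -> np.ndarray:
        """Evaluate the ECDF at ``x`` (right-continuous)."""
        return np.searchsorted(self.ecdf_x, np.asarray(x, dtype=float), side="right") / max(self.n, 1)


def summarize(
    distances: np.ndarray, bin_width: float = 5.0, bin_start: float = 0.0
) -> ProximitySummary:
    """Mean ± sample SD, histogram, and ECDF of a distance sample.

    Requires at least one distance; the SD additionally requires two and is
    NaN otherwise.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("cannot summarize an empty distance sample")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    mean = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size >= 2 else float("nan")
    # np.histogram closes the last bin, so ceil-ing to the max keeps counts
    # summing to n even when the max sits exactly on an edge
    n_bins = max(1, int(np.ceil((d.max() - bin_start) / bin_width)))
    edges = bin_start + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(d, bins=edges)
    x, y = ecdf(d)
    return ProximitySummary(
        distances=d, mean=mean, sd=sd, bin_edges=edges, counts=counts,
        ecdf_x=x, ecdf_y=y,
    )
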