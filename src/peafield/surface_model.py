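"""Terrain and canopy surfaces: DTM interpolation, CSM, canopy metrics.

The crop surface model is the per-pixel difference ``CSM = DSM - DTM``
(height above ground level). Canopy is segmented at a height threshold
(default 0.15 m AGL, strict ``>``); pixels at or below the threshold are
non-target canopy and double as the soil mask. Per plot:

    CH_uas = mean CSM over in-plot canopy pixels   [m]
    CC     = n_canopy_pixels * pixel_area          [m^2]
    PV     = CH_uas * CC                           [m^3]

CH_uas uses the mean (a config option offers upper percentiles) so that
PV approximates the integral of canopy height over the covered area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import QhullError

from .geo_io import ElevationGrid, GeoTransform, PlotRecord
from .zonal import polygon_pixel_mask

#: Height above ground (m) separating canopy from non-target canopy.
DEFAULT_CANOPY_THRESHOLD = 0.15

#: Cap on soil samples fed to the DTM interpolator; a denser cloud adds
#: nothing to a low-order terrain surface. Subsampling is by fixed stride,
#: hence deterministic.
_MAX_SOIL_SAMPLES = 4000


class SurfaceModelError(ValueError):
    pass


@dataclass
class CanopyMask:
    """Binary canopy/non-canopy grid; True = canopy (CSM > threshold)."""

    values: np.ndarray
    threshold: float
    transform: GeoTransform

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class PlotCanopyMetrics:
    plot_id: str
    ch_uas: float
    cc: float
    pv: float
    n_canopy_pixels: int


def _soil_points_from_mask(dsm: ElevationGrid, soil_mask: np.ndarray):
    rows, cols = np.nonzero(soil_mask & ~dsm.nodata_mask)
    if rows.size > _MAX_SOIL_SAMPLES:
        stride = int(np.ceil(rows.size / _MAX_SOIL_SAMPLES))
        rows, cols = rows[::stride], cols[::stride]
    e, n = dsm.transform.pixel_center(rows, cols)
    z = dsm.values[rows, cols]
    return np.column_stack([e, n]), z


def build_dtm(dsm: ElevationGrid,
              soil_points_or_mask: np.ndarray) -> ElevationGrid:
    """Interpolate bare-soil elevations to a full-grid terrain model.

    ``soil_points_or_mask`` is either a boolean grid marking bare-soil
    pixels of the DSM, or an (n, 3) array of (easting, northing, z)
    samples. Interpolation is piecewise-linear over a Delaunay
    triangulation of the soil points, with nearest-value extrapolation
    outside their convex hull; at soil sample pixels the DTM equals the
    DSM exactly.
    """
    arr = np.asarray(soil_points_or_mask)
    if arr.dtype == bool:
        if arr.shape != dsm.shape:
            raise SurfaceModelError("soil mask shape differs from DSM shape")
        xy, z = _soil_points_from_mask(dsm, arr)
    else:
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise SurfaceModelError(
                "soil points must be an (n, 3) array of easting, northing, z")
        xy, z = arr[:, :2].astype(float), arr[:, 2].astype(float)
    if xy.shape[0] < 3:
        raise SurfaceModelError(
            f"insufficient soil support: need >= 3 soil points, got {xy.shape[0]}")
    try:
        linear = LinearNDInterpolator(xy, z)
    except QhullError as exc:
        raise SurfaceModelError(
            "insufficient soil support: soil points are collinear") from exc
    if linear.tri.simplices.size == 0:  # pragma: no cover - qhull guards first
        raise SurfaceModelError("insufficient soil support: degenerate triangulation")
    nearest = NearestNDInterpolator(xy, z)
    nrows, ncols = dsm.shape
    cgrid, rgrid = np.meshgrid(np.arange(ncols), np.arange(nrows))
    e, n = dsm.transform.pixel_center(rgrid, cgrid)
    values = linear(e, n)
    outside = np.isnan(values)
    if outside.any():
        values[outside] = nearest(e[outside], n[outside])
    return ElevationGrid(values=values, transform=dsm.transform, role="DTM",
                         nodata_mask=dsm.nodata_mask.copy())


def compute_csm(dsm: ElevationGrid, dtm: ElevationGrid) -> ElevationGrid:
    """Per-pixel crop surface model, ``DSM - DTM``; nodata propagates."""
    if dsm.shape != dtm.shape or dsm.transform != dtm.transform:
        raise SurfaceModelError("DSM and DTM must share shape and transform")
    mask = dsm.nodata_mask | dtm.nodata_mask
    values = dsm.values - dtm.values
    values = np.where(mask, np.nan, values)
    return ElevationGrid(values=values, transform=dsm.transform, role="CSM",
                         nodata_mask=mask)


def segment_canopy(csm: ElevationGrid,
                   threshold: float = DEFAULT_CANOPY_THRESHOLD) -> CanopyMask:
    """Classify pixels strictly above ``threshold`` m AGL as canopy.

    The complement (including nodata) is the soil/non-target mask.
    """
    if csm.role != "CSM":
        raise SurfaceModelError(f"expected a CSM grid, got role {csm.role!r}")
    if threshold < 0:
        raise SurfaceModelError(f"canopy threshold must be >= 0, got {threshold}")
    with np.errstate(invalid="ignore"):
        values = (csm.values > threshold) & ~csm.nodata_mask
    return CanopyMask(values=values, threshold=threshold, transform=csm.transform)


def plot_canopy_metrics(csm: ElevationGrid, mask: CanopyMask,
                        plot: PlotRecord,
                        height_statistic: str = "mean") -> PlotCanopyMetrics:
    """Canopy height, coverage and volume for one plot polygon.

    ``height_statistic``: "mean" (default) or "pXX" for the XX-th
    percentile of in-plot canopy CSM values. A plot with no canopy pixels
    reports CH = CC = PV = 0.
    """
    if csm.shape != mask.shape:
        raise SurfaceModelError("CSM and canopy mask must share shape")
    in_plot = polygon_pixel_mask(plot.polygon, csm.transform, csm.shape)
    if not in_plot.any():
        raise SurfaceModelError(
            f"plot {plot.plot_id!r} lies fully outside the raster")
    canopy = in_plot & mask.values & ~csm.nodata_mask
    n = int(np.count_nonzero(canopy))
    if n == 0:
        return PlotCanopyMetrics(plot.plot_id, 0.0, 0.0, 0.0, 0)
    heights = csm.values[canopy]
    if height_statistic == "mean":
        ch = float(np.mean(heights))
    elif height_statistic.startswith("p"):
        ch = float(np.percentile(heights, float(height_statistic[1:])))
    else:
        raise SurfaceModelError(f"unknown height statistic {height_statistic!r}")
    cc = n * csm.transform.pixel_area
    return PlotCanopyMetrics(plot.plot_id, ch, cc, ch * cc, n)


def soil_mask_from_plots(grid: ElevationGrid, plots) -> np.ndarray:
    """Default bare-soil mask: every pixel outside all plot polygons."""
    mask = np.zeros(grid.shape, dtype=bool)
    for p in plots:
        mask |= polygon_pixel_mask(p.polygon, grid.transform, grid.shape)
    return ~mask
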