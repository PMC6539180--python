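"""Pixel-center-in-polygon rasterization shared by zonal statistics and
radiometry.

A pixel belongs to a polygon iff its center lies strictly inside the
polygon. With half-open pixel cells and alleys between plots this rule is
deterministic and never assigns one pixel to two disjoint plot polygons.
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import Polygon

from .geo_io import GeoTransform


def polygon_pixel_mask(polygon: Polygon, transform: GeoTransform,
                       shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside ``polygon``.

    Only the pixel window covered by the polygon's bounding box is tested,
    so cost scales with the polygon, not the raster.
    """
    nrows, ncols = shape
    minx, miny, maxx, maxy = polygon.bounds
    r0, c0 = transform.map_to_pixel(minx, maxy)
    r1, c1 = transform.map_to_pixel(maxx, miny)
    r0 = max(int(r0), 0)
    c0 = max(int(c0), 0)
    r1 = min(int(r1) + 1, nrows)
    c1 = min(int(c1) + 1, ncols)
    mask = np.zeros(shape, dtype=bool)
    if r0 >= r1 or c0 >= c1:
        return mask
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    cgrid, rgrid = np.meshgrid(cols, rows)
    e, n = transform.pixel_center(rgrid, cgrid)
    mask[r0:r1, c0:c1] = shapely.contains_xy(polygon, e, n)
    return mask
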