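"""Radiometric correction and vegetation-index grids.

Correction uses a white reference panel (nominal reflectance 0.99 across
the visible/RE/NIR range) imaged in the scene: each band is rescaled by a
single global gain so the panel-region mean equals the nominal panel
reflectance. Indices:

    GRVI = (G - R) / (G + R)
    NDVI = (NIR - R) / (NIR + R)
    NDRE = (NIR - RE) / (NIR + RE)
    NIRv = NIR * NDVI - 0.08          (default form)
         = (NDVI - 0.08) * NIR        (variant "badgley")

Pixels whose normalized-difference denominator is zero become nodata rather
than +/-inf so plot-level sums stay finite. Nearest-neighbour resampling
degrades resolution (e.g. to emulate 1.5 m satellite pixels) without
introducing values absent from the source grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .geo_io import BandStack, ElevationGrid, GeoTransform
from .zonal import polygon_pixel_mask

VI_NAMES = ("GRVI", "NDVI", "NDRE", "NIRv")

_VI_BANDS = {"GRVI": ("G", "R"), "NDVI": ("NIR", "R"), "NDRE": ("NIR", "RE")}


class RadiometryError(ValueError):
    pass


@dataclass
class ValueGrid:
    """Per-pixel unitless index values with the stack's geotransform."""

    values: np.ndarray
    index_name: str
    transform: GeoTransform
    nodata_mask: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def panel_correct(stack: BandStack, panel_polygon: Polygon,
                  panel_reflectance: float = 0.99) -> BandStack:
    """Scale every band by ``panel_reflectance / mean(panel pixels)``.

    A single global gain per band — the panel is assumed representative of
    the whole mosaic (no vignetting model).
    """
    inside = polygon_pixel_mask(panel_polygon, stack.transform, stack.shape)
    inside &= ~stack.nodata_mask
    if not inside.any():
        raise RadiometryError("no panel pixels: panel polygon contains no valid pixels")
    corrected = {}
    for name, band in stack.bands.items():
        mean = float(np.mean(band[inside]))
        if mean <= 0:
            raise RadiometryError(
                f"band {name}: panel mean {mean!r} is not positive; cannot correct")
        corrected[name] = band * (panel_reflectance / mean)
    return BandStack(bands=corrected, transform=stack.transform,
                     nodata_mask=stack.nodata_mask.copy())


def compute_vi(stack: BandStack, index_name: str) -> ValueGrid:
    """Normalized-difference index grid (GRVI, NDVI or NDRE)."""
    if index_name == "NIRv":
        return compute_nirv(stack)
    if index_name not in _VI_BANDS:
        raise RadiometryError(f"unknown index {index_name!r}; expected one of {VI_NAMES}")
    a_name, b_name = _VI_BANDS[index_name]
    a, b = stack.band(a_name), stack.band(b_name)
    denom = a + b
    bad = stack.nodata_mask | (denom == 0) | ~np.isfinite(denom)
    values = np.full(a.shape, np.nan)
    np.divide(a - b, denom, out=values, where=~bad)
    return ValueGrid(values=values, index_name=index_name,
                     transform=stack.transform, nodata_mask=bad)


def compute_nirv(stack: BandStack, variant: str = "paper") -> ValueGrid:
    """NIR reflectance of vegetation.

    ``variant="paper"`` computes ``NIR * NDVI - 0.08`` (offset subtracted
    from the NIR x NDVI product); ``variant="badgley"`` computes
    ``(NDVI - 0.08) * NIR``, the form of the index's original source.
    """
    if variant not in ("paper", "badgley"):
        raise RadiometryError(f"unknown NIRv variant {variant!r}")
    ndvi = compute_vi(stack, "NDVI")
    nir = stack.band("NIR")
    if variant == "paper":
        values = nir * ndvi.values - 0.08
    else:
        values = (ndvi.values - 0.08) * nir
    values = np.where(ndvi.nodata_mask, np.nan, values)
    return ValueGrid(values=values, index_name="NIRv",
                     transform=stack.transform, nodata_mask=ndvi.nodata_mask.copy())


def resample_nearest(grid, target_pixel_size: float):
    """Degrade a grid to a coarser pixel size by nearest-neighbour sampling.

    Each output pixel takes the value of the source pixel whose center is
    nearest the output pixel center; the output value set is a subset of the
    input's. Upsampling is refused — the operation models coarser sensors.
    """
    transform = grid.transform
    src = transform.pixel_size
    if target_pixel_size < src:
        raise RadiometryError(
            f"target pixel size {target_pixel_size} is smaller than source {src}; "
            "only degradation (no upsampling) is supported")
    if target_pixel_size == src:
        return grid

    def _resample_array(values: np.ndarray) -> tuple[np.ndarray, GeoTransform]:
        nrows, ncols = values.shape
        out_rows = max(1, int(np.ceil(nrows * src / target_pixel_size)))
        out_cols = max(1, int(np.ceil(ncols * src / target_pixel_size)))
        rr = np.arange(out_rows)
        cc = np.arange(out_cols)
        # nearest source-pixel center to each output-pixel center
        src_r = np.clip(np.floor((rr + 0.5) * target_pixel_size / src).astype(int),
                        0, nrows - 1)
        src_c = np.clip(np.floor((cc + 0.5) * target_pixel_size / src).astype(int),
                        0, ncols - 1)
        out_tf = GeoTransform(transform.origin_easting, transform.origin_northing,
                              target_pixel_size)
        return values[np.ix_(src_r, src_c)], out_tf

    if isinstance(grid, BandStack):
        bands = {}
        for name, band in grid.bands.items():
            bands[name], out_tf = _resample_array(band)
        mask, _ = _resample_array(grid.nodata_mask.astype(float))
        return BandStack(bands=bands, transform=out_tf, nodata_mask=mask > 0.5)
    if isinstance(grid, ElevationGrid):
        values, out_tf = _resample_array(grid.values)
        mask, _ = _resample_array(grid.nodata_mask.astype(float))
        return ElevationGrid(values=values, transform=out_tf, role=grid.role,
                             nodata_mask=mask > 0.5)
    if isinstance(grid, ValueGrid):
        values, out_tf = _resample_array(grid.values)
        mask, _ = _resample_array(grid.nodata_mask.astype(float))
        return ValueGrid(values=values, index_name=grid.index_name,
                         transform=out_tf, nodata_mask=mask > 0.5)
    raise RadiometryError(f"cannot resample object of type {type(grid).__name__}")
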